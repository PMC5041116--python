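"""Life-history parameters and strategy (phenotype) containers.

The model describes a hermaphroditic perennial plant that divides a fixed
resource budget (normalized to R = 1) among three functions each season:
pollen production (proportion M), ovule/seed production (proportion F), and
its own survival (the remainder 1 - M - F).  A phenotype is equivalently
written in life-history coordinates as the reproductive allocation
E = M + F, the sex allocation r = M / E, and the selfing rate s.

Selfed offspring suffer inbreeding depression twice: a fraction delta_j of
selfed juveniles die during recruitment (relative survivorship
w_j = 1 - delta_j) and a fraction delta_a of selfed adults die each season
(w_a = 1 - delta_a).  gamma is the growth rate of the selfed-adult fraction:
with a linear uptake S(s) = gamma * s, a resident selfing rate s puts a
fraction gamma * s of adults in the selfed class.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import DomainError

__all__ = ["LifeHistoryParams", "Strategy"]


class LifeHistoryParams(BaseModel):
    """All model constants, validated on construction and immutable.

    Defaults are the package's running example: a moderately fecund perennial
    with stronger adult than juvenile inbreeding depression.

    Attributes
    ----------
    Pj : float
        Juvenile (outcrossed) survivorship through recruitment, in (0, 1].
    delta_j : float
        Fraction of juvenile inbreeding depression, in [0, 1].
    delta_a : float
        Fraction of adult inbreeding depression, in [0, 1].
    gamma : float
        Growth rate of the self-fertilized adult class, in (0, 1); the slope
        of the default selfed-adult fraction S(s) = gamma * s.
    f_max : float
        Seeds produced when every resource goes to seed production (> 0).
    m_max : float
        Pollen produced when every resource goes to pollen production (> 0).
    eta : float
        Exponent of the power-law male gain curve m(M) = m_max * M**eta,
        in (0, 1]; eta < 1 gives diminishing returns on pollen.
    Pa_max : float
        Adult survivorship with zero reproductive spending, in (0, 1].
    beta : float
        Curvature of the default adult-survival curve
        Pa(E) = Pa_max * (1 - E)**beta, in (0, 1).
    R : float
        Total resource budget.  Allocations are proportions of R, so R is a
        bookkeeping constant; the default (and normalization) is 1.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    Pj: float = Field(default=0.2, gt=0.0, le=1.0)
    delta_j: float = Field(default=0.2, ge=0.0, le=1.0)
    delta_a: float = Field(default=0.4, ge=0.0, le=1.0)
    gamma: float = Field(default=0.5, gt=0.0, lt=1.0)
    f_max: float = Field(default=10.0, gt=0.0)
    m_max: float = Field(default=100.0, gt=0.0)
    eta: float = Field(default=0.8, gt=0.0, le=1.0)
    Pa_max: float = Field(default=0.9, gt=0.0, le=1.0)
    beta: float = Field(default=0.5, gt=0.0, lt=1.0)
    R: float = Field(default=1.0, gt=0.0)

    @property
    def w_j(self) -> float:
        """Relative survivorship of selfed juveniles, 1 - delta_j."""
        return 1.0 - self.delta_j

    @property
    def w_a(self) -> float:
        """Relative survivorship of selfed adults, 1 - delta_a."""
        return 1.0 - self.delta_a

    def with_updates(self, **updates) -> "LifeHistoryParams":
        """Return a copy with fields replaced, re-running validation."""
        data = self.model_dump()
        data.update(updates)
        return LifeHistoryParams(**data)


class Strategy(BaseModel):
    """A phenotype (E, r, s) on the resource-allocation simplex.

    E is the proportion of total resources spent on reproduction, r the
    proportion of reproductive resources spent on male function, s the
    selfing rate.  M = E*r and F = E*(1 - r) recover the raw allocations;
    the remainder 1 - E funds survival.  At E = 0 the convention r = 0 is
    used (fitness does not depend on r there).
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    E: float = Field(ge=0.0, le=1.0)
    r: float = Field(ge=0.0, le=1.0)
    s: float = Field(ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _canonical_r_at_zero_E(self) -> "Strategy":
        if self.E == 0.0 and self.r != 0.0:
            object.__setattr__(self, "r", 0.0)
        return self

    @property
    def M(self) -> float:
        """Proportion of total resources allocated to pollen, E * r."""
        return self.E * self.r

    @property
    def F(self) -> float:
        """Proportion of total resources allocated to seeds, E * (1 - r)."""
        return self.E * (1.0 - self.r)

    @classmethod
    def from_MF(cls, M: float, F: float, s: float) -> "Strategy":
        """Build a strategy from raw allocations (M, F) and selfing rate s."""
        if M < 0.0 or F < 0.0:
            raise DomainError(f"allocations must be nonnegative, got M={M}, F={F}")
        E = M + F
        if E > 1.0:
            # tolerate round-off from callers that split E numerically
            if E <= 1.0 + 1e-12:
                E = 1.0
            else:
                raise DomainError(f"M + F = {E} exceeds the resource budget 1")
        r = M / E if E > 0.0 else 0.0
        return cls(E=E, r=min(max(r, 0.0), 1.0), s=s)
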