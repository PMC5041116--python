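"""Gain curves: resource-to-fitness maps and the selfed-adult fraction.

Four curves parameterize the model:

* ``Pa(E)`` — adult survivorship as a function of reproductive spending,
  strictly decreasing and strictly concave (default ``Pa_max * (1-E)**beta``);
* ``f(F)`` — seed number (default linear, ``f_max * F``);
* ``m(M)`` — pollen number (default power, ``m_max * M**eta``);
* ``S(s)`` — fraction of selfed adults (default linear, ``gamma * s``).

Every curve exposes ``__call__`` and ``derivative``; the default curves also
expose ``second_derivative``.  Curves validate their argument domain and raise
:class:`~perennial_ess.errors.DomainError` outside it.  The bundle
:class:`GainFunctions` groups the four and builds the defaults from a
parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

from .errors import DomainError
from .params import LifeHistoryParams

__all__ = [
    "Curve",
    "PowerSurvival",
    "LinearGain",
    "PowerGain",
    "LinearSelfedFraction",
    "FixedValue",
    "GainFunctions",
    "adult_survival",
    "female_gain",
    "male_gain",
    "selfed_adult_fraction",
]


def _check_unit(x: float, name: str) -> None:
    if not 0.0 <= x <= 1.0:
        raise DomainError(f"{name} must lie in [0, 1], got {x}")


@runtime_checkable
class Curve(Protocol):
    """A scalar map on [0, 1] with a first derivative."""

    def __call__(self, x: float) -> float: ...

    def derivative(self, x: float) -> float: ...


@dataclass(frozen=True)
class PowerSurvival:
    """Adult survival Pa(E) = scale * (1 - E)**beta.

    Strictly decreasing and strictly concave on [0, 1) for beta in (0, 1);
    reaches 0 at E = 1, where the derivative diverges (not evaluated there).
    """

    scale: float
    beta: float

    def __call__(self, E: float) -> float:
        _check_unit(E, "E")
        return self.scale * (1.0 - E) ** self.beta

    def derivative(self, E: float) -> float:
        _check_unit(E, "E")
        if E == 1.0:
            raise DomainError("Pa'(E) diverges at E = 1 for beta < 1")
        return -self.scale * self.beta * (1.0 - E) ** (self.beta - 1.0)

    def second_derivative(self, E: float) -> float:
        _check_unit(E, "E")
        if E == 1.0:
            raise DomainError("Pa''(E) diverges at E = 1 for beta < 1")
        b = self.beta
        return self.scale * b * (b - 1.0) * (1.0 - E) ** (b - 2.0)


@dataclass(frozen=True)
class LinearGain:
    """Linear gain slope * x; the default female curve f(F) = f_max * F."""

    slope: float

    def __call__(self, x: float) -> float:
        _check_unit(x, "allocation")
        return self.slope * x

    def derivative(self, x: float) -> float:
        _check_unit(x, "allocation")
        return self.slope

    def second_derivative(self, x: float) -> float:
        _check_unit(x, "allocation")
        return 0.0


@dataclass(frozen=True)
class PowerGain:
    """Power gain scale * x**exponent; the default male curve.

    For exponent < 1 the derivative is unbounded at x = 0; solvers must not
    evaluate the derivative there.
    """

    scale: float
    exponent: float

    def __call__(self, x: float) -> float:
        _check_unit(x, "allocation")
        return self.scale * x ** self.exponent

    def derivative(self, x: float) -> float:
        _check_unit(x, "allocation")
        if x == 0.0:
            if self.exponent < 1.0:
                raise DomainError("power-gain derivative is unbounded at 0")
            return self.scale
        return self.scale * self.exponent * x ** (self.exponent - 1.0)

    def second_derivative(self, x: float) -> float:
        _check_unit(x, "allocation")
        if x == 0.0:
            if self.exponent < 1.0:
                raise DomainError("power-gain curvature is unbounded at 0")
            return 0.0
        e = self.exponent
        return self.scale * e * (e - 1.0) * x ** (e - 2.0)


@dataclass(frozen=True)
class LinearSelfedFraction:
    """Selfed-adult fraction S(s) = gamma * s, gamma in (0, 1)."""

    gamma: float

    def __call__(self, s: float) -> float:
        _check_unit(s, "s")
        return self.gamma * s

    def derivative(self, s: float) -> float:
        _check_unit(s, "s")
        return self.gamma

    def second_derivative(self, s: float) -> float:
        _check_unit(s, "s")
        return 0.0


@dataclass(frozen=True)
class FixedValue:
    """A constant curve, for thresholds quoted at fixed Pa and f values."""

    value: float

    def __call__(self, x: float) -> float:
        _check_unit(x, "argument")
        return self.value

    def derivative(self, x: float) -> float:
        _check_unit(x, "argument")
        return 0.0

    def second_derivative(self, x: float) -> float:
        _check_unit(x, "argument")
        return 0.0


@dataclass(frozen=True)
class GainFunctions:
    """The four curves bundled; ``defaults`` builds them from parameters."""

    survival: Curve
    female: Curve
    male: Curve
    selfed_fraction: Curve

    @classmethod
    def defaults(cls, params: LifeHistoryParams) -> "GainFunctions":
        return cls(
            survival=PowerSurvival(scale=params.Pa_max, beta=params.beta),
            female=LinearGain(slope=params.f_max),
            male=PowerGain(scale=params.m_max, exponent=params.eta),
            selfed_fraction=LinearSelfedFraction(gamma=params.gamma),
        )

    def has_default_forms(self) -> bool:
        """True when every curve has the default parametric family."""
        return (
            isinstance(self.survival, PowerSurvival)
            and isinstance(self.female, LinearGain)
            and isinstance(self.male, PowerGain)
            and isinstance(self.selfed_fraction, LinearSelfedFraction)
        )


def adult_survival(E: float, params: LifeHistoryParams) -> float:
    """Adult survivorship Pa(E) under the default curve."""
    return PowerSurvival(scale=params.Pa_max, beta=params.beta)(E)


def female_gain(F: float, params: LifeHistoryParams) -> float:
    """Seed number f(F) under the default linear curve."""
    return LinearGain(slope=params.f_max)(F)


def male_gain(M: float, params: LifeHistoryParams) -> float:
    """Pollen number m(M) under the default power curve."""
    return PowerGain(scale=params.m_max, exponent=params.eta)(M)


def selfed_adult_fraction(s: float, params: LifeHistoryParams) -> float:
    """Fraction of selfed adults S(s) under the default linear curve."""
    return LinearSelfedFraction(gamma=params.gamma)(s)
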