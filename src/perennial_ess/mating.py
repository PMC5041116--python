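"""Evolution of the selfing rate: gradient, threshold and invasibility.

With the allocation (E, r) held at its ESS and the selfing rate s free to
mutate, the selection gradient on a mutant selfing rate s' at mutant =
resident is, under the default (linear) curves,

    dW/ds' = Pj * f(F) * (w_j - 1/2) - Pa(E) * gamma * delta_a
           = Pj * f(F) * (1/2 - delta_j - tau),
    tau    = delta_a * Pa(E) * gamma / (Pj * f(F)).

tau is the selfed-adult mortality rate caused by inbreeding depression; it
shifts the classic selfing threshold from delta_j = 1/2 to 1/2 - tau.  W is
linear in s', so the gradient sign is constant along [0, 1]: a positive
gradient drives the population to complete selfing (the automatic
transmission advantage outweighs inbreeding deaths), a negative one to
complete outcrossing, and at delta_j = 1/2 - tau the selfing rate is
neutral.  Juvenile inbreeding depression below the threshold therefore
favors complete selfing; above it, complete outcrossing.

Nonlinear user-supplied curves can make the gradient change sign along s;
the classifier then reports the interior zero as a singular selfing rate —
an extension beyond the three linear-model regimes, labeled as such.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import brentq

from .errors import ZeroFemaleGainError
from .fitness import total_fitness
from .gains import GainFunctions
from .ess import solve_ess_E, solve_ess_r
from .params import LifeHistoryParams, Strategy

__all__ = [
    "MatingClassification",
    "InvasionGrid",
    "DeltajBoundary",
    "tau",
    "selfing_selection_gradient",
    "classify_mating_ess",
    "find_deltaj_boundary",
    "pairwise_invasibility",
]

#: absolute tolerance for calling the gradient neutral
NEUTRAL_TOL = 1e-9

Regime = Literal[
    "complete_outcrossing", "complete_selfing", "neutral", "interior_singular"
]


@dataclass(frozen=True)
class MatingClassification:
    """Outcome of the selfing-rate ESS analysis."""

    tau: float
    delta_j_boundary: float
    regime: Regime
    gradient_sign: int
    gradient: float
    strategy: Strategy
    singular_s: float | None = None


@dataclass(frozen=True)
class DeltajBoundary:
    """Root of the selfing gradient in delta_j, or the uniform regime."""

    value: float | None
    uniform_regime: Regime | None
    tau_at_boundary: float | None


@dataclass(frozen=True)
class InvasionGrid:
    """Pairwise-invasibility data: sign of invasion fitness over (s, s')."""

    s_resident_axis: np.ndarray
    s_mutant_axis: np.ndarray
    invasion_sign: np.ndarray  # shape (len(mutant), len(resident))
    invasion_value: np.ndarray

    def to_csv(self, path) -> None:
        """Write the sign matrix; first row/column carry the grid values."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["s_mutant\\s_resident"] + [f"{v:.12g}" for v in self.s_resident_axis])
            for i, sm in enumerate(self.s_mutant_axis):
                writer.writerow([f"{sm:.12g}"] + [str(int(v)) for v in self.invasion_sign[i]])

    def plot(self, path) -> None:
        """Optional raster plot of the sign matrix (requires matplotlib)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4.5, 4))
        ax.pcolormesh(
            self.s_resident_axis,
            self.s_mutant_axis,
            self.invasion_sign,
            cmap="RdBu_r",
            vmin=-1,
            vmax=1,
            shading="nearest",
        )
        ax.set_xlabel("resident selfing rate s")
        ax.set_ylabel("mutant selfing rate s'")
        ax.set_title("sign of invasion fitness")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def _ess_strategy(
    params: LifeHistoryParams, s: float, gains: GainFunctions
) -> Strategy:
    """Allocation ESS at selfing rate s, or a fixed probe for constant curves."""
    if gains.has_default_forms():
        return Strategy(E=solve_ess_E(params, s, gains), r=solve_ess_r(params, s), s=s)
    # non-default curves (e.g. fixed-value Pa and f): any strategy probes the
    # constant curves; an interior point keeps finite differences two-sided
    return Strategy(E=0.5, r=0.5, s=s)


def tau(
    params: LifeHistoryParams,
    s: float = 0.0,
    E_eval: float | None = None,
    r_eval: float | None = None,
    gains: GainFunctions | None = None,
) -> float:
    """Selfed-adult mortality-rate threshold term.

    tau = delta_a * Pa(E) * gamma / (Pj * f(F)) with F = E * (1 - r).  By
    default Pa and f are evaluated at the allocation ESS for selfing rate
    ``s``; pass ``E_eval``/``r_eval`` (or fixed-value curves via ``gains``)
    to evaluate at a prescribed strategy instead.
    """
    g = gains if gains is not None else GainFunctions.defaults(params)
    if E_eval is None:
        strategy = _ess_strategy(params, s, g)
    else:
        strategy = Strategy(E=E_eval, r=r_eval if r_eval is not None else 0.0, s=s)
    f_val = g.female(strategy.F)
    if f_val <= 0.0:
        raise ZeroFemaleGainError(
            f"tau needs f(F) > 0; got f({strategy.F}) = {f_val}"
        )
    return params.delta_a * g.survival(strategy.E) * params.gamma / (params.Pj * f_val)


def selfing_selection_gradient(
    resident: Strategy,
    params: LifeHistoryParams,
    gains: GainFunctions | None = None,
    method: Literal["analytic", "numeric"] = "analytic",
    step: float = 1e-6,
) -> float:
    """dW/ds' at mutant = resident, allocation held fixed.

    ``analytic`` evaluates Pj * f(F) * (w_j - 1/2) - Pa(E) * S'(s) * delta_a
    using the curves' derivatives (S'(s) = gamma for the default linear
    uptake).  ``numeric`` differentiates :func:`total_fitness` in the
    mutant's s by central differences, falling back to a second-order
    one-sided stencil at the s = 0 and s = 1 boundaries.
    """
    g = gains if gains is not None else GainFunctions.defaults(params)
    if method == "analytic":
        f_val = g.female(resident.F)
        return params.Pj * f_val * (params.w_j - 0.5) - g.survival(
            resident.E
        ) * g.selfed_fraction.derivative(resident.s) * params.delta_a
    if method != "numeric":
        raise ValueError(f"unknown method {method!r}")

    s = resident.s

    def w(s_mut: float) -> float:
        return total_fitness(resident.model_copy(update={"s": s_mut}), resident, params, g)

    h = step
    if s - h >= 0.0 and s + h <= 1.0:
        return (w(s + h) - w(s - h)) / (2.0 * h)
    if s - h < 0.0:  # one-sided, forward
        return (-3.0 * w(s) + 4.0 * w(s + h) - w(s + 2.0 * h)) / (2.0 * h)
    return (3.0 * w(s) - 4.0 * w(s - h) + w(s - 2.0 * h)) / (2.0 * h)


def classify_mating_ess(
    params: LifeHistoryParams,
    s_resident: float = 0.0,
    gains: GainFunctions | None = None,
    tol: float = NEUTRAL_TOL,
) -> MatingClassification:
    """Classify the selfing-rate ESS: complete selfing, outcrossing or neutral.

    Computes tau at the allocation ESS for ``s_resident``, the boundary
    1/2 - tau, and the selection gradient at the same strategy.  The
    rule-based regime (compare delta_j with 1/2 - tau) and the
    gradient-based regime must agree; a disagreement raises
    :class:`~perennial_ess.errors.InternalConsistencyError`.  For nonlinear
    curves whose gradient changes sign along s, the interior zero is
    located and reported with regime ``interior_singular``.
    """
    from .errors import InternalConsistencyError

    g = gains if gains is not None else GainFunctions.defaults(params)
    strategy = _ess_strategy(params, s_resident, g)
    t = tau(params, s=s_resident, E_eval=strategy.E, r_eval=strategy.r, gains=g)
    boundary = 0.5 - t
    grad = selfing_selection_gradient(strategy, params, g)

    # nonlinear S or f can flip the gradient sign along s
    singular_s = None
    grad0 = selfing_selection_gradient(strategy.model_copy(update={"s": 0.0}), params, g)
    grad1 = selfing_selection_gradient(strategy.model_copy(update={"s": 1.0}), params, g)
    if grad0 * grad1 < -tol**2:
        singular_s = float(
            brentq(
                lambda sv: selfing_selection_gradient(
                    strategy.model_copy(update={"s": sv}), params, g
                ),
                0.0,
                1.0,
                xtol=1e-10,
            )
        )
        return MatingClassification(
            tau=t,
            delta_j_boundary=boundary,
            regime="interior_singular",
            gradient_sign=int(np.sign(grad)),
            gradient=grad,
            strategy=strategy,
            singular_s=singular_s,
        )

    if abs(grad) <= tol:
        grad_regime: Regime = "neutral"
        sign = 0
    elif grad > 0.0:
        grad_regime, sign = "complete_selfing", 1
    else:
        grad_regime, sign = "complete_outcrossing", -1

    # consistency tripwire: both margins measure delta_j distance to boundary
    f_val = g.female(strategy.F)
    rule_margin = boundary - params.delta_j
    grad_margin = grad / (params.Pj * f_val)
    if abs(rule_margin - grad_margin) > 1e-6:
        raise InternalConsistencyError(
            f"rule margin {rule_margin} and gradient margin {grad_margin} disagree"
        )
    return MatingClassification(
        tau=t,
        delta_j_boundary=boundary,
        regime=grad_regime,
        gradient_sign=sign,
        gradient=grad,
        strategy=strategy,
    )


def find_deltaj_boundary(
    params: LifeHistoryParams,
    s_resident: float = 0.0,
    gains: GainFunctions | None = None,
    xtol: float = 1e-8,
) -> DeltajBoundary:
    """Bisect on delta_j for the zero of the selfing selection gradient.

    All parameters except delta_j are held fixed; the allocation ESS is
    re-solved at each probe (at s = 0 it does not depend on delta_j, so tau
    stays constant during the search).  If the gradient has the same sign at
    delta_j = 0 and delta_j = 1 there is no boundary and the uniform regime
    is reported instead; the located boundary equals 1/2 - tau (tau evaluated
    at the boundary's own allocation strategy).
    """
    g = gains if gains is not None else GainFunctions.defaults(params)

    def grad_at(dj: float) -> float:
        p = params.with_updates(delta_j=dj)
        strategy = _ess_strategy(p, s_resident, g)
        return selfing_selection_gradient(strategy, p, g)

    g0, g1 = grad_at(0.0), grad_at(1.0)
    if g0 == 0.0:
        root = 0.0
    elif g1 == 0.0:
        root = 1.0
    elif g0 * g1 > 0.0:
        regime: Regime = "complete_selfing" if g0 > 0.0 else "complete_outcrossing"
        return DeltajBoundary(value=None, uniform_regime=regime, tau_at_boundary=None)
    else:
        root = float(brentq(grad_at, 0.0, 1.0, xtol=xtol))
    p_at = params.with_updates(delta_j=root)
    strategy = _ess_strategy(p_at, s_resident, g)
    t = tau(p_at, s=s_resident, E_eval=strategy.E, r_eval=strategy.r, gains=g)
    return DeltajBoundary(value=root, uniform_regime=None, tau_at_boundary=t)


def pairwise_invasibility(
    params: LifeHistoryParams,
    grid_size: int,
    gains: GainFunctions | None = None,
    strategy: Strategy | None = None,
    sign_tol: float = 1e-12,
) -> InvasionGrid:
    """Sign of invasion fitness over a (resident s, mutant s') grid.

    For each resident selfing rate the allocation is set to its ESS (or to
    ``strategy``'s allocation if given); the mutant differs only in s'.
    Under the default curves W is linear in s', so each column of the plot
    has a uniform sign, consistent with :func:`classify_mating_ess`; the
    diagonal is exactly zero (self-invasion is neutral).
    """
    if grid_size < 2:
        raise ValueError("grid_size must be at least 2")
    g = gains if gains is not None else GainFunctions.defaults(params)
    axis = np.linspace(0.0, 1.0, grid_size)
    signs = np.zeros((grid_size, grid_size), dtype=int)
    values = np.zeros((grid_size, grid_size))
    for j, s_res in enumerate(axis):
        if strategy is None:
            res = _ess_strategy(params, float(s_res), g)
        else:
            res = strategy.model_copy(update={"s": float(s_res)})
        w_res = total_fitness(res, res, params, g)
        for i, s_mut in enumerate(axis):
            mut = res.model_copy(update={"s": float(s_mut)})
            diff = total_fitness(mut, res, params, g) - w_res
            values[i, j] = diff
            if diff > sign_tol:
                signs[i, j] = 1
            elif diff < -sign_tol:
                signs[i, j] = -1
    return InvasionGrid(
        s_resident_axis=axis,
        s_mutant_axis=axis,
        invasion_sign=signs,
        invasion_value=values,
    )
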