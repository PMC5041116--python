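"""ESS conditions and solvers for reproductive and sex allocation.

For a fixed selfing rate s, an interior ESS (E*, r*) makes the mutant
fitness W stationary and maximal at mutant = resident.  Writing
h(s) = 1 + s * (2 * w_j - 1) for the selfing-weighted seed value and
c(s) = 1 - S(s) * delta_a for the selfed-adult survival discount, the
first-order conditions under a linear female gain f(F) = f_max * F and a
power male gain m(M) = m_max * M**eta reduce to

    -Pa'(E*) * c(s) = (Pj * f_max / 2) * h(s)            (reproductive effort)
    r* = eta*(1-s) / (eta*(1-s) + h(s))                  (sex allocation)

The first condition is independent of r and of the male curve; the second is
independent of E, f_max, m_max and delta_a.  Under the default survival curve
Pa(E) = Pa_max * (1 - E)**beta the first has the closed form

    E* = 1 - (Pa_max * beta / K)**(1 / (1 - beta)),
    K  = (Pj * f_max / 2) * h(s) / c(s).

Whether E* increases or decreases with s is decided by the ratio
w_j / (1 - gamma + gamma * w_a) against 1/2 (sign of 2*w_j - 1 + gamma*delta_a).

An independent numerical oracle, :func:`solve_ess_numeric`, finds the ESS by
best-response iteration on the full fitness function and works for arbitrary
gain curves; agreement with the closed forms is the module's central check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import brentq

from .errors import (
    BoundaryGradientError,
    ConvergenceError,
    CurveSupportError,
    UnboundedMarginalError,
)
from .fitness import total_fitness
from .gains import GainFunctions, LinearGain, PowerSurvival
from .params import LifeHistoryParams, Strategy

__all__ = [
    "ESSResult",
    "SecondOrderReport",
    "selection_gradient",
    "marginal_balance_residual",
    "solve_ess_E",
    "solve_ess_r",
    "solve_ess",
    "solve_ess_numeric",
    "check_second_order",
    "classify_dE_ds",
    "sex_allocation_slope",
]

#: default absolute tolerance for solver outputs
SOLVER_TOL = 1e-6
#: relative step for central first differences
FD_STEP = 1e-5
#: relative step for second differences
FD_STEP2 = 1e-4


@dataclass(frozen=True)
class ESSResult:
    """A solved ESS allocation with diagnostics."""

    E_star: float
    r_star: float
    gradient_at_ess: tuple[float, float] | None
    second_order_ok: bool
    boundary: bool
    method: Literal["analytic", "numeric"]
    iterations: int = 0


@dataclass(frozen=True)
class SecondOrderReport:
    """Finite-difference Hessian of W in (M', F') and its definiteness."""

    hessian: np.ndarray
    negative_definite: bool
    indeterminate: bool


def _h(params: LifeHistoryParams, s: float) -> float:
    """Selfing-weighted seed value h(s) = 1 + s*(2*w_j - 1)."""
    return 1.0 + s * (2.0 * params.w_j - 1.0)


def _require_interior(resident: Strategy) -> None:
    if not (0.0 < resident.E < 1.0 and 0.0 < resident.r < 1.0):
        raise BoundaryGradientError(
            f"resident (E={resident.E}, r={resident.r}) is not interior; "
            "two-sided gradients are undefined on the boundary"
        )


def _gradient_MF(
    resident: Strategy, params: LifeHistoryParams, gains: GainFunctions
) -> tuple[float, float]:
    """(dW/dM', dW/dF') at mutant = resident, from curve derivatives."""
    E, s = resident.E, resident.s
    M, F = resident.M, resident.F
    c = 1.0 - gains.selfed_fraction(s) * params.delta_a
    dPa = gains.survival.derivative(E)
    seed_coeff = params.Pj * (s * params.w_j + 0.5 * (1.0 - s))
    dW_dF = dPa * c + seed_coeff * gains.female.derivative(F)
    pool = (1.0 - s) * gains.female(F)
    if pool > 0.0:
        dW_dM = dPa * c + 0.5 * params.Pj * pool * gains.male.derivative(M) / gains.male(M)
    else:
        dW_dM = dPa * c
    return dW_dM, dW_dF


def selection_gradient(
    resident: Strategy,
    params: LifeHistoryParams,
    gains: GainFunctions | None = None,
    method: Literal["analytic", "numeric"] = "analytic",
    step: float = FD_STEP,
) -> tuple[float, float]:
    """Selection gradient (dW/dE', dW/dr') at mutant = resident.

    ``analytic`` uses the curves' own derivatives and the chain rule from the
    (M', F') gradient: dW/dE' = r*dW/dM' + (1-r)*dW/dF' and
    dW/dr' = E*(dW/dM' - dW/dF').  ``numeric`` uses central finite
    differences on :func:`total_fitness` with step ``step * max(1, |x|)``.
    The two routes agree to ~1e-6 for smooth curves; that agreement is a
    standing regression check.

    Raises
    ------
    BoundaryGradientError
        If the resident is on the boundary of the allocation simplex
        (one-sided differences are never silently substituted).
    """
    _require_interior(resident)
    g = gains if gains is not None else GainFunctions.defaults(params)
    if method == "analytic":
        dW_dM, dW_dF = _gradient_MF(resident, params, g)
        dW_dE = resident.r * dW_dM + (1.0 - resident.r) * dW_dF
        dW_dr = resident.E * (dW_dM - dW_dF)
        return dW_dE, dW_dr
    if method != "numeric":
        raise ValueError(f"unknown method {method!r}")

    out = []
    for attr in ("E", "r"):
        x = getattr(resident, attr)
        h = step * max(1.0, abs(x))
        if x - h < 0.0 or x + h > 1.0:
            raise BoundaryGradientError(
                f"resident {attr}={x} too close to the boundary for step {h}"
            )
        lo = resident.model_copy(update={attr: x - h})
        hi = resident.model_copy(update={attr: x + h})
        w_lo = total_fitness(lo, resident, params, g)
        w_hi = total_fitness(hi, resident, params, g)
        out.append((w_hi - w_lo) / (2.0 * h))
    return out[0], out[1]


def marginal_balance_residual(
    resident: Strategy,
    params: LifeHistoryParams,
    gains: GainFunctions | None = None,
) -> float:
    """Marginal male-fitness gain minus marginal female-fitness gain.

    The equal-marginal-advantage condition for the ESS sex allocation: moving
    one unit of reproductive resource from seeds to pollen changes W by
    dW/dM' - dW/dF' (the survival terms cancel); the residual is zero at r*,
    negative when male function is overinvested.
    """
    _require_interior(resident)
    g = gains if gains is not None else GainFunctions.defaults(params)
    if resident.M == 0.0:
        raise UnboundedMarginalError("male marginal gain is unbounded at M = 0")
    dW_dM, dW_dF = _gradient_MF(resident, params, g)
    return dW_dM - dW_dF


def _require_linear_female(gains: GainFunctions) -> LinearGain:
    if not isinstance(gains.female, LinearGain):
        raise CurveSupportError(
            "the reproductive-effort solver requires a linear female gain"
        )
    return gains.female


def solve_ess_E(
    params: LifeHistoryParams,
    s: float,
    gains: GainFunctions | None = None,
) -> float:
    """ESS reproductive allocation E* at selfing rate s (linear female gain).

    Solves -Pa'(E) * c(s) = (Pj * f_max / 2) * h(s); closed form under the
    default survival curve, Brent root-finding for any other strictly
    decreasing concave survival curve.  Roots outside [0, 1] are clipped to
    the boundary (see :func:`solve_ess` for the boundary flag).  The result
    does not depend on r, m_max or the male curve.
    """
    E, _ = _solve_ess_E_detail(params, s, gains)
    return E


def _solve_ess_E_detail(
    params: LifeHistoryParams,
    s: float,
    gains: GainFunctions | None = None,
) -> tuple[float, bool]:
    g = gains if gains is not None else GainFunctions.defaults(params)
    female = _require_linear_female(g)
    c = 1.0 - g.selfed_fraction(s) * params.delta_a
    K = 0.5 * params.Pj * female.slope * _h(params, s) / c
    if isinstance(g.survival, PowerSurvival):
        scale, beta = g.survival.scale, g.survival.beta
        root = 1.0 - (scale * beta / K) ** (1.0 / (1.0 - beta))
        if root <= 0.0:
            return 0.0, True
        return root, False  # root < 1 always since (scale*beta/K)**x > 0

    # general route: -Pa'(E)*c - (Pj*f_max/2)*h(s) with the survival curve's
    # own derivative; bracket shrunk away from the possibly singular edge
    def residual(E: float) -> float:
        return -g.survival.derivative(E) * c - 0.5 * params.Pj * female.slope * _h(params, s)

    lo, hi = 0.0, 1.0 - 1e-12
    r_lo, r_hi = residual(lo), residual(hi)
    if r_lo >= 0.0:
        return 0.0, True
    if r_hi <= 0.0:
        return 1.0, True
    return float(brentq(residual, lo, hi, xtol=1e-12)), False


def solve_ess_r(params: LifeHistoryParams, s: float) -> float:
    """ESS sex allocation r* = eta*(1-s) / (eta*(1-s) + h(s)).

    Valid under a linear female gain and power male gain.  Strictly
    decreasing in s (for w_j > 0), invariant to E, f_max, m_max and delta_a,
    and 0 at complete selfing (no outcross siring, no male investment).
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"s must lie in [0, 1], got {s}")
    if s == 1.0:
        return 0.0
    a = params.eta * (1.0 - s)
    return a / (a + _h(params, s))


def sex_allocation_slope(params: LifeHistoryParams, s: float) -> float:
    """d r*/d s in closed form: -2 * eta * w_j / (eta*(1-s) + h(s))**2.

    Strictly negative whenever w_j > 0; zero only in the degenerate case of
    complete juvenile inbreeding depression (w_j = 0).
    """
    if not 0.0 <= s < 1.0:
        raise ValueError(f"s must lie in [0, 1), got {s}")
    denom = params.eta * (1.0 - s) + _h(params, s)
    return -2.0 * params.eta * params.w_j / denom**2


def solve_ess(
    params: LifeHistoryParams,
    s: float,
    gains: GainFunctions | None = None,
) -> ESSResult:
    """Closed-form ESS (E*, r*) at selfing rate s with diagnostics."""
    g = gains if gains is not None else GainFunctions.defaults(params)
    E_star, clipped = _solve_ess_E_detail(params, s, g)
    r_star = solve_ess_r(params, s)
    boundary = clipped or not (0.0 < E_star < 1.0 and 0.0 < r_star < 1.0)
    if boundary:
        grad = None
        so_ok = False
    else:
        strategy = Strategy(E=E_star, r=r_star, s=s)
        grad = selection_gradient(strategy, params, g, method="analytic")
        so_ok = check_second_order(strategy, params, g).negative_definite
    return ESSResult(
        E_star=E_star,
        r_star=r_star,
        gradient_at_ess=grad,
        second_order_ok=so_ok,
        boundary=boundary,
        method="analytic",
    )


_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0


def _golden_max(f, lo: float, hi: float, xatol: float) -> float:
    """Golden-section maximizer of a unimodal f on [lo, hi]."""
    a, b = lo, hi
    h = b - a
    c = b - _INVPHI * h
    d = a + _INVPHI * h
    fc, fd = f(c), f(d)
    while h > xatol:
        if fc > fd:
            b, d, fd = d, c, fc
            h = b - a
            c = b - _INVPHI * h
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            h = b - a
            d = a + _INVPHI * h
            fd = f(d)
    return 0.5 * (a + b)


def _siring_value(
    resident: Strategy, params: LifeHistoryParams, gains: GainFunctions
) -> float:
    """Fitness credited per unit of the mutant's relative pollen output.

    B = (1/2) * Pj * (1 - s) * f(F) / m(M): the resident population's pool
    of outcrossed ovules divided by the resident pollen output.  For a fixed
    selfing rate the resident enters the best-response problem only through
    this scalar.
    """
    pool = (1.0 - resident.s) * gains.female(resident.F)
    if pool <= 0.0:
        return 0.0
    m_res = gains.male(resident.M)
    if m_res <= 0.0:
        return math.inf
    return 0.5 * params.Pj * pool / m_res


def _best_response_given_B(
    B: float,
    s: float,
    params: LifeHistoryParams,
    gains: GainFunctions,
    xatol: float,
) -> tuple[float, float]:
    """Mutant (E', r') maximizing W for a given siring value B.

    W(E', r') = Pa(E')*c + A*f(E'*(1-r')) + B*m(E'*r') with
    c = 1 - S(s)*delta_a and A = Pj*(s*w_j + (1-s)/2); nested golden-section
    maximization, r' inner and E' outer.
    """
    c = 1.0 - gains.selfed_fraction(s) * params.delta_a
    A = params.Pj * (s * params.w_j + 0.5 * (1.0 - s))
    survival, female, male = gains.survival, gains.female, gains.male

    def best_r(E: float) -> float:
        if E == 0.0 or B == 0.0:
            return 0.0
        return _golden_max(
            lambda r: A * female(E * (1.0 - r)) + B * male(E * r), 0.0, 1.0, xatol
        )

    def w_of_E(E: float) -> float:
        r = best_r(E)
        return survival(E) * c + A * female(E * (1.0 - r)) + B * male(E * r)

    E_opt = _golden_max(w_of_E, 0.0, 1.0, xatol)
    return E_opt, best_r(E_opt)


def _best_response(
    resident: Strategy,
    params: LifeHistoryParams,
    gains: GainFunctions,
    xatol: float = 1e-12,
) -> tuple[float, float]:
    """Mutant (E', r') maximizing total fitness against a fixed resident."""
    B = _siring_value(resident, params, gains)
    if math.isinf(B):
        raise ConvergenceError(
            "resident produces no pollen while outcrossed ovules exist; "
            "the best response is unbounded in relative siring share"
        )
    return _best_response_given_B(B, resident.s, params, gains, xatol)


def solve_ess_numeric(
    params: LifeHistoryParams,
    s: float,
    gains: GainFunctions | None = None,
    tol: float = 1e-6,
    xatol: float = 1e-12,
    max_expand: int = 200,
) -> ESSResult:
    """Numeric ESS oracle: fixed point of the best-response map.

    Independent of the closed forms: mutant best responses come from nested
    golden-section maximization of the full mutant fitness on [0, 1]^2, and
    the ESS is the resident the best response maps to itself.  Because the
    resident enters the best-response problem only through the scalar siring
    value B (the outcrossed-ovule pool per unit resident pollen), the fixed
    point is located as the unique root of the strictly decreasing map
    B -> B_implied(best_response(B)) - B by Brent bracketing — undamped
    best-response cycling never arises.  Deterministic; no randomness.

    The returned resident is verified to move less than ``tol`` under one
    further best-response step; a violation raises
    :class:`~perennial_ess.errors.ConvergenceError`.  ``tol`` is the
    solver's advertised accuracy: the best-response map amplifies the
    golden-section resolution ``xatol`` by its (steep) Jacobian, so the
    verification residual sits orders of magnitude above ``xatol`` even at a
    machine-accurate fixed point.  Requires a strictly
    concave male gain (the best response in r' is flat when the male curve
    is linear, a degenerate case with no isolated fixed point).
    """
    g = gains if gains is not None else GainFunctions.defaults(params)
    evals = 0

    if s >= 1.0:
        # no outcross pollen pool: the best response ignores male function
        E, r = _best_response_given_B(0.0, s, params, g, xatol)
    else:

        def implied_excess(B: float) -> float:
            nonlocal evals
            evals += 1
            E_b, r_b = _best_response_given_B(B, s, params, g, xatol)
            pool = (1.0 - s) * g.female(E_b * (1.0 - r_b))
            m_b = g.male(E_b * r_b)
            if m_b <= 0.0:
                return 1.0 if pool > 0.0 else -B
            return 0.5 * params.Pj * pool / m_b - B

        lo, hi = 1e-12, 1.0
        expansions = 0
        while implied_excess(hi) > 0.0:
            hi *= 4.0
            expansions += 1
            if expansions > max_expand:
                raise ConvergenceError(
                    "could not bracket the best-response fixed point in B"
                )
        if implied_excess(lo) <= 0.0:
            B_star = 0.0
        else:
            B_star = float(brentq(implied_excess, lo, hi, xtol=1e-30, rtol=8.9e-16))
        E, r = _best_response_given_B(B_star, s, params, g, xatol)

    # fixed-point verification: one explicit best-response step
    resident = Strategy(E=E, r=r, s=s)
    E_br, r_br = _best_response(resident, params, g, xatol)
    residual = max(abs(E_br - E), abs(r_br - r))
    if residual >= tol:
        raise ConvergenceError(
            f"best-response fixed point not attained: residual {residual}",
            trajectory=[(E, r), (E_br, r_br)],
        )
    iteration = evals
    edge_tol = 10.0 * max(tol, xatol)
    boundary = (
        E < edge_tol or E > 1.0 - edge_tol or r < edge_tol or r > 1.0 - edge_tol
    )
    if boundary:
        grad = None
        so_ok = False
    else:
        strategy = Strategy(E=E, r=r, s=s)
        grad = selection_gradient(strategy, params, g, method="numeric")
        so_ok = check_second_order(strategy, params, g).negative_definite
    return ESSResult(
        E_star=E,
        r_star=r,
        gradient_at_ess=grad,
        second_order_ok=so_ok,
        boundary=boundary,
        method="numeric",
        iterations=iteration,
    )


def check_second_order(
    resident: Strategy,
    params: LifeHistoryParams,
    gains: GainFunctions | None = None,
    step: float = FD_STEP2,
    singular_tol: float = 1e-6,
) -> SecondOrderReport:
    """Second-derivative (maximality) conditions at mutant = resident.

    Builds the 2x2 Hessian of W with respect to the mutant's (M', F') by
    central finite differences and tests negative definiteness via the
    leading minors (H11 < 0 and det H > 0).  A Hessian whose minors fall
    within ``singular_tol`` of zero is flagged indeterminate rather than
    rejected — linear gain curves produce exactly this semidefinite
    degeneracy.  The check is pointwise: it does not require the first-order
    conditions to hold.
    """
    _require_interior(resident)
    g = gains if gains is not None else GainFunctions.defaults(params)
    M0, F0, s = resident.M, resident.F, resident.s
    h = step * max(1.0, abs(M0), abs(F0))

    def w(M: float, F: float) -> float:
        return total_fitness(Strategy.from_MF(M, F, s), resident, params, g)

    w0 = w(M0, F0)
    H = np.empty((2, 2))
    H[0, 0] = (w(M0 + h, F0) - 2.0 * w0 + w(M0 - h, F0)) / h**2
    H[1, 1] = (w(M0, F0 + h) - 2.0 * w0 + w(M0, F0 - h)) / h**2
    H[0, 1] = H[1, 0] = (
        w(M0 + h, F0 + h)
        - w(M0 + h, F0 - h)
        - w(M0 - h, F0 + h)
        + w(M0 - h, F0 - h)
    ) / (4.0 * h**2)
    det = float(np.linalg.det(H))
    neg_def = H[0, 0] < -singular_tol and det > singular_tol
    indeterminate = not neg_def and (
        abs(H[0, 0]) <= singular_tol or abs(det) <= singular_tol
    )
    return SecondOrderReport(
        hessian=H, negative_definite=bool(neg_def), indeterminate=bool(indeterminate)
    )


def classify_dE_ds(
    params: LifeHistoryParams, tol: float = 1e-9
) -> Literal["increasing", "decreasing", "independent"]:
    """How the ESS reproductive allocation responds to the selfing rate.

    Computes the ratio w_j / (1 - gamma + gamma * w_a) and compares it with
    1/2: E* increases with s when the ratio exceeds 1/2, decreases below it,
    and is independent of s exactly at 1/2 (ties resolved within ``tol`` on
    the ratio).  With delta_a = 0 this reduces to the sign of 1/2 - delta_j.
    """
    ratio = params.w_j / (1.0 - params.gamma + params.gamma * params.w_a)
    if ratio > 0.5 + tol:
        return "increasing"
    if ratio < 0.5 - tol:
        return "decreasing"
    return "independent"
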