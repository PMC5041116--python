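"""ESS solvers: closed forms, gradients, the numeric oracle, second order."""

import numpy as np
import pytest
from scipy.optimize import brentq

from perennial_ess import (
    BoundaryGradientError,
    GainFunctions,
    LifeHistoryParams,
    Strategy,
    check_second_order,
    classify_dE_ds,
    marginal_balance_residual,
    selection_gradient,
    sex_allocation_slope,
    solve_ess,
    solve_ess_E,
    solve_ess_numeric,
    solve_ess_r,
)
from perennial_ess.gains import PowerSurvival

from conftest import sample_interior_cases, sample_valid_params


class OpaqueSurvival:
    """Wraps the default survival curve without its type, forcing solvers
    onto their curve-agnostic numerical route."""

    def __init__(self, scale, beta):
        self._inner = PowerSurvival(scale=scale, beta=beta)

    def __call__(self, E):
        return self._inner(E)

    def derivative(self, E):
        return self._inner.derivative(E)

    def second_derivative(self, E):
        return self._inner.second_derivative(E)


def opaque_gains(params):
    g = GainFunctions.defaults(params)
    return GainFunctions(
        survival=OpaqueSurvival(params.Pa_max, params.beta),
        female=g.female,
        male=g.male,
        selfed_fraction=g.selfed_fraction,
    )


# ---------------------------------------------------------------- closed forms


def test_ess_reproductive_allocation_closed_form(default_params):
    assert solve_ess_E(default_params, 0.5) == pytest.approx(0.902944, abs=1e-6)


def test_ess_E_outcrossing_limit_ignores_inbreeding(default_params):
    """At s = 0 the effort condition contains no delta_j, delta_a or gamma."""
    base = solve_ess_E(default_params, 0.0)
    for updates in (
        dict(delta_j=0.9),
        dict(delta_a=0.9),
        dict(gamma=0.1),
        dict(delta_j=0.0, delta_a=0.0),
    ):
        assert solve_ess_E(default_params.with_updates(**updates), 0.0) == base


def test_ess_E_independent_of_s_at_critical_ratio(default_params):
    """w_j = 1/2 with delta_a = 0 puts the ratio exactly at 1/2."""
    p = default_params.with_updates(delta_j=0.5, delta_a=0.0)
    values = [solve_ess_E(p, s) for s in (0.0, 0.5, 1.0)]
    assert max(values) - min(values) == pytest.approx(0.0, abs=1e-12)


def test_ess_E_general_route_matches_closed_form(default_params):
    """Brent root on the effort condition (opaque curve) vs closed form."""
    for s in (0.0, 0.3, 0.8):
        assert solve_ess_E(default_params, s, gains=opaque_gains(default_params)) == (
            pytest.approx(solve_ess_E(default_params, s), abs=1e-9)
        )


@pytest.mark.parametrize(
    "updates,s,expected",
    [
        (dict(), 1.0, 0.0),  # complete selfing: no outcross siring
        (dict(eta=1.0, delta_j=0.2), 0.0, 0.5),  # symmetric outcrossing limit
        (dict(eta=0.8, delta_j=0.2), 0.5, 0.235294),  # 0.4/1.7
    ],
)
def test_ess_sex_allocation_closed_form(default_params, updates, s, expected):
    p = default_params.with_updates(**updates)
    assert solve_ess_r(p, s) == pytest.approx(expected, abs=1e-6)


def test_sex_allocation_strictly_decreasing_in_s(default_params):
    grid = np.linspace(0.0, 1.0, 21)
    values = [solve_ess_r(default_params, float(s)) for s in grid]
    assert all(a > b for a, b in zip(values, values[1:]))


# ------------------------------------------------------------------- gradients


def test_gradient_vanishes_at_analytic_ess(default_params):
    for s in (0.0, 0.5, 0.9):
        strat = Strategy(
            E=solve_ess_E(default_params, s), r=solve_ess_r(default_params, s), s=s
        )
        dE, dr = selection_gradient(strat, default_params)
        assert abs(dE) < 1e-9
        assert abs(dr) < 1e-9


def test_gradient_two_routes_agree_on_random_strategies():
    """Closed-form (curve-derivative) vs finite-difference gradients."""
    rng = np.random.default_rng(42)
    worst = 0.0
    for _ in range(100):
        params = sample_valid_params(rng)
        strat = Strategy(
            E=float(rng.uniform(0.1, 0.9)),
            r=float(rng.uniform(0.1, 0.9)),
            s=float(rng.uniform(0.0, 1.0)),
        )
        g_an = selection_gradient(strat, params, method="analytic")
        g_fd = selection_gradient(strat, params, method="numeric")
        worst = max(worst, abs(g_an[0] - g_fd[0]), abs(g_an[1] - g_fd[1]))
    assert worst < 1e-6


def test_gradient_selfing_factor_invariance(default_params):
    """With delta_a = 0 and w_j = 1/2 the effort gradient is s-independent."""
    p = default_params.with_updates(delta_a=0.0, delta_j=0.5)
    strat0 = Strategy(E=0.6, r=solve_ess_r(p, 0.0), s=0.0)
    # compare dW/dE at the sex-allocation balance for each s
    strat1 = Strategy(E=0.6, r=solve_ess_r(p, 1.0), s=1.0)
    dE0, _ = selection_gradient(strat0, p)
    # at s = 1 the resident pollen pool is empty; r* = 0 is a boundary, so
    # evaluate just inside
    strat1 = Strategy(E=0.6, r=1e-6, s=1.0)
    dE1, _ = selection_gradient(strat1, p)
    assert dE0 == pytest.approx(dE1, abs=1e-4)


def test_gradient_requires_interior_resident(default_params):
    with pytest.raises(BoundaryGradientError):
        selection_gradient(Strategy(E=0.0, r=0.0, s=0.5), default_params)
    with pytest.raises(BoundaryGradientError):
        selection_gradient(Strategy(E=0.5, r=1.0, s=0.5), default_params)


# ------------------------------------------------------------ marginal balance


def test_marginal_balance_zero_at_ess_and_signed_off_it(default_params):
    s = 0.5
    r_star = solve_ess_r(default_params, s)
    E = 0.6
    at_ess = marginal_balance_residual(Strategy(E=E, r=r_star, s=s), default_params)
    assert abs(at_ess) < 1e-9
    above = marginal_balance_residual(
        Strategy(E=E, r=min(r_star + 0.2, 0.95), s=s), default_params
    )
    below = marginal_balance_residual(
        Strategy(E=E, r=max(r_star - 0.1, 0.05), s=s), default_params
    )
    assert above < 0.0  # male overinvested
    assert below > 0.0


def test_marginal_balance_ignores_adult_inbreeding(default_params):
    """Sex-allocation balance has no delta_a in it."""
    strat = Strategy(E=0.6, r=0.3, s=0.5)
    r0 = marginal_balance_residual(strat, default_params.with_updates(delta_a=0.0))
    r1 = marginal_balance_residual(strat, default_params.with_updates(delta_a=1.0))
    assert r0 == r1


# ------------------------------------------------------------- numeric oracle


def test_numeric_oracle_matches_closed_forms_on_sampled_sets():
    for params, s in sample_interior_cases(10, seed=7):
        res = solve_ess_numeric(params, s)
        assert res.E_star == pytest.approx(solve_ess_E(params, s), abs=1e-6)
        assert res.r_star == pytest.approx(solve_ess_r(params, s), abs=1e-6)
        assert res.method == "numeric"


def test_numeric_oracle_flags_boundary_when_reproduction_worthless(default_params):
    res = solve_ess_numeric(default_params.with_updates(f_max=1e-6), 0.5)
    assert res.boundary
    assert res.E_star == pytest.approx(0.0, abs=1e-6)


def test_numeric_oracle_complete_selfing(default_params):
    res = solve_ess_numeric(default_params, 1.0)
    assert res.E_star == pytest.approx(solve_ess_E(default_params, 1.0), abs=1e-6)
    assert res.r_star == 0.0


# --------------------------------------------------------------- second order


def test_second_order_negative_definite_at_interior_ess(default_params):
    for s in (0.0, 0.5):
        strat = Strategy(
            E=solve_ess_E(default_params, s), r=solve_ess_r(default_params, s), s=s
        )
        report = check_second_order(strat, default_params)
        assert report.negative_definite
        assert not report.indeterminate


def test_second_order_check_is_pointwise(default_params):
    """Away from the ESS the first-order conditions fail but the Hessian
    still computes."""
    strat = Strategy(E=0.3, r=0.5, s=0.5)  # E far below E* = 0.90
    dE, _ = selection_gradient(strat, default_params)
    assert abs(dE) > 1e-3
    report = check_second_order(strat, default_params)
    assert report.hessian.shape == (2, 2)


def test_second_order_linear_gains_flagged_indeterminate(default_params):
    """eta = 1 with a linear female curve gives a rank-one Hessian."""
    p = default_params.with_updates(eta=1.0)
    strat = Strategy(E=0.6, r=0.4, s=0.3)
    report = check_second_order(strat, p)
    assert not report.negative_definite
    assert report.indeterminate


# --------------------------------------------------- effort-vs-selfing regimes


@pytest.mark.parametrize(
    "updates,expected",
    [
        (dict(delta_j=0.2, delta_a=0.4, gamma=0.5), "increasing"),  # ratio 8/9
        (dict(delta_j=0.5, delta_a=0.0), "independent"),  # ratio exactly 1/2
        (dict(delta_j=0.7, delta_a=0.4, gamma=0.5), "decreasing"),  # ratio 1/3
        (dict(delta_j=0.3, delta_a=0.0), "increasing"),  # w_a = 1, delta_j < 1/2
        (dict(delta_j=0.6, delta_a=0.0), "decreasing"),  # w_a = 1, delta_j > 1/2
    ],
)
def test_classify_dE_ds_rule(default_params, updates, expected):
    assert classify_dE_ds(default_params.with_updates(**updates)) == expected


def test_classify_dE_ds_agrees_with_solved_allocations():
    """The label must match the measured sign of E*(0.9) - E*(0.1)."""
    rng = np.random.default_rng(3)
    for _ in range(25):
        params = sample_valid_params(rng)
        label = classify_dE_ds(params)
        diff = solve_ess_E(params, 0.9) - solve_ess_E(params, 0.1)
        if label == "increasing":
            assert diff > 0.0
        elif label == "decreasing":
            assert diff < 0.0
        else:
            assert abs(diff) < 1e-9


# ------------------------------------------------------- sex-allocation slope


def test_sex_allocation_slope_matches_central_difference(default_params):
    h = 1e-6
    s = 0.3
    fd = (solve_ess_r(default_params, s + h) - solve_ess_r(default_params, s - h)) / (
        2.0 * h
    )
    assert sex_allocation_slope(default_params, s) == pytest.approx(fd, abs=1e-6)


def test_sex_allocation_slope_negative_except_degenerate(default_params):
    rng = np.random.default_rng(11)
    for _ in range(200):
        params = sample_valid_params(rng)
        s = float(rng.uniform(0.0, 0.95))
        assert sex_allocation_slope(params, s) < 0.0
    # w_j = 0: r* = eta(1-s)/((eta+1)(1-s)) is constant, slope exactly 0
    degenerate = default_params.with_updates(delta_j=1.0)
    assert sex_allocation_slope(degenerate, 0.3) == 0.0


# --------------------------------------------------------------- ESSResult API


def test_solve_ess_reports_interior_diagnostics(default_params):
    res = solve_ess(default_params, 0.5)
    assert not res.boundary
    assert res.second_order_ok
    assert res.method == "analytic"
    assert max(abs(g) for g in res.gradient_at_ess) < 1e-9
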