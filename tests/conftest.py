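"""Shared fixtures and deterministic parameter sampling."""

from __future__ import annotations

import numpy as np
import pytest

from perennial_ess import LifeHistoryParams, solve_ess_E


@pytest.fixture
def default_params() -> LifeHistoryParams:
    """The package's running example parameter set."""
    return LifeHistoryParams()


def sample_valid_params(rng: np.random.Generator) -> LifeHistoryParams:
    """One random parameter set from the sampling ranges used throughout.

    eta stays strictly below 1 (the linear-male degeneracy has no isolated
    sex-allocation optimum) and delta_j below 1 so that selfed seeds retain
    some value.
    """
    return LifeHistoryParams(
        Pj=rng.uniform(0.1, 1.0),
        delta_j=rng.uniform(0.0, 0.95),
        delta_a=rng.uniform(0.0, 1.0),
        gamma=rng.uniform(0.05, 0.95),
        f_max=rng.uniform(2.0, 50.0),
        m_max=rng.uniform(1.0, 200.0),
        eta=rng.uniform(0.3, 0.95),
        Pa_max=rng.uniform(0.3, 1.0),
        beta=rng.uniform(0.2, 0.8),
    )


def sample_interior_cases(
    n: int, seed: int
) -> list[tuple[LifeHistoryParams, float]]:
    """n (params, s) pairs whose allocation ESS is safely interior."""
    rng = np.random.default_rng(seed)
    cases: list[tuple[LifeHistoryParams, float]] = []
    while len(cases) < n:
        params = sample_valid_params(rng)
        s = float(rng.uniform(0.05, 0.9))
        E_star = solve_ess_E(params, s)
        if 0.02 < E_star < 0.98:
            cases.append((params, s))
    return cases
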