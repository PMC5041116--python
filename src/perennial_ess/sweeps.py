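"""Parameter sweeps and bundled scenarios.

Sweeps trace the qualitative regimes of the model: how the ESS reproductive
allocation E* responds to the selfing rate (increasing, decreasing or flat
depending on the ratio w_j / (1 - gamma + gamma*w_a) versus 1/2), the
universal decline of the ESS sex allocation r* with the selfing rate, and
the phase diagram of mating regimes over (delta_j, tau).  No quantitative
curve from any particular published figure is targeted — only the signs,
monotonicities and boundaries the model implies; the bundled scenarios are
chosen to sit clearly inside each regime.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .ess import classify_dE_ds, solve_ess_E, solve_ess_r
from .gains import FixedValue, GainFunctions, LinearSelfedFraction, PowerGain
from .mating import classify_mating_ess
from .params import LifeHistoryParams

__all__ = [
    "SweepResult",
    "Scenario",
    "SCENARIOS",
    "FIG_R_VS_S_WJ_VALUES",
    "sweep_E_vs_s",
    "sweep_r_vs_s",
    "phase_diagram",
]

FLOAT_FMT = "{:.12g}"


@dataclass(frozen=True)
class SweepResult:
    """ESS allocations and regime labels along one swept parameter."""

    axis_name: str
    axis_values: np.ndarray
    E_star_values: np.ndarray
    r_star_values: np.ndarray
    regime_labels: tuple[str, ...]
    params_snapshot: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                self.axis_name: self.axis_values,
                "E_star": self.E_star_values,
                "r_star": self.r_star_values,
                "regime": list(self.regime_labels),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        """Deterministic CSV: header row, floats at 12 significant digits."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow([self.axis_name, "E_star", "r_star", "regime"])
            for x, e, r, lab in zip(
                self.axis_values, self.E_star_values, self.r_star_values, self.regime_labels
            ):
                writer.writerow(
                    [FLOAT_FMT.format(x), FLOAT_FMT.format(e), FLOAT_FMT.format(r), lab]
                )

    def snapshot_json(self) -> str:
        return json.dumps(self.params_snapshot, sort_keys=True, indent=2)


@dataclass(frozen=True)
class Scenario:
    """A named, documented parameter set bundled with the package."""

    name: str
    params: LifeHistoryParams
    description: str


#: w_j family traced by the sex-allocation-vs-selfing sweep
FIG_R_VS_S_WJ_VALUES: tuple[float, ...] = (0.3, 0.6, 0.9)

SCENARIOS: tuple[Scenario, ...] = (
    Scenario(
        name="effort_increasing",
        params=LifeHistoryParams(delta_j=0.2, delta_a=0.4, gamma=0.5),
        description=(
            "w_j/(1-gamma+gamma*w_a) = 0.8/0.9 > 1/2: ESS reproductive "
            "allocation increases with the selfing rate."
        ),
    ),
    Scenario(
        name="effort_decreasing",
        params=LifeHistoryParams(delta_j=0.7, delta_a=0.4, gamma=0.5),
        description=(
            "w_j/(1-gamma+gamma*w_a) = 0.3/0.9 < 1/2: ESS reproductive "
            "allocation decreases with the selfing rate."
        ),
    ),
    Scenario(
        name="effort_independent",
        params=LifeHistoryParams(delta_j=0.5, delta_a=0.0, gamma=0.5),
        description=(
            "ratio exactly 1/2 (delta_j = 1/2, delta_a = 0): ESS reproductive "
            "allocation is independent of the selfing rate."
        ),
    ),
    Scenario(
        name="sex_allocation_family",
        params=LifeHistoryParams(delta_j=0.4, delta_a=0.4, gamma=0.5),
        description=(
            "base set for the r*-vs-s family over w_j in "
            f"{FIG_R_VS_S_WJ_VALUES}; every curve declines with s."
        ),
    ),
    Scenario(
        name="mating_complete_selfing",
        params=LifeHistoryParams(delta_j=0.2, delta_a=0.0, gamma=0.5),
        description=(
            "delta_a = 0 so tau = 0 and the boundary sits at delta_j = 1/2; "
            "delta_j = 0.2 below it, selfing gradient positive: complete "
            "selfing is the ESS."
        ),
    ),
    Scenario(
        name="mating_complete_outcrossing",
        params=LifeHistoryParams(delta_j=0.45, delta_a=0.4, gamma=0.5),
        description=(
            "adult inbreeding depression shifts the boundary to 1/2 - tau "
            "(~0.41 at the allocation ESS); delta_j = 0.45 above it: complete "
            "outcrossing is the ESS."
        ),
    ),
)


def get_scenario(name: str) -> Scenario:
    for sc in SCENARIOS:
        if sc.name == name:
            return sc
    raise KeyError(f"unknown scenario {name!r}; known: {[s.name for s in SCENARIOS]}")


def _snapshot(params: LifeHistoryParams) -> dict:
    return params.model_dump()


def sweep_E_vs_s(
    params: LifeHistoryParams, s_grid: Sequence[float] | np.ndarray
) -> SweepResult:
    """ESS allocations along a selfing-rate grid.

    The monotonicity of E* along the grid matches :func:`classify_dE_ds`.
    """
    s_grid = np.asarray(s_grid, dtype=float)
    if s_grid.ndim != 1 or np.any(s_grid < 0.0) or np.any(s_grid > 1.0):
        raise DomainError("s_grid must be a 1-D grid inside [0, 1]")
    label = classify_dE_ds(params)
    E = np.array([solve_ess_E(params, float(s)) for s in s_grid])
    r = np.array([solve_ess_r(params, float(s)) for s in s_grid])
    return SweepResult(
        axis_name="s",
        axis_values=s_grid,
        E_star_values=E,
        r_star_values=r,
        regime_labels=tuple([label] * len(s_grid)),
        params_snapshot=_snapshot(params),
    )


def sweep_r_vs_s(
    params: LifeHistoryParams,
    s_grid: Sequence[float] | np.ndarray,
    w_j_values: Sequence[float] = FIG_R_VS_S_WJ_VALUES,
) -> list[SweepResult]:
    """One r*-vs-s curve per juvenile relative survivorship w_j.

    Every curve is strictly decreasing for w_j > 0 and reaches 0 at s = 1.
    """
    results = []
    for w_j in w_j_values:
        p = params.with_updates(delta_j=1.0 - w_j)
        results.append(sweep_E_vs_s(p, s_grid))
    return results


def phase_diagram(
    params: LifeHistoryParams,
    delta_j_grid: Sequence[float] | np.ndarray,
    tau_grid: Sequence[float] | np.ndarray,
    Pa_value: float = 0.5,
    f_value: float = 5.0,
) -> pd.DataFrame:
    """Mating-regime table over (delta_j, tau).

    Each tau is realized by fixed-value survival and female curves (Pa and f
    held at ``Pa_value`` and ``f_value``) with the adult inbreeding
    depression back-solved from tau = delta_a * Pa * gamma / (Pj * f);
    the regime in each cell comes from the gradient-based classifier, so
    boundary cells straddle delta_j = 1/2 - tau by construction.

    Returns a DataFrame with delta_j as the index and tau as the columns.
    """
    delta_j_grid = np.asarray(delta_j_grid, dtype=float)
    tau_grid = np.asarray(tau_grid, dtype=float)
    table = {}
    for t in tau_grid:
        delta_a = t * params.Pj * f_value / (Pa_value * params.gamma)
        if delta_a > 1.0:
            raise DomainError(
                f"tau = {t} needs delta_a = {delta_a} > 1 at Pa = {Pa_value}, f = {f_value}"
            )
        p = params.with_updates(delta_a=delta_a)
        gains = GainFunctions(
            survival=FixedValue(Pa_value),
            female=FixedValue(f_value),
            male=PowerGain(scale=p.m_max, exponent=p.eta),
            selfed_fraction=LinearSelfedFraction(gamma=p.gamma),
        )
        column = []
        for dj in delta_j_grid:
            cls = classify_mating_ess(p.with_updates(delta_j=float(dj)), gains=gains)
            column.append(cls.regime)
        table[float(t)] = column
    frame = pd.DataFrame(table, index=[float(d) for d in delta_j_grid])
    frame.index.name = "delta_j"
    frame.columns.name = "tau"
    return frame


def plot_sweep(result: SweepResult, path: str | Path) -> None:
    """Line plot of E* and r* along the swept axis (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(result.axis_values, result.E_star_values, label="E*")
    ax.plot(result.axis_values, result.r_star_values, label="r*")
    ax.set_xlabel(result.axis_name)
    ax.set_ylabel("ESS allocation")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
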