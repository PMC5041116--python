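"""Flat key-value configuration files.

Format: one ``key = value`` pair per line, ``#`` starts a comment, blank
lines ignored.  Keys are exactly the :class:`LifeHistoryParams` field names
plus the optional solver settings below; unknown keys are rejected with the
offending names listed.
"""

from __future__ import annotations

from pathlib import Path

from .errors import DomainError
from .params import LifeHistoryParams

__all__ = ["SOLVER_KEYS", "read_config", "params_from_config", "write_config"]

PARAM_KEYS = frozenset(LifeHistoryParams.model_fields)
#: solver knobs accepted alongside parameters
SOLVER_KEYS = frozenset({"solver_tol", "solver_max_iter", "fd_step", "fd_step2"})


def read_config(path: str | Path) -> dict[str, float]:
    """Parse a flat config file into a {key: float} mapping."""
    values: dict[str, float] = {}
    unknown: list[str] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise DomainError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        key = key.strip()
        if key not in PARAM_KEYS and key not in SOLVER_KEYS:
            unknown.append(key)
            continue
        try:
            values[key] = float(value.strip())
        except ValueError as exc:
            raise DomainError(f"{path}:{lineno}: non-numeric value {value.strip()!r}") from exc
    if unknown:
        raise DomainError(f"unknown config keys: {', '.join(sorted(unknown))}")
    return values


def params_from_config(
    config: dict[str, float], overrides: dict[str, float] | None = None
) -> LifeHistoryParams:
    """Build parameters from a config mapping plus optional overrides."""
    merged = {k: v for k, v in config.items() if k in PARAM_KEYS}
    if overrides:
        merged.update({k: v for k, v in overrides.items() if v is not None})
    return LifeHistoryParams(**merged)


def write_config(params: LifeHistoryParams, path: str | Path) -> None:
    """Serialize parameters so that read/params_from_config round-trips."""
    lines = [f"{name} = {getattr(params, name)!r}" for name in LifeHistoryParams.model_fields]
    Path(path).write_text("\n".join(lines) + "\n")
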