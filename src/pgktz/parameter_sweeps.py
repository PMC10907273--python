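"""Dissociation-parameter sweeps: when does terazosin stimulate vs. inhibit?

The stimulatory bypass works because 3-PG leaves E.TZ.PG at rate b- while
it leaves E.PG at the much slower rate c-.  Sweeping c- with b- fixed maps
the transition: for c-/b- near zero every terazosin concentration
stimulates ATP production, and as the ratio approaches one the drug acts
as a plain competitive inhibitor at every dose.  Each sweep cell simulates
its own TZ-free baseline at the same parameter value and reports the ratio
of ATP produced with terazosin to that without.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .reaction_network import RateParameters, build_canonical_network
from .simulator import (
    DEFAULT_TZ_GRID,
    SimulationConfig,
    SimulationError,
    atp_production,
    simulate,
)

__all__ = [
    "SweepResult",
    "sweep_parameter",
    "stimulation_heatmap",
    "default_c_minus_grid",
    "SWEEPABLE_PARAMETERS",
]

SWEEPABLE_PARAMETERS = (
    "a_plus", "a_minus", "b_plus", "b_minus", "c_plus", "c_minus",
    "d_plus", "d_minus", "k_plus", "k_minus", "eta",
)


def default_c_minus_grid(
    b_minus: float = 160.0,
    n: int = 25,
    ratio_range: tuple[float, float] = (0.005, 1.2),
) -> np.ndarray:
    """Log-spaced c- grid spanning c-/b- from 0.005 to 1.2 (25 points)."""
    lo, hi = ratio_range
    return b_minus * np.logspace(np.log10(lo), np.log10(hi), n)


@dataclass(frozen=True)
class SweepResult:
    """ATP-production ratios (with TZ / without TZ) over a parameter grid.

    ``ratio[i, j]`` is production at ``param_values[i]``, ``tz_values[j]``
    divided by the TZ-free production at the same parameter value.  Cells
    whose simulation failed are NaN and listed in ``failures`` with the
    solver diagnostic.
    """

    param_name: str
    param_values: np.ndarray
    tz_values: np.ndarray
    ratio: np.ndarray
    baseline_production: np.ndarray
    failures: tuple[tuple[float, float, str], ...] = field(default=())

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (param_value, tz_uM, ratio)."""
        rows = []
        for i, p in enumerate(self.param_values):
            for j, tz in enumerate(self.tz_values):
                rows.append((p, tz, self.ratio[i, j]))
        return pd.DataFrame(rows, columns=[self.param_name, "tz_uM", "ratio"])


def sweep_parameter(
    base_params: RateParameters,
    param_name: str,
    param_grid: Sequence[float],
    tz_grid: Sequence[float] | None = None,
    config: SimulationConfig | None = None,
    clamped: Sequence[str] = ("BPG",),
) -> SweepResult:
    """Sweep one rate parameter against a terazosin grid.

    For each parameter value a fresh network is built, a TZ-free baseline
    is simulated, and then each terazosin concentration is simulated under
    otherwise identical conditions.  A solver failure at one grid point is
    recorded (NaN cell + diagnostic) without aborting the sweep.
    """
    if param_name not in SWEEPABLE_PARAMETERS:
        raise ValueError(
            f"param_name must be one of {SWEEPABLE_PARAMETERS}, got {param_name!r}"
        )
    param_grid = np.asarray(param_grid, dtype=float)
    tz_grid = np.asarray(
        DEFAULT_TZ_GRID if tz_grid is None else tz_grid, dtype=float
    )
    if param_grid.size == 0 or tz_grid.size == 0:
        raise ValueError("parameter and TZ grids must be non-empty")
    config = config if config is not None else SimulationConfig()

    ratio = np.full((len(param_grid), len(tz_grid)), np.nan)
    baseline = np.full(len(param_grid), np.nan)
    failures: list[tuple[float, float, str]] = []
    for i, value in enumerate(param_grid):
        params = base_params.replace(**{param_name: float(value)})
        network = build_canonical_network(params, clamped=clamped)
        try:
            base_traj = simulate(network, config, tz=0.0)
        except SimulationError as exc:
            failures.append((float(value), 0.0, str(exc)))
            continue
        baseline[i] = atp_production(base_traj)
        for j, tz in enumerate(tz_grid):
            if tz == 0.0:
                ratio[i, j] = 1.0
                continue
            try:
                traj = simulate(network, config, tz=float(tz))
            except SimulationError as exc:
                failures.append((float(value), float(tz), str(exc)))
                continue
            ratio[i, j] = atp_production(traj) / baseline[i]
    return SweepResult(
        param_name, param_grid, tz_grid, ratio, baseline, tuple(failures)
    )


def stimulation_heatmap(sweep: SweepResult, eps: float = 0.01) -> np.ndarray:
    """Classify each sweep cell as stimulation, neutral or inhibition.

    A cell is ``"stimulation"`` if ratio > 1 + eps, ``"inhibition"`` if
    ratio < 1 - eps, ``"neutral"`` if |ratio - 1| <= eps, and ``"missing"``
    for failed cells.
    """
    if eps < 0:
        raise ValueError("eps must be >= 0")
    out = np.full(sweep.ratio.shape, "neutral", dtype=object)
    out[sweep.ratio > 1 + eps] = "stimulation"
    out[sweep.ratio < 1 - eps] = "inhibition"
    out[np.isnan(sweep.ratio)] = "missing"
    return out
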