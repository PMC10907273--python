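"""Net-flux and enzyme-occupancy analysis.

The net flux of a reversible interaction is the forward minus the reverse
mass-action rate, e.g. a+[E][ADP] - a-[E.ADP] for ADP binding to free
enzyme.  The sign convention is positive in the direction each reaction is
written in the canonical network.  Occupancy tables report the fraction of
total enzyme in each configuration at the evaluation time and, for the
TZ-free forms, the percent change relative to a terazosin-free baseline
run; for the three TZ-bound forms a percent change is undefined (the
baseline is zero) so the percent of total enzyme is reported instead.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .reaction_network import (
    ENZYME_FORMS,
    ReactionNetwork,
    TZ_BOUND_FORMS,
    TZ_FREE_FORMS,
)

__all__ = ["net_fluxes", "flux_table", "occupancy", "occupancy_table"]

#: Baseline concentrations below this (uM) make a percent change undefined.
BASELINE_FLOOR = 1e-15


def net_fluxes(network: ReactionNetwork, state: np.ndarray) -> pd.DataFrame:
    """Net flux (uM/s) of every reaction at one state.

    Returns a DataFrame with columns ``reaction`` and ``net_flux_uM_per_s``
    in canonical reaction order (R1..R14).
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (network.n_species,):
        raise ValueError(f"state must have length {network.n_species}")
    flux = network.reaction_fluxes(state)
    return pd.DataFrame(
        {
            "reaction": [r.label for r in network.reactions],
            "net_flux_uM_per_s": flux,
        }
    )


def flux_table(
    network: ReactionNetwork,
    states_by_tz: dict[float, np.ndarray],
) -> pd.DataFrame:
    """Long-format net-flux table across terazosin concentrations.

    ``states_by_tz`` maps each TZ concentration (uM) to the state at the
    evaluation time (typically the 60 s endpoint of a default run).
    """
    frames = []
    for tz in sorted(states_by_tz):
        df = net_fluxes(network, states_by_tz[tz])
        df.insert(1, "tz_uM", tz)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def occupancy(
    network: ReactionNetwork,
    state: np.ndarray,
    baseline_state: np.ndarray,
) -> pd.DataFrame:
    """Enzyme-configuration occupancies versus a terazosin-free baseline.

    Both states must come from runs identical except for the terazosin
    concentration, evaluated at the same time; the baseline must be TZ-free
    (no free TZ, no TZ-bound enzyme).

    Returns one row per enzyme form with columns:

    - ``fraction``: share of total enzyme in that form;
    - ``percent_change``: 100 * (x - x0)/x0 vs. the baseline for TZ-free
      forms (NaN if the baseline concentration is below 1e-15 uM);
    - ``percent_of_enzyme``: fraction * 100, the quantity reported for the
      TZ-bound forms;
    - ``tz_bound``: whether the form carries terazosin.
    """
    state = np.asarray(state, dtype=float)
    baseline_state = np.asarray(baseline_state, dtype=float)
    for arr in (state, baseline_state):
        if arr.shape != (network.n_species,):
            raise ValueError(f"states must have length {network.n_species}")
    tz_idx = [network.index(n) for n in ("TZ", *TZ_BOUND_FORMS) if n in network.species_names]
    if np.any(baseline_state[tz_idx] > BASELINE_FLOOR):
        raise ValueError("baseline state must be terazosin-free (TZ = 0 run)")

    form_idx = network.indices(ENZYME_FORMS)
    conc = state[form_idx]
    conc0 = baseline_state[form_idx]
    total = conc.sum()
    if total <= 0:
        raise ValueError("no enzyme present in state")
    fractions = conc / total

    pct_change = np.full(len(ENZYME_FORMS), np.nan)
    for i, name in enumerate(ENZYME_FORMS):
        if name in TZ_FREE_FORMS and conc0[i] > BASELINE_FLOOR:
            pct_change[i] = 100.0 * (conc[i] - conc0[i]) / conc0[i]

    return pd.DataFrame(
        {
            "form": list(ENZYME_FORMS),
            "fraction": fractions,
            "percent_change": pct_change,
            "percent_of_enzyme": fractions * 100.0,
            "tz_bound": [name in TZ_BOUND_FORMS for name in ENZYME_FORMS],
        }
    )


def occupancy_table(
    network: ReactionNetwork,
    states_by_tz: dict[float, np.ndarray],
) -> pd.DataFrame:
    """Long-format occupancy table across terazosin concentrations.

    Requires a TZ = 0 entry, which serves as the common baseline.
    """
    if 0.0 not in states_by_tz:
        raise ValueError("states_by_tz must include the TZ = 0 baseline")
    baseline = states_by_tz[0.0]
    frames = []
    for tz in sorted(states_by_tz):
        df = occupancy(network, states_by_tz[tz], baseline)
        df.insert(1, "tz_uM", tz)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
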