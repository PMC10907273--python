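"""Independent oracles used by the tests.

The linear steady-state oracle hand-codes the enzyme-form transition
structure of the model (it does not reuse the package's compiled reaction
arrays): when every free ligand is clamped, the 10 enzyme forms obey a
linear ODE dx/dt = A x, whose stationary distribution is the null space of
A, normalized to the total enzyme.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import null_space

# Enzyme-form order matches the package's canonical order.
FORMS = [
    "E", "E.ADP", "E.BPG", "E.ADP.BPG", "E.ATP", "E.PG", "E.ATP.PG",
    "E.TZ", "E.TZ.BPG", "E.TZ.PG",
]

# Each edge: (from_form, to_form, rate-constant key, ligand consumed or None).
# Forward direction is binding (or phosphotransfer); reverse is dissociation.
EDGES = [
    ("E", "E.ADP", "a_plus", "a_minus", "ADP"),
    ("E", "E.BPG", "c_plus", "c_minus", "BPG"),
    ("E.ADP", "E.ADP.BPG", "b_plus", "b_minus", "BPG"),
    ("E.BPG", "E.ADP.BPG", "d_plus", "d_minus", "ADP"),
    ("E.ADP.BPG", "E.ATP.PG", "k_plus", "k_minus", None),
    ("E", "E.ATP", "a_plus", "a_minus", "ATP"),
    ("E", "E.PG", "c_plus", "c_minus", "PG"),
    ("E.ATP", "E.ATP.PG", "b_plus", "b_minus", "PG"),
    ("E.PG", "E.ATP.PG", "d_plus", "d_minus", "ATP"),
    ("E", "E.TZ", "eta*a_plus", "a_minus", "TZ"),
    ("E.BPG", "E.TZ.BPG", "eta*d_plus", "d_minus", "TZ"),
    ("E.PG", "E.TZ.PG", "eta*d_plus", "d_minus", "TZ"),
    ("E.TZ", "E.TZ.BPG", "b_plus", "b_minus", "BPG"),
    ("E.TZ", "E.TZ.PG", "b_plus", "b_minus", "PG"),
]


def clamped_rate_matrix(params: dict[str, float], ligands: dict[str, float]) -> np.ndarray:
    """10x10 generator matrix A of the clamped-ligand linear subsystem."""

    def k(key: str) -> float:
        if key.startswith("eta*"):
            return params["eta"] * params[key[4:]]
        return params[key]

    idx = {f: i for i, f in enumerate(FORMS)}
    A = np.zeros((10, 10))
    for src, dst, kf_key, kr_key, ligand in EDGES:
        kf = k(kf_key) * (ligands[ligand] if ligand else 1.0)
        kr = k(kr_key)
        i, j = idx[src], idx[dst]
        A[i, i] -= kf
        A[j, i] += kf
        A[j, j] -= kr
        A[i, j] += kr
    return A


def stationary_distribution(
    params: dict[str, float], ligands: dict[str, float], total_enzyme: float
) -> np.ndarray:
    """Steady-state enzyme-form concentrations by null-space solve."""
    A = clamped_rate_matrix(params, ligands)
    ns = null_space(A)
    if ns.shape[1] != 1:
        raise RuntimeError(f"expected a 1-dimensional null space, got {ns.shape[1]}")
    v = ns[:, 0]
    v = v * np.sign(v.sum())
    if np.any(v < -1e-12 * np.abs(v).max()):
        raise RuntimeError("null-space vector is not sign-definite")
    v = np.clip(v, 0.0, None)
    return total_enzyme * v / v.sum()
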