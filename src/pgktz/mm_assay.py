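"""Synthetic competitive-inhibition assay: data generation and MM fitting.

Emulates the statistical structure of an initial-rate enzyme assay: rates
follow the Michaelis-Menten form with a competitive inhibitor,

    v(S) = Vmax * S / (Km * (1 + I/Ki) + S) + Gaussian noise,

so an inhibited dataset is exactly an MM curve with the apparent constant
Km' = Km (1 + I/Ki) and an unchanged Vmax -- the signature by which a
competitive inhibitor is recognized.  Fitting is direct nonlinear least
squares on the hyperbola (no Lineweaver-Burk linearization) with
positivity bounds and asymptotic standard errors.

Units are whatever the caller uses, as long as they are consistent;
substrate is typically mM and rates absorbance per millisecond.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "MMParameters",
    "AssayDataset",
    "MMFit",
    "michaelis_menten",
    "generate_assay",
    "fit_mm",
    "FitError",
]


class FitError(RuntimeError):
    """Raised when the nonlinear fit fails to converge or is singular."""


@dataclass(frozen=True)
class MMParameters:
    """Generating parameters: Vmax, Km, and optionally a competitive inhibitor.

    ``inhibitor`` is the inhibitor concentration I and ``ki`` its
    dissociation constant; together they inflate the apparent Km by the
    factor (1 + I/Ki).
    """

    vmax: float
    km: float
    ki: float = np.inf
    inhibitor: float = 0.0

    def __post_init__(self) -> None:
        if self.vmax <= 0:
            raise ValueError("vmax must be > 0")
        if self.km <= 0:
            raise ValueError("km must be > 0")
        if self.ki <= 0:
            raise ValueError("ki must be > 0")
        if self.inhibitor < 0:
            raise ValueError("inhibitor concentration must be >= 0")

    @property
    def apparent_km(self) -> float:
        return self.km * (1.0 + self.inhibitor / self.ki)


def michaelis_menten(s: np.ndarray, vmax: float, km: float) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    return vmax * s / (km + s)


@dataclass(frozen=True)
class AssayDataset:
    """Initial-rate measurements over a substrate grid.

    Keeps the generating truth (``true_params``, ``noise_sd``, ``seed``)
    alongside the observations so recovery can be scored.
    """

    substrate: np.ndarray
    rate: np.ndarray
    true_params: MMParameters
    noise_sd: float
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"substrate_mM": self.substrate, "rate": self.rate})


@dataclass(frozen=True)
class MMFit:
    """Least-squares Michaelis-Menten fit with asymptotic standard errors."""

    vmax: float
    km: float
    vmax_se: float
    km_se: float
    rss: float
    converged: bool
    n_points: int


def generate_assay(
    params: MMParameters,
    substrate_grid: Sequence[float],
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> AssayDataset:
    """Generate synthetic initial rates on a substrate grid.

    Rates are the competitive-inhibition MM curve plus additive
    homoscedastic Gaussian noise of standard deviation ``noise_sd``;
    identical seeds give identical datasets.
    """
    grid = np.asarray(substrate_grid, dtype=float)
    if grid.size == 0 or np.any(grid <= 0):
        raise ValueError("substrate grid values must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rates = michaelis_menten(grid, params.vmax, params.apparent_km)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        rates = rates + rng.normal(0.0, noise_sd, size=grid.shape)
    return AssayDataset(grid, rates, params, noise_sd, seed)


def fit_mm(dataset: AssayDataset) -> MMFit:
    """Fit Vmax and Km to a dataset by bounded nonlinear least squares.

    Standard errors are the asymptotic least-squares estimates from the
    Jacobian at the optimum, with the noise variance estimated from the
    residual sum of squares (n - 2 degrees of freedom).
    """
    s = np.asarray(dataset.substrate, dtype=float)
    y = np.asarray(dataset.rate, dtype=float)
    if len(np.unique(s)) < 4:
        raise ValueError("need at least 4 distinct substrate concentrations")
    if not np.all(np.isfinite(y)):
        raise ValueError("rates must be finite")

    # Normalize rates and substrate to O(1) so the optimizer's stopping
    # criteria behave regardless of the measurement units (rates can be
    # ~1e-7 absorbance/ms while Km is in mM).
    y_scale = max(float(np.abs(y).max()), np.finfo(float).tiny)
    s_scale = float(np.median(s))
    yn, sn = y / y_scale, s / s_scale
    v0 = max(yn.max(), 1e-6)
    km0 = float(sn[np.argmin(np.abs(yn - v0 / 2))])
    km0 = max(km0, sn.min() * 1e-3)

    def residuals(theta: np.ndarray) -> np.ndarray:
        return michaelis_menten(sn, theta[0], theta[1]) - yn

    result = least_squares(
        residuals,
        x0=[v0, km0],
        bounds=([0.0, 0.0], [np.inf, np.inf]),
        method="trf",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not result.success:
        raise FitError(f"Michaelis-Menten fit did not converge: {result.message}")
    vmax_hat = result.x[0] * y_scale
    km_hat = result.x[1] * s_scale
    rss = float(2.0 * result.cost) * y_scale**2
    n = len(s)
    dof = max(n - 2, 1)
    JTJ = result.jac.T @ result.jac
    try:
        cov = np.linalg.inv(JTJ) * (2.0 * result.cost / dof)
    except np.linalg.LinAlgError as exc:
        raise FitError(f"singular Jacobian in Michaelis-Menten fit: {exc}") from exc
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None)) * [y_scale, s_scale]
    return MMFit(
        vmax=float(vmax_hat),
        km=float(km_hat),
        vmax_se=float(se[0]),
        km_se=float(se[1]),
        rss=rss,
        converged=bool(result.success),
        n_points=n,
    )
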