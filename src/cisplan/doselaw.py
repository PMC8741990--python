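"""Minimal-dose-versus-volume power laws and dose-reduction comparisons.

Over tumor volumes below ~40 cm^3 the minimal effective dose follows
``dose = alpha * Volume^beta`` to good approximation, with alpha and beta
depending on the number of injections; beta falls as injections are added
because distributed sites shorten the diffusion distances the drug must
cover.  Fits are ordinary least squares of log10(dose) on log10(volume)
with classical t-based 95% confidence intervals.

beta and R^2 are invariant to the Green's-function normalization mode;
log10(alpha) shifts by exactly log10(4 pi) between modes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .geometry import make_sphere_mask
from .pkpd import ModelParams
from .response import DEFAULT_N_REPLICATES, min_dose

DEFAULT_MAX_VOLUME_CM3 = 40.0  # validity range of the power-law approximation


@dataclass
class PowerLawFit:
    """OLS fit of log10(dose) = log10_alpha + beta * log10(volume)."""

    log10_alpha: float
    beta: float
    ci_log10_alpha: tuple[float, float]
    ci_beta: tuple[float, float]
    r2: float
    n_points: int

    def dose_at(self, volume_cm3: float) -> float:
        """Predicted minimal dose (mg) at a volume (cm^3)."""
        return 10.0 ** (self.log10_alpha + self.beta * np.log10(volume_cm3))


def fit_power_law(
    volumes: Sequence[float], doses: Sequence[float]
) -> PowerLawFit:
    """Fit dose = alpha * Volume^beta by OLS in log10-log10 space.

    95% CIs use the classical t-based slope/intercept standard errors.
    """
    v = np.asarray(volumes, dtype=float)
    d = np.asarray(doses, dtype=float)
    if v.shape != d.shape or v.ndim != 1:
        raise ValueError("volumes and doses must be 1-D of equal length")
    if v.size < 3:
        raise ValueError(f"need >= 3 points, got {v.size}")
    if np.any(v <= 0) or np.any(d <= 0):
        raise ValueError("volumes and doses must all be positive")
    if np.allclose(v, v[0]):
        raise ValueError("all volumes identical; slope is undefined")
    X = sm.add_constant(np.log10(v))
    res = sm.OLS(np.log10(d), X).fit()
    ci = res.conf_int(alpha=0.05)
    return PowerLawFit(
        log10_alpha=float(res.params[0]),
        beta=float(res.params[1]),
        ci_log10_alpha=(float(ci[0, 0]), float(ci[0, 1])),
        ci_beta=(float(ci[1, 0]), float(ci[1, 1])),
        r2=float(res.rsquared),
        n_points=int(v.size),
    )


def _subseed(seed: int, n: int, i: int) -> int:
    # disjoint replicate seed blocks per (injection count, volume index)
    return (seed + 10_000 * (i + 100 * n)) % 2**31


def min_dose_curve(
    volumes: Sequence[float],
    n: int,
    params: ModelParams,
    n_replicates: int = DEFAULT_N_REPLICATES,
    seed: int = 0,
    spacing_mm: float = 1.0,
) -> np.ndarray:
    """Minimal effective dose (mg) on sphere surrogates at each volume."""
    doses = np.empty(len(volumes))
    for i, v in enumerate(volumes):
        mask = make_sphere_mask(v, spacing_mm)
        doses[i] = min_dose(mask, n, params, n_replicates, _subseed(seed, n, i))
    return doses


def dose_law_table(
    volumes: Sequence[float],
    n_list: Sequence[int],
    params: ModelParams,
    n_replicates: int = DEFAULT_N_REPLICATES,
    seed: int = 0,
    spacing_mm: float = 1.0,
    max_volume_cm3: float = DEFAULT_MAX_VOLUME_CM3,
) -> pd.DataFrame:
    """Power-law fit per injection count over sphere surrogates.

    Volumes at or above ``max_volume_cm3`` are excluded (the power-law
    approximation is only claimed below ~40 cm^3).

    Returns a DataFrame with one row per injection count:
    ``n, log10_alpha, alpha_ci_lo, alpha_ci_hi, beta, beta_ci_lo,
    beta_ci_hi, r2, n_points``.
    """
    v = np.asarray(volumes, dtype=float)
    v = v[v < max_volume_cm3]
    if v.size < 3:
        raise ValueError("fewer than 3 volumes below the validity limit")
    rows = []
    for n in n_list:
        doses = min_dose_curve(v, n, params, n_replicates, seed, spacing_mm)
        fit = fit_power_law(v, doses)
        rows.append(
            {
                "n": n,
                "log10_alpha": fit.log10_alpha,
                "alpha_ci_lo": fit.ci_log10_alpha[0],
                "alpha_ci_hi": fit.ci_log10_alpha[1],
                "beta": fit.beta,
                "beta_ci_lo": fit.ci_beta[0],
                "beta_ci_hi": fit.ci_beta[1],
                "r2": fit.r2,
                "n_points": fit.n_points,
            }
        )
    return pd.DataFrame(rows).set_index("n")


def dose_reduction_orders(
    mask_volume_cm3: float,
    n_lo: int,
    n_hi: int,
    params: ModelParams,
    n_replicates: int = DEFAULT_N_REPLICATES,
    seed: int = 0,
    spacing_mm: float = 1.0,
) -> float:
    """Orders of magnitude saved by splitting the dose over more injections.

    log10( min_dose with n_lo injections / min_dose with n_hi injections )
    on a sphere surrogate of the given volume; invariant to greens_mode.
    """
    if n_lo > n_hi:
        raise ValueError(f"need n_lo <= n_hi, got {n_lo} > {n_hi}")
    if n_lo == n_hi:
        return 0.0
    mask = make_sphere_mask(mask_volume_cm3, spacing_mm)
    d_lo = min_dose(mask, n_lo, params, n_replicates, seed)
    d_hi = min_dose(mask, n_hi, params, n_replicates, seed)
    return float(np.log10(d_lo / d_hi))
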