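"""Stochastic apoptosis thresholds, V_response, classification and minimal dose.

Per-voxel apoptosis thresholds phi_t are drawn i.i.d. from a log-normal
distribution, 10^Normal(mu, sigma) with mu, sigma in log10(mg/ml), fitted
to in-vitro 72-h cisplatin IC50 values across NSCLC cell lines.  A tumor is
predicted to respond when at least ``response_fraction`` (default 66%) of
its volume reaches an asymptotic intracellular concentration at or above
the local threshold — the volume-equivalent of a RECIST v1.1 partial
response (30% diameter reduction; 1 - 0.7^3 = 65.7% of the volume).

The minimal effective dose exploits linearity of the field in dose: with
the unit-dose field Phi(v), voxel v is covered at total dose M iff
M >= phi_t(v) / Phi(v), so the smallest dose achieving the required
coverage is the k-th smallest per-voxel critical dose with
k = ceil(response_fraction * N_vox).  Replicate threshold draws are
aggregated by the mean for V_response and by the median for minimal dose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import TumorMask
from .pkpd import ConcentrationField, ModelParams, steady_state_field
from .planning import apportion_dose, place_sites

DEFAULT_N_REPLICATES = 25


@dataclass(frozen=True, eq=False)
class ThresholdField:
    """Per-voxel apoptosis threshold phi_t (mg/ml), aligned to a mask."""

    values: np.ndarray
    mask: TumorMask
    seed: int

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size != self.mask.n_occupied:
            raise ValueError("values must be 1-D with one entry per occupied voxel")
        if np.any(vals <= 0):
            raise ValueError("thresholds must be positive")
        object.__setattr__(self, "values", vals)


@dataclass
class ResponseResult:
    """Outcome of a stochastic response prediction.

    v_response_pct is the mean over replicates; ``predicted`` is 1 iff that
    mean reaches 100 * response_fraction.
    """

    v_response_pct: float
    predicted: int
    replicates: np.ndarray
    seed: int


def recist_volume_reduction_pct(diameter_reduction: float = 0.3) -> float:
    """Volume-reduction percentage equivalent to a RECIST diameter reduction.

    For a sphere, a 30% diameter reduction is 100 * (1 - 0.7^3) = 65.7%,
    which rounds to the 66% response fraction used by the classifier.
    """
    return 100.0 * (1.0 - (1.0 - diameter_reduction) ** 3)


def sample_thresholds(mask: TumorMask, params: ModelParams, seed: int) -> ThresholdField:
    """Draw per-voxel thresholds phi_t = 10^x, x ~ Normal(mu, sigma) i.i.d.

    Deterministic given ``seed`` (bit-for-bit reproducible).
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(params.mu, params.sigma, size=mask.n_occupied)
    return ThresholdField(10.0**x, mask, seed)


def v_response(field: ConcentrationField, thresholds: ThresholdField) -> float:
    """Percent of tumor volume at or above its local threshold."""
    if field.mask is not thresholds.mask and (
        field.mask.occupancy.shape != thresholds.mask.occupancy.shape
        or field.mask.n_occupied != thresholds.mask.n_occupied
    ):
        raise ValueError("field and thresholds are defined on different masks")
    return float(100.0 * np.mean(field.values >= thresholds.values))


def classify(v_response_pct: float, params: ModelParams) -> int:
    """1 (responder) iff v_response_pct >= 100 * response_fraction (inclusive)."""
    if not 0.0 <= v_response_pct <= 100.0:
        raise ValueError(f"v_response_pct must be in [0, 100], got {v_response_pct}")
    return int(v_response_pct >= 100.0 * params.response_fraction)


def predict(
    mask: TumorMask,
    total_dose: float,
    n: int,
    params: ModelParams,
    n_replicates: int = DEFAULT_N_REPLICATES,
    seed: int = 0,
) -> ResponseResult:
    """Predict response for a tumor given total dose and injection count.

    Sites come from the deterministic planner with equal dose split; each
    replicate r draws thresholds with ``seed + r``; the replicate-mean
    V_response feeds the classifier.
    """
    if n_replicates < 1:
        raise ValueError(f"n_replicates must be >= 1, got {n_replicates}")
    plan = apportion_dose(place_sites(mask, n), total_dose)
    field = steady_state_field(mask, plan, params)
    reps = np.array(
        [
            v_response(field, sample_thresholds(mask, params, seed + r))
            for r in range(n_replicates)
        ]
    )
    mean_v = float(reps.mean())
    return ResponseResult(mean_v, classify(mean_v, params), reps, seed)


def min_dose_replicates(
    mask: TumorMask,
    n: int,
    params: ModelParams,
    n_replicates: int = DEFAULT_N_REPLICATES,
    seed: int = 0,
) -> np.ndarray:
    """Per-replicate minimal effective dose (mg) by the percentile formula.

    For each replicate: critical doses M_v = phi_t(v) / Phi(v) with Phi the
    unit-total-dose field, then the k-th smallest with
    k = ceil(response_fraction * N_vox).
    """
    if n_replicates < 1:
        raise ValueError(f"n_replicates must be >= 1, got {n_replicates}")
    plan = place_sites(mask, n)  # unit total dose
    unit_field = steady_state_field(mask, plan, params)
    n_vox = mask.n_occupied
    k = int(np.ceil(params.response_fraction * n_vox))
    doses = np.empty(n_replicates)
    for r in range(n_replicates):
        phi_t = sample_thresholds(mask, params, seed + r).values
        critical = phi_t / unit_field.values
        doses[r] = np.partition(critical, k - 1)[k - 1]
    return doses


def min_dose(
    mask: TumorMask,
    n: int,
    params: ModelParams,
    n_replicates: int = DEFAULT_N_REPLICATES,
    seed: int = 0,
) -> float:
    """Median over replicates of the minimal effective dose, mg."""
    return float(np.median(min_dose_replicates(mask, n, params, n_replicates, seed)))
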