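"""Injection-site placement and dose apportioning.

The placement algorithm chooses N sites that spread the superposed,
monotonically decaying concentration kernel as evenly as possible over the
tumor: the first seed is the occupied voxel nearest the mask centroid,
subsequent seeds are added by farthest-point selection, and the seed set is
refined by Lloyd-style clustering (assign occupied voxels to their nearest
site, move each site to its cluster centroid snapped back to the nearest
occupied voxel) until a fixed point or 100 iterations.  Everything is
deterministic; ties break on the lexicographic voxel order.

Dose is split equally among sites (m_j = total / N); site geometry is
independent of dose because the field is linear in dose.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import TumorMask, MM_PER_CM
from .pkpd import ConcentrationField, ModelParams

_MAX_LLOYD_ITER = 100


@dataclass(frozen=True, eq=False)
class InjectionPlan:
    """N injection sites (voxel-center positions, cm) with per-site doses (mg)."""

    sites_cm: np.ndarray  # (N, 3)
    doses_mg: np.ndarray  # (N,)
    voxel_indices: np.ndarray  # (N, 3) int

    def __post_init__(self) -> None:
        sites = np.atleast_2d(np.asarray(self.sites_cm, dtype=float))
        doses = np.atleast_1d(np.asarray(self.doses_mg, dtype=float))
        idx = np.atleast_2d(np.asarray(self.voxel_indices, dtype=int))
        if sites.shape[0] != doses.shape[0] or sites.shape != idx.shape:
            raise ValueError("sites, doses and voxel_indices must have matching length")
        if sites.shape[0] < 1:
            raise ValueError("plan must contain at least one site")
        if np.any(doses <= 0):
            raise ValueError("all per-site doses must be positive")
        if len({tuple(i) for i in idx}) != len(idx):
            raise ValueError("all sites must occupy distinct voxels")
        object.__setattr__(self, "sites_cm", sites)
        object.__setattr__(self, "doses_mg", doses)
        object.__setattr__(self, "voxel_indices", idx)

    @property
    def n_sites(self) -> int:
        return len(self.doses_mg)

    @property
    def total_dose_mg(self) -> float:
        return float(self.doses_mg.sum())


def place_sites(
    mask: TumorMask,
    n: int,
    params: ModelParams | None = None,
    return_history: bool = False,
):
    """Choose ``n`` injection sites in the mask; unit total dose.

    ``params`` is accepted for interface symmetry but unused: for an
    isotropic monotone kernel the equidistant partition produced here does
    not depend on the rate constants.

    With ``return_history=True`` also returns the list of site-index arrays
    after each Lloyd iteration (for auditing convergence).
    """
    del params
    n_vox = mask.n_occupied
    if n < 1:
        raise ValueError(f"number of sites must be >= 1, got {n}")
    if n > n_vox:
        raise ValueError(f"requested {n} sites but mask has only {n_vox} voxels")

    centers = mask.occupied_centers_cm()  # lexicographic order
    centroid = centers.mean(axis=0)

    # farthest-point seeding, first seed nearest the centroid
    chosen = [int(np.argmin(np.linalg.norm(centers - centroid, axis=1)))]
    if n > 1:
        d_min = np.linalg.norm(centers - centers[chosen[0]], axis=1)
        for _ in range(1, n):
            nxt = int(np.argmax(d_min))  # argmax takes first index on ties
            chosen.append(nxt)
            d_min = np.minimum(d_min, np.linalg.norm(centers - centers[nxt], axis=1))

    sites = np.array(sorted(chosen))
    history = [sites.copy()]
    for _ in range(_MAX_LLOYD_ITER):
        labels = np.argmin(cdist(centers, centers[sites]), axis=1)
        new_sites = []
        for k in range(n):
            members = np.nonzero(labels == k)[0]
            if members.size == 0:
                new_sites.append(sites[k])  # keep an empty cluster's site
                continue
            c = centers[members].mean(axis=0)
            new_sites.append(int(np.argmin(np.linalg.norm(centers - c, axis=1))))
        new_sites = np.array(sorted(set(new_sites)))
        if new_sites.size < n:
            break  # collision of snapped centroids: keep the previous site set
        if np.array_equal(new_sites, sites):
            break
        sites = new_sites
        history.append(sites.copy())

    idx = mask.occupied_indices()[sites]
    plan = InjectionPlan(
        sites_cm=centers[sites],
        doses_mg=np.full(len(sites), 1.0 / len(sites)),
        voxel_indices=idx,
    )
    if return_history:
        return plan, history
    return plan


def apportion_dose(plan: InjectionPlan, total_dose: float) -> InjectionPlan:
    """Split ``total_dose`` equally among the plan's sites: m_j = total / N."""
    if total_dose <= 0:
        raise ValueError(f"total_dose must be positive, got {total_dose}")
    return InjectionPlan(
        sites_cm=plan.sites_cm.copy(),
        doses_mg=np.full(plan.n_sites, total_dose / plan.n_sites),
        voxel_indices=plan.voxel_indices.copy(),
    )


def homogeneity_cost(field: ConcentrationField) -> float:
    """Coefficient of variation (population SD / mean) of the field.

    Lower is more homogeneous; zero for a uniform field.
    """
    v = field.values
    if v.size < 2:
        raise ValueError("homogeneity cost needs a field on >= 2 voxels")
    mean = v.mean()
    if mean == 0:
        raise ValueError("field mean is zero; cost undefined")
    return float(v.std() / mean)  # population (n-denominator) SD


# -- plan (de)serialization --------------------------------------------------


def plan_to_json(plan: InjectionPlan, path: str) -> None:
    """Serialize a plan as JSON: site coordinates in mm, doses in mg."""
    payload = {
        "sites_mm": (plan.sites_cm * MM_PER_CM).tolist(),
        "doses_mg": plan.doses_mg.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def plan_from_json(path: str, mask: TumorMask) -> InjectionPlan:
    """Load a plan (e.g. a clinician's actual sites) and snap it to *mask*.

    Each site position is snapped to the nearest occupied voxel center;
    positions farther than one voxel diagonal from any occupied voxel are
    rejected.
    """
    with open(path) as fh:
        payload = json.load(fh)
    sites_cm = np.atleast_2d(np.asarray(payload["sites_mm"], dtype=float)) / MM_PER_CM
    doses = np.atleast_1d(np.asarray(payload["doses_mg"], dtype=float))
    centers = mask.occupied_centers_cm()
    tol = np.linalg.norm(np.asarray(mask.spacing_mm)) / MM_PER_CM
    snapped_idx = []
    for j, s in enumerate(sites_cm):
        d = np.linalg.norm(centers - s, axis=1)
        k = int(np.argmin(d))
        if d[k] > tol:
            raise ValueError(
                f"site {j} at {s * MM_PER_CM} mm is {d[k] * MM_PER_CM:.1f} mm "
                "from the nearest occupied voxel — outside the mask"
            )
        snapped_idx.append(k)
    idx = mask.occupied_indices()[snapped_idx]
    return InjectionPlan(centers[snapped_idx], doses, idx)
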