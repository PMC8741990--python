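"""Cisplatin pharmacodynamics after intratumoral injection.

The tumor is a voxelized domain with two local compartments per voxel
(extracellular phi_e, intracellular phi_i) plus one systemic fluid
compartment (phi_f).  Drug diffuses in the extracellular space with uniform
coefficient D, is taken up irreversibly into cells at rate k_i, and is
cleared to the fluid compartment at rate k_f, from which it may be
eliminated renally at rate k_r:

    d phi_e / dt = D lap(phi_e) - (k_i + k_f) phi_e
    d phi_i / dt = k_i phi_e
    d phi_f / dt = (k_f / V_f) * integral(phi_e) - k_r phi_f

Because uptake is irreversible, phi_i rises monotonically to an asymptote.
For N point injections of mass m_j at positions r_j the asymptote is a
superposition of screened-Coulomb kernels,

    phi_i(r, inf) = sum_j C * k_i m_j / (D |r - r_j|) * exp(-|r - r_j| / L),

with decay length L = sqrt(D / (k_i + k_f)) (~1 mm at the defaults).  The
kernel constant C is 1 in ``greens_mode="paper"`` and 1/(4 pi) in
``greens_mode="physical"`` (the free-space Green's function normalization);
all coverage fractions, dose ratios and classifications are invariant to
this constant, absolute dose intercepts are not, so both modes are exposed.

Units: cm, s, mg throughout; concentrations in mg/ml (= mg/cm^3).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import TYPE_CHECKING

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import TumorMask, pad_domain, MM_PER_CM

if TYPE_CHECKING:  # pragma: no cover
    from .planning import InjectionPlan

GREENS_MODES = ("paper", "physical")


@dataclass
class ModelParams:
    """Rate constants, threshold-distribution parameters and mode switches.

    Attributes
    ----------
    D : float
        Extracellular diffusion coefficient, cm^2/s.  Default estimated
        from the molecular weight of cisplatin for soft tissue at 37 C.
    k_i : float
        Irreversible intracellular uptake rate constant, 1/s.
    k_f : float
        Clearance rate from tumor to the systemic fluid compartment, 1/s.
    V_f : float
        Systemic fluid compartment volume, ml.
    k_r : float
        Renal elimination rate from the fluid compartment, 1/s.  Default 0:
        response prediction never depends on it because intracellular
        uptake is irreversible and the fluid compartment does not feed back
        into the tumor.
    mu, sigma : float
        Mean and SD of log10(IC50 in mg/ml) for the per-voxel apoptosis
        threshold distribution (fit to 72-h cisplatin IC50 values in 75
        NSCLC cell lines).
    response_fraction : float
        Volume fraction that must exceed threshold for a predicted
        response; 0.66 corresponds to the 30% diameter reduction of
        RECIST v1.1 partial response on a sphere (1 - 0.7^3 = 0.657).
    greens_mode : str
        "paper" (C = 1) or "physical" (C = 1/(4 pi)); see module docstring.
    mw_cisplatin : float
        Molecular weight of cisplatin, g/mol (bookkeeping only).
    """

    D: float = 2.47e-6
    k_i: float = 1.05e-4
    k_f: float = 1.46e-4
    V_f: float = 12200.0
    k_r: float = 0.0
    mu: float = -2.59
    sigma: float = 0.50
    response_fraction: float = 0.66
    greens_mode: str = "paper"
    mw_cisplatin: float = 300.01

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("D", "V_f"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.k_i < 0 or self.k_f < 0:
            raise ValueError("k_i and k_f must be >= 0")
        if self.k_i + self.k_f <= 0:
            raise ValueError("k_i + k_f must be > 0 (decay length undefined)")
        if self.k_r < 0:
            raise ValueError(f"k_r must be >= 0, got {self.k_r}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if not 0.0 < self.response_fraction < 1.0:
            raise ValueError(
                f"response_fraction must be in (0, 1), got {self.response_fraction}"
            )
        if self.greens_mode not in GREENS_MODES:
            raise ValueError(
                f"greens_mode must be one of {GREENS_MODES}, got {self.greens_mode!r}"
            )

    @property
    def kernel_constant(self) -> float:
        return 1.0 if self.greens_mode == "paper" else 1.0 / (4.0 * np.pi)

    def replace(self, **changes) -> "ModelParams":
        return replace(self, **changes)


@dataclass(frozen=True, eq=False)
class ConcentrationField:
    """Asymptotic intracellular concentration per occupied voxel, mg/ml.

    ``values[i]`` corresponds to ``mask.occupied_indices()[i]``.
    """

    values: np.ndarray
    mask: TumorMask

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size != self.mask.n_occupied:
            raise ValueError("values must be 1-D with one entry per occupied voxel")
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise ValueError("field values must be finite and >= 0")
        object.__setattr__(self, "values", vals)

    def to_volume(self, fill: float = 0.0) -> np.ndarray:
        """Scatter the field back onto the mask grid (3-D array)."""
        vol = np.full(self.mask.occupancy.shape, fill, dtype=float)
        idx = self.mask.occupied_indices()
        vol[idx[:, 0], idx[:, 1], idx[:, 2]] = self.values
        return vol


@dataclass
class TransientState:
    """Snapshot of the transient solution at time ``t`` (seconds).

    phi_e and phi_i are 3-D arrays on the padded solver domain; phi_f is
    the scalar fluid-compartment concentration (mg/ml).
    """

    phi_e: np.ndarray
    phi_i: np.ndarray
    phi_f: float
    t: float


def decay_length(params: ModelParams) -> float:
    """Characteristic decay length sqrt(D / (k_i + k_f)), in cm."""
    return float(np.sqrt(params.D / (params.k_i + params.k_f)))


def steady_state_field(
    mask: TumorMask, plan: "InjectionPlan", params: ModelParams
) -> ConcentrationField:
    """Asymptotic intracellular field of an injection plan by superposition.

    For every occupied voxel v and site j,

        phi(v) += C * k_i m_j / (D * r_eff) * exp(-r / L)

    with r the center-to-site distance, L the decay length, and
    r_eff = max(r, h/2) where h is the voxel edge — a distance floor that
    keeps the 1/r kernel finite at the source voxel.
    """
    if len(plan.doses_mg) == 0:
        raise ValueError("injection plan is empty")
    if np.any(plan.doses_mg <= 0):
        raise ValueError("all per-site doses must be positive")
    _check_sites_inside(mask, plan)
    centers = mask.occupied_centers_cm()
    r = cdist(centers, plan.sites_cm)  # (Nvox, Nsites), cm
    h = mask.voxel_edge_cm
    r_eff = np.maximum(r, h / 2.0)
    L = decay_length(params)
    kern = params.kernel_constant * params.k_i / params.D
    values = (kern * plan.doses_mg / r_eff * np.exp(-r / L)).sum(axis=1)
    return ConcentrationField(values, mask)


def _check_sites_inside(mask: TumorMask, plan: "InjectionPlan") -> None:
    occ = mask.occupancy
    for j, idx in enumerate(plan.voxel_indices):
        i = tuple(int(x) for x in idx)
        if any(x < 0 or x >= s for x, s in zip(i, occ.shape)) or not occ[i]:
            raise ValueError(f"injection site {j} at voxel {i} is outside the mask")


def fluid_asymptote(params: ModelParams, total_dose: float) -> float:
    """Limiting fluid-compartment concentration phi_f(inf), mg/ml, for k_r = 0.

    The dose partitions between irreversible uptake and clearance in the
    ratio k_i : k_f, so the fluid compartment ultimately receives the
    fraction k_f / (k_i + k_f) of the dose, diluted in V_f.
    """
    if params.k_r > 0:
        raise ValueError(
            "fluid asymptote is only defined for k_r = 0; "
            "use transient_simulate for k_r > 0"
        )
    if total_dose < 0:
        raise ValueError("total_dose must be >= 0")
    return params.k_f / (params.k_i + params.k_f) * total_dose / params.V_f


def transient_simulate(
    mask: TumorMask,
    plan: "InjectionPlan",
    params: ModelParams,
    t_end: float,
    pad_mm: float | None = None,
    dt: float | None = None,
    n_snapshots: int = 50,
) -> list[TransientState]:
    """Explicit finite-difference solution of the full transient system.

    Serves as a verification oracle for :func:`steady_state_field` (the
    planner itself only uses the asymptote).  phi_e evolves on a padded
    bounding box with a 7-point Laplacian, uniform coefficients (tumor and
    surround identical, matching the free-space kernel assumption) and a
    zero-concentration boundary condition; phi_i integrates k_i * phi_e
    per voxel; phi_f integrates the clearance flux.  The initial dose m_j
    is loaded into the extracellular compartment of each site's voxel.

    Parameters
    ----------
    t_end : float
        End time, s.
    pad_mm : float, optional
        Padding margin; default 5 decay lengths.
    dt : float, optional
        Time step, s; must satisfy the explicit stability bound
        ``dt <= 0.9 * h^2 / (6 D)``; defaults to that bound.
    n_snapshots : int
        Number of evenly spaced states to record (the final state is
        always included).

    Returns
    -------
    list of TransientState on the padded domain (see :func:`pad_domain`).
    """
    if t_end <= 0:
        raise ValueError(f"t_end must be positive, got {t_end}")
    L = decay_length(params)
    if pad_mm is None:
        pad_mm = 5.0 * L * MM_PER_CM
    domain = pad_domain(mask, pad_mm)
    h = min(domain.spacing_mm) / MM_PER_CM  # cm
    # positivity/stability: dt * (6D/h^2 + k_i + k_f) <= 0.9; this implies
    # the pure-diffusion bound 0.9 h^2 / (6D) and keeps phi_e >= 0
    dt_max = 0.9 / (6.0 * params.D / h**2 + params.k_i + params.k_f)
    if dt is None:
        dt = dt_max
    elif dt > dt_max:
        raise ValueError(
            f"dt = {dt:.4g} s violates the explicit stability bound "
            f"{dt_max:.4g} s for h = {h:.4g} cm"
        )
    n_steps = int(np.ceil(t_end / dt))
    if n_steps < 1:
        raise ValueError("t_end is shorter than one time step")
    dt = t_end / n_steps

    snapped = _snap_plan_to(domain, plan)
    _check_sites_inside(domain, snapped)

    v_vox = domain.voxel_volume_cm3
    phi_e = np.zeros(domain.occupancy.shape, dtype=float)
    for idx, m in zip(snapped.voxel_indices, snapped.doses_mg):
        phi_e[tuple(idx)] += m / v_vox
    phi_i = np.zeros_like(phi_e)
    phi_f = 0.0

    spacing_cm = np.asarray(domain.spacing_mm) / MM_PER_CM
    inv_h2 = 1.0 / spacing_cm**2
    loss = params.k_i + params.k_f

    record_at = set(
        np.linspace(1, n_steps, min(n_snapshots, n_steps), dtype=int).tolist()
    )
    states: list[TransientState] = [
        TransientState(phi_e.copy(), phi_i.copy(), phi_f, 0.0)
    ]
    for step in range(1, n_steps + 1):
        lap = _laplacian_dirichlet0(phi_e, inv_h2)
        # forward Euler: all right-hand sides evaluated at the current state
        flux_to_fluid = params.k_f * phi_e.sum() * v_vox  # mg/s
        phi_i = phi_i + dt * params.k_i * phi_e
        phi_f = phi_f + dt * (flux_to_fluid / params.V_f - params.k_r * phi_f)
        phi_e = phi_e + dt * (params.D * lap - loss * phi_e)
        if step in record_at:
            states.append(TransientState(phi_e.copy(), phi_i.copy(), phi_f, step * dt))
    return states


def _laplacian_dirichlet0(u: np.ndarray, inv_h2: np.ndarray) -> np.ndarray:
    """7-point Laplacian with zero (Dirichlet) values outside the box."""
    lap = np.zeros_like(u)
    for ax in range(3):
        upper = np.zeros_like(u)
        lower = np.zeros_like(u)
        sl_from = [slice(None)] * 3
        sl_to = [slice(None)] * 3
        sl_from[ax] = slice(1, None)
        sl_to[ax] = slice(None, -1)
        upper[tuple(sl_to)] = u[tuple(sl_from)]
        lower[tuple(sl_from)] = u[tuple(sl_to)]
        lap += (upper + lower - 2.0 * u) * inv_h2[ax]
    return lap


def _snap_plan_to(domain: TumorMask, plan: "InjectionPlan") -> "InjectionPlan":
    """Re-index plan sites onto a (padded/re-cropped) domain grid."""
    from .planning import InjectionPlan

    spacing = np.asarray(domain.spacing_mm)
    origin = np.asarray(domain.origin_mm)
    pos_mm = plan.sites_cm * MM_PER_CM
    idx = np.floor((pos_mm - origin) / spacing).astype(int)
    return InjectionPlan(
        sites_cm=plan.sites_cm.copy(),
        doses_mg=plan.doses_mg.copy(),
        voxel_indices=idx,
    )


def trajectory_to_csv(
    states: list[TransientState], domain: TumorMask, path: str
) -> None:
    """Write a trajectory as CSV: t, total extracellular and intracellular
    mass (mg), and fluid concentration (mg/ml)."""
    v_vox = domain.voxel_volume_cm3
    with open(path, "w") as fh:
        fh.write("t_s,mass_extracellular_mg,mass_intracellular_mg,phi_f_mg_per_ml\n")
        for s in states:
            fh.write(
                f"{s.t!r},{s.phi_e.sum() * v_vox!r},"
                f"{s.phi_i.sum() * v_vox!r},{s.phi_f!r}\n"
            )


def total_mass(state: TransientState, domain: TumorMask, params: ModelParams) -> float:
    """Total drug mass in mg: extracellular + intracellular + fluid."""
    v_vox = domain.voxel_volume_cm3
    return float(
        state.phi_e.sum() * v_vox
        + state.phi_i.sum() * v_vox
        + params.V_f * state.phi_f
    )
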