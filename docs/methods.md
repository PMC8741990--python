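# Methods

## Model

`cisplan` treats a lung tumor as a set of occupied voxels on a regular
grid with physical spacing. Each voxel superposes an extracellular and an
intracellular compartment; a single well-mixed systemic fluid compartment
sits outside the tumor. Cisplatin diffuses extracellularly with uniform
coefficient `D`, enters cells irreversibly at rate `k_i` (cisplatin binds
DNA covalently, so no efflux term), and is cleared by tumor perfusion at
rate `k_f` into the fluid compartment of volume `V_f`, from which it can
be eliminated renally at rate `k_r`:

    dφ_e/dt = D ∇²φ_e − (k_i + k_f) φ_e
    dφ_i/dt = k_i φ_e
    dφ_f/dt = (k_f / V_f) ∫ φ_e dV − k_r φ_f

Irreversible uptake makes φ_i monotone in time with the asymptote

    φ_i(r, ∞) = Σ_j C · k_i m_j / (D |r − r_j|) · exp(−|r − r_j|/λ),
    λ = √(D / (k_i + k_f)),

a superposition of screened point-source kernels over the N injection
sites with per-site masses m_j. All internal units are cm / s / mg
(concentrations in mg/ml ≡ mg/cm³); voxel spacings and NIfTI headers are
in mm and converted at the geometry boundary.

### Kernel normalization (`greens_mode`)

The free-space Green's function of diffusion with linear loss carries a
1/(4π) prefactor; the asymptotic formula above is also in circulation
without it. Both conventions are exposed: `greens_mode="paper"` uses
C = 1 (the default, matching the published formula verbatim) and
`"physical"` uses C = 1/(4π). Every coverage fraction, response
classification, power-law exponent, R², and dose *ratio* is exactly
invariant to this constant; absolute minimal doses scale by 4π and the
power-law intercept log₁₀α shifts by log₁₀(4π) ≈ 1.10. The transient
solver converges to the *physical* normalization, which is the reason
both modes exist.

### Singularity handling

The 1/r kernel diverges at a source voxel. Distances are floored at
r_eff = max(r, h/2) with h the voxel edge (cube root of the voxel volume
for anisotropic grids); the exponential uses the true r. This keeps
source voxels finite and preserves strict monotone decay beyond the
floor.

## Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| `D` | extracellular diffusion coefficient | 2.47e−6 | cm²/s |
| `k_i` | intracellular uptake rate | 1.05e−4 | 1/s |
| `k_f` | clearance rate to fluid | 1.46e−4 | 1/s |
| `V_f` | fluid compartment volume | 12 200 | ml |
| `k_r` | renal elimination | 0 | 1/s |
| `mu`, `sigma` | log10 IC50 distribution | −2.59, 0.50 | log10(mg/ml) |
| `response_fraction` | volume fraction for response | 0.66 | — |

`D` comes from a molecular-weight scaling for soft tissue at 37 °C, `k_i`
from carcinoma uptake measurements, and `k_f`/`V_f` from a fit to serial
blood cisplatin concentrations after intratumoral injection. The decay
length at the defaults is λ = √(2.47e−6 / 2.51e−4) = 0.992 mm, which is
why injection geometry dominates outcomes at clinical tumor sizes.
`k_r` defaults to zero because response prediction never depends on it:
uptake is irreversible and the fluid compartment does not feed back into
the tumor. `k_i` and `k_f` may individually be zero (limits used in
closed-form checks) but not both, since λ would be undefined.

The threshold distribution maps a 72-hour constant-exposure in-vitro IC50
onto the asymptotic post-bolus intracellular concentration — an inherited
modeling assumption, not a derived equivalence. The 66% response fraction
is the spherical-volume equivalent of the RECIST v1.1 partial-response
cut (30% diameter reduction; 1 − 0.7³ = 65.7%). The classifier is
inclusive (≥ 66%).

## Response and minimal dose

Per-voxel thresholds are drawn i.i.d. as φ_t = 10^x, x ~ Normal(μ, σ),
independently per replicate; 25 replicates with consecutive seeds are the
default. The replicate *mean* V_response feeds classification; minimal
doses aggregate replicates by the *median*. Means/medians are a
stabilizing choice over single draws; with ~10³–10⁵ voxels per tumor the
replicate spread of V_response is already small.

Minimal effective dose uses linearity: with the unit-dose field Φ(v),
voxel v is covered at dose M iff M ≥ φ_t(v)/Φ(v), so the smallest dose
with coverage ≥ f is the k-th smallest critical dose, k = ⌈f·N_vox⌉.
This is exact (a test pins it against a bisection search on coverage to
0.1%).

## Injection-site planning

Sites are chosen deterministically: the first at the occupied voxel
nearest the centroid, the rest by farthest-point seeding, then Lloyd
refinement (nearest-site partition of the occupied voxels, sites moved to
cluster centroids snapped to the nearest occupied voxel) to a fixed point
or 100 iterations, with lexicographic tie-breaks throughout. Equidistant
partitioning minimizes the heterogeneity of a superposed monotone-decaying
kernel; the coefficient of variation of the field (population SD / mean)
is reported as an audit metric. Lloyd minimizes within-cluster squared
distance, not the field CV directly, so the observed monotone decrease of
the CV across iterations is an empirical property (verified in tests on
spheres, not guaranteed for arbitrary masks). Dose is split equally
(m_j = total/N): no per-site weights are published, and equal split is
the only symmetric default. Site geometry is independent of total dose
and of the rate constants.

## Synthetic geometry

Real cohort tumors are known only by volume, so the replay and dose-law
paths use centered digital spheres at 1 mm isotropic spacing (CT-typical;
a 40 cm³ tumor is ~40k voxels). The ball is the set of the
N = round(V / voxel volume) voxel centers closest to the center —
equivalently the center-inside rule with a radius calibrated per volume —
because complete lattice-distance shells jump by tens of voxels and a
fixed nominal radius cannot guarantee even 2% volume accuracy at small V.
The boundary shell fills in lexicographic order, so masks are
deterministic.

What spheres do *not* capture: lobulation, cavitation, and elongation of
real lesions, which mostly *increase* the surface-to-volume ratio and
make distributed injections more favorable; and spatial heterogeneity of
D and k_f (fibrosis, necrosis, perfusion), which the model assumes away.
Passing cohort-replay tests therefore shows consistency of the pipeline
with the published analysis, not validation against real tumor shapes.
Mid-range per-patient V_response values (e.g. printed 57 or 72) depend on
the true segmented shapes and are monitored qualitatively only; in
practice the sphere replay reproduces 31/32 published binary predictions
at defaults.

## Transient solver

`transient_simulate` is a verification oracle, not part of the planning
path. It integrates the full system with forward Euler and a 7-point
Laplacian on the tumor's bounding box padded by 5λ (≈5 mm), uniform
coefficients inside and outside the tumor (the free-space assumption of
the asymptotic kernel), zero concentration at the box boundary, and the
dose loaded into the extracellular compartment of each site's voxel. The
default time step is 0.9 / (6D/h² + k_i + k_f), which implies the usual
explicit diffusion bound and additionally keeps φ_e non-negative at the
injection spike.

Numerical behavior worth knowing:

* Mass (extracellular + intracellular + V_f·φ_f) is conserved to ≪0.5%
  with k_r = 0 over 24 h; the only loss channel is the far boundary.
* Doubling the padding changes the solution on tumor voxels by <1%.
* The solution converges to the 1/(4π)-normalized kernel, which
  documents that the verbatim published asymptote omits that factor.
* Near a source, the 7-point stencil shows lattice anisotropy and
  screening dispersion: per-voxel errors up to ~13% within ~6 spacings of
  the source at h = λ, shrinking with refinement (~7% at h = λ/4).
  Equivalence tests therefore compare shell-averaged profiles at 0.5 mm
  and per-voxel values at 0.25 mm for r ≥ 2 mm, where agreement is <2%.

## Cohort replay and sensitivity

The packaged fixture transcribes the published 32-patient tables
(15 adenocarcinoma, 16 squamous, 1 large-cell). Printed-source
evaluations are exact re-tabulations; regenerated-source evaluations
rerun the model on sphere surrogates. The published text reports 25
responders while the printed outcome columns sum to 24; the fixture
follows the tables. Reported percentages follow the published rounding:
accuracy to the nearest integer where the publication prints integers
(72, 80), one decimal otherwise (62.5), and the squamous response rate
truncated to 68.7.

The sensitivity harness perturbs D, k_i, k_f and μ by ×0.1/×10 and
re-tallies the confusion matrix with identical threshold seeds, so
differences are attributable to the perturbation alone. A factor on μ is
interpreted as a factor on the IC50 *concentration scale*
(μ → μ + log₁₀ f): multiplying the log-mean itself by 10 would place
thresholds at 10⁻²⁵·⁹ mg/ml, where every voxel responds — a regime the
published sensitivity table visibly does not describe, whereas the
concentration-scale reading reproduces its ×0.1 row digit-for-digit.
Note that perturbing D, k_i or k_f changes λ by up to √10 and therefore
*does* change regenerated predictions for mid-size tumors in this model;
the published claim of complete invariance for those six perturbations is
not reproducible under any monotone reading (their printed rows are
digit-identical to baseline), and the corresponding acceptance test
documents the disagreement rather than hiding it.

The exact Mann–Whitney test enumerates the rank-sum null distribution by
a subset-sum recurrence (exact counts, no normal approximation), restricted
to ≤25 total observations and tie-free data across groups; scipy's exact
method serves as an independent cross-check in the tests.

## Dose-volume power law

For each injection count n, minimal doses on sphere surrogates at the 28
cohort volumes below 40 cm³ (the published validity range; the exact
volume grid used originally is unstated, so the cohort's own volumes are
the closest reconstruction) are fit by OLS of log₁₀(dose) on
log₁₀(volume) with classical t-based 95% CIs. At the defaults this yields
β ≈ 3.87 (1 injection) and β ≈ 2.55 (5 injections) with R² ≈ 0.98,
inside the published confidence intervals, and β decreases monotonically
from 1 to 5 injections. The true single-site law is exponential in
radius, so log–log residual curvature exists; over this volume range the
power law is nevertheless an excellent summary.

Splitting a fixed dose over more sites saves orders of magnitude at large
volumes: ~2.6 decades at 40 cm³ and ~0.9 at 4 cm³ for 1→5 injections at
the defaults. Spheres are the *best* case for a single central injection
(minimal surface-to-volume ratio), so these sphere-based ratios are lower
bounds on the savings expected for irregular lesions.

## Problem sizes and determinism

Default problem sizes — 1 mm voxels (up to ~230k voxels for the largest
cohort tumor), 25 threshold replicates, 0.25–0.5 mm grids for the
transient oracle on sub-cm³ phantoms — keep every documented workflow in
the seconds-to-minutes range on a single CPU. All stochastic operations
take explicit integer seeds; replicates use consecutive seeds and cohort
records disjoint seed blocks, so every result in this document is
bit-reproducible from (inputs, seed).

## Known limitations

* Sphere surrogates and spatially uniform D, k_f (no fibrosis, necrosis,
  or interstitial-pressure effects).
* The IC50 → asymptotic-concentration threshold mapping is assumed.
* Equal dose split only; no airway-accessibility constraints on sites.
* The power law is not extrapolated above 40 cm³.
* k_r is not calibrated here (response prediction does not use it).
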