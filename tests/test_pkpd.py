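import numpy as np
import pytest

from cisplan import (
    InjectionPlan,
    ModelParams,
    apportion_dose,
    decay_length,
    fluid_asymptote,
    place_sites,
    steady_state_field,
    transient_simulate,
)
from cisplan.geometry import pad_domain
from cisplan.pkpd import _snap_plan_to, total_mass


def single_site_plan(mask, dose, voxel_index=None):
    """Plan with one site at a given voxel (default: first occupied)."""
    idx = mask.occupied_indices()
    k = 0 if voxel_index is None else voxel_index
    centers = mask.occupied_centers_cm()
    return InjectionPlan(centers[k], np.array([dose]), idx[k])


class TestDecayLength:
    def test_default_value(self, params):
        # sqrt(2.47e-6 / 2.51e-4) = 0.0992 cm (~1 mm)
        assert decay_length(params) == pytest.approx(0.0992, abs=2e-4)

    def test_identity_when_rates_match_diffusivity(self):
        p = ModelParams(D=1.05e-4, k_i=1.05e-4, k_f=0.0)
        assert decay_length(p) == pytest.approx(1.0)

    def test_sqrt_scaling_in_D(self, params):
        p10 = params.replace(D=params.D * 10)
        assert decay_length(p10) == pytest.approx(decay_length(params) * np.sqrt(10))


class TestSteadyStateField:
    def test_point_kernel_value_at_1cm(self, params, line_mask):
        # independent scalar evaluation: k_i*m/(D*r) * exp(-r/L) at r = 1 cm
        mask = line_mask  # voxel k is k mm from voxel 0
        plan = single_site_plan(mask, 10.0)
        field = steady_state_field(mask, plan, params)
        expected = (1.05e-4 * 10) / (2.47e-6 * 1.0) * np.exp(-1.0 / 0.0992)
        assert expected == pytest.approx(1.78e-2, rel=5e-3)  # sanity of the oracle
        assert field.values[10] == pytest.approx(expected, rel=1e-3)

    def test_linearity_in_dose(self, params, sphere1):
        plan = apportion_dose(place_sites(sphere1, 3), 10.0)
        double = apportion_dose(plan, 20.0)
        f1 = steady_state_field(sphere1, plan, params)
        f2 = steady_state_field(sphere1, double, params)
        np.testing.assert_allclose(f2.values, 2.0 * f1.values, rtol=1e-12)

    def test_superposition_of_single_site_fields(self, params, sphere1):
        plan = apportion_dose(place_sites(sphere1, 3), 30.0)
        total = steady_state_field(sphere1, plan, params).values
        parts = sum(
            steady_state_field(
                sphere1,
                InjectionPlan(plan.sites_cm[j], plan.doses_mg[j : j + 1],
                              plan.voxel_indices[j]),
                params,
            ).values
            for j in range(3)
        )
        np.testing.assert_allclose(total, parts, rtol=1e-12)

    def test_monotone_decay_with_distance(self, params, line_mask):
        plan = single_site_plan(line_mask, 5.0)
        v = steady_state_field(line_mask, plan, params).values
        assert (np.diff(v[1:]) < 0).all()  # beyond the r_eff floor at the source

    def test_greens_modes_differ_by_4pi(self, params, sphere1):
        plan = apportion_dose(place_sites(sphere1, 2), 40.0)
        f_paper = steady_state_field(sphere1, plan, params)
        f_phys = steady_state_field(sphere1, plan, params.replace(greens_mode="physical"))
        np.testing.assert_allclose(
            f_paper.values, 4 * np.pi * f_phys.values, rtol=1e-12
        )

    def test_site_outside_mask_rejected(self, params, sphere1):
        idx = np.array([[0, 0, 0]])  # corner voxel of the grid is outside the ball
        assert not sphere1.occupancy[0, 0, 0]
        plan = InjectionPlan(np.zeros((1, 3)), np.array([1.0]), idx)
        with pytest.raises(ValueError, match="outside the mask"):
            steady_state_field(sphere1, plan, params)


class TestFluidAsymptote:
    def test_default_partition(self, params):
        # (k_f/(k_i+k_f)) * dose / V_f = 1.91e-3 mg/ml for 40 mg
        assert fluid_asymptote(params, 40.0) == pytest.approx(1.91e-3, rel=5e-3)

    def test_no_clearance_means_no_fluid_dose(self, params):
        p = params.replace(k_f=0.0)
        assert fluid_asymptote(p, 40.0) == 0.0

    def test_no_uptake_sends_everything_to_fluid(self, params):
        p = params.replace(k_i=0.0)
        assert fluid_asymptote(p, 40.0) == pytest.approx(40.0 / 12200.0)

    def test_renal_elimination_rejected(self, params):
        with pytest.raises(ValueError, match="transient_simulate"):
            fluid_asymptote(params.replace(k_r=1e-5), 40.0)


@pytest.fixture(scope="module")
def transient_run(params):
    """24 h single-site run on a 0.5 cm^3 sphere at 0.5 mm spacing."""
    from cisplan import make_sphere_mask

    mask = make_sphere_mask(0.5, spacing_mm=0.5)
    plan = apportion_dose(place_sites(mask, 1), 10.0)
    states = transient_simulate(mask, plan, params, t_end=24 * 3600.0)
    domain = pad_domain(mask, 5 * decay_length(params) * 10.0)
    return mask, plan, states, domain


class TestTransient:
    def test_mass_conserved_over_trajectory(self, params, transient_run):
        _, _, states, domain = transient_run
        masses = np.array([total_mass(s, domain, params) for s in states])
        np.testing.assert_allclose(masses, 10.0, rtol=5e-3)

    def test_phi_i_nondecreasing(self, transient_run):
        _, _, states, _ = transient_run
        for a, b in zip(states, states[1:]):
            assert (b.phi_i >= a.phi_i - 1e-15).all()

    def test_intracellular_uptake_fraction(self, params, transient_run):
        # limiting captured fraction = k_i/(k_i+k_f) = 0.418
        _, _, states, domain = transient_run
        final = states[-1]
        frac = final.phi_i.sum() * domain.voxel_volume_cm3 / 10.0
        assert frac == pytest.approx(params.k_i / (params.k_i + params.k_f), rel=5e-3)

    def test_shell_profile_matches_physical_kernel(self, params, transient_run):
        # radial shell means of phi_i vs the 1/(4 pi) normalized kernel:
        # confirms the normalization and the decay constant; per-voxel
        # deviations (7-point lattice anisotropy) are larger near the source
        mask, plan, states, domain = transient_run
        from cisplan import steady_state_field

        snapped = _snap_plan_to(domain, plan)
        f = steady_state_field(domain, snapped, params.replace(greens_mode="physical"))
        idx = domain.occupied_indices()
        num = states[-1].phi_i[idx[:, 0], idx[:, 1], idx[:, 2]]
        r = np.linalg.norm(domain.occupied_centers_cm() - snapped.sites_cm[0], axis=1)
        h = domain.voxel_edge_cm
        L = decay_length(params)
        edges = np.arange(2 * h, 3 * L, h)
        for lo, hi in zip(edges, edges[1:]):
            sel = (r >= lo) & (r < hi)
            if sel.sum() < 5:
                continue
            assert num[sel].mean() == pytest.approx(f.values[sel].mean(), rel=0.05)

    def test_no_diffusion_limit_single_compartment(self, params):
        # D -> 0, k_f = 0: site voxel tends to m / V_voxel
        from cisplan import TumorMask

        occ = np.ones((3, 3, 3), dtype=bool)
        mask = TumorMask(occ, (1.0, 1.0, 1.0))
        plan = single_site_plan(mask, 2.0, voxel_index=13)  # center voxel
        p = params.replace(D=1e-12, k_f=0.0)
        states = transient_simulate(mask, plan, p, t_end=1.2e5, dt=400.0, pad_mm=1.0)
        final = states[-1]
        expected = 2.0 / mask.voxel_volume_cm3  # 2000 mg/ml
        assert final.phi_i.max() == pytest.approx(expected, rel=2e-3)

    def test_pad_doubling_changes_solution_under_1pct(self, params):
        from cisplan import make_sphere_mask

        mask = make_sphere_mask(0.3, spacing_mm=0.5)
        plan = apportion_dose(place_sites(mask, 1), 10.0)
        L_mm = decay_length(params) * 10.0
        sols = []
        for pad in (5 * L_mm, 10 * L_mm):
            states = transient_simulate(mask, plan, params, t_end=12 * 3600.0, pad_mm=pad)
            dom = pad_domain(mask, pad)
            idx = dom.occupied_indices()
            phi = states[-1].phi_i[idx[:, 0], idx[:, 1], idx[:, 2]]
            order = np.lexsort(dom.occupied_centers_cm().T)
            sols.append(phi[order])
        np.testing.assert_allclose(sols[0], sols[1], rtol=0.01)

    def test_trajectory_csv_export(self, tmp_path, params, transient_run):
        import pandas as pd

        from cisplan.pkpd import trajectory_to_csv

        _, _, states, domain = transient_run
        path = tmp_path / "traj.csv"
        trajectory_to_csv(states, domain, str(path))
        df = pd.read_csv(path)
        assert len(df) == len(states)
        assert df["t_s"].is_monotonic_increasing
        assert df["mass_intracellular_mg"].is_monotonic_increasing

    def test_unstable_step_rejected(self, params, sphere1):
        plan = apportion_dose(place_sites(sphere1, 1), 1.0)
        with pytest.raises(ValueError, match="stability"):
            transient_simulate(sphere1, plan, params, t_end=3600.0, dt=1e6)

    def test_nonpositive_t_end_rejected(self, params, sphere1):
        plan = apportion_dose(place_sites(sphere1, 1), 1.0)
        with pytest.raises(ValueError):
            transient_simulate(sphere1, plan, params, t_end=0.0)


class TestModelParams:
    def test_defaults_are_printed_values(self, params):
        assert (params.D, params.k_i, params.k_f) == (2.47e-6, 1.05e-4, 1.46e-4)
        assert params.V_f == 12200.0
        assert (params.mu, params.sigma) == (-2.59, 0.50)
        assert params.response_fraction == 0.66

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"D": 0.0},
            {"V_f": -1.0},
            {"k_i": -1e-5},
            {"k_i": 0.0, "k_f": 0.0},
            {"sigma": -0.1},
            {"response_fraction": 1.0},
            {"greens_mode": "bogus"},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)
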