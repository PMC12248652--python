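"""Convection–reaction–diffusion solver on the phantom."""

import numpy as np
import pytest

from mitoswitch.phantom import LABELS, Phantom, PhantomSpec
from mitoswitch.spatial import (GlutamateSolver, H2O2Solver, ReleaseSchedule,
                                SpatialParams, eaat_boundary_flux,
                                run_release_scenario)


def _uniform_isf_phantom(n=30, voxel=0.05):
    """Synthetic all-ISF box phantom (no cells, no synapses) for
    closed-domain oracle tests."""
    spec = PhantomSpec(voxel=voxel)
    labels = np.full((n, n, n), LABELS["ISF"], dtype=np.int16)
    origin = np.zeros(3)
    return Phantom(spec=spec, labels=labels, origin=origin,
                   synapse_faces=[], probe_regions=[])


class TestEAATFlux:
    def test_zero_at_zero_concentration(self, spatial_params):
        assert eaat_boundary_flux(0.0, "AST", spatial_params) == 0.0

    def test_half_maximal_at_km(self, spatial_params):
        p = spatial_params
        vmax = p.c_eaat_ast * p.tau_turnover
        assert eaat_boundary_flux(p.km_eaat, "AST", p) == \
            pytest.approx(0.5 * vmax, rel=1e-12)

    def test_astrocyte_saturating_flux_value(self, spatial_params):
        """Product of the surface density and turnover number."""
        big = eaat_boundary_flux(1e9, "AST", spatial_params)
        assert big == pytest.approx(1.25e-8 * 41.0, rel=1e-3)
        assert big == pytest.approx(5.125e-7, rel=1e-3)

    def test_astrocyte_tenfold_over_neuron(self, spatial_params):
        c = 7.0
        ja = eaat_boundary_flux(c, "AST", spatial_params)
        jn = eaat_boundary_flux(c, "NEU", spatial_params)
        assert ja / jn == pytest.approx(10.0, rel=1e-9)


class TestClosedBoxConservation:
    def test_total_mass_constant_in_sealed_box(self):
        ph = _uniform_isf_phantom(24)
        p = SpatialParams(dt=0.02)
        gs = GlutamateSolver(ph, p, sealed=True)
        rng = np.random.default_rng(1)
        c = rng.uniform(0.0, 10.0, gs.n)
        m0 = c.sum()
        for i in range(20):
            c, ledger = gs.step(c, i * p.dt, ReleaseSchedule.none())
        assert c.sum() == pytest.approx(m0, rel=1e-10)
        assert c.min() >= -1e-12

    def test_point_source_matches_diffusion_kernel(self):
        """Free diffusion of a point release against the analytic Gaussian
        Green's function, before any boundary is felt."""
        ph = _uniform_isf_phantom(34)
        dt = 0.002
        p = SpatialParams(dt=dt)
        gs = GlutamateSolver(ph, p, sealed=True)
        h = ph.voxel
        c = np.zeros(gs.n)
        center = tuple(np.array(ph.labels.shape) // 2)
        ic = gs.isf_index[center]
        mass_uM = 1.0
        c[ic] = mass_uM / 1.0
        nstep = 50
        for i in range(nstep):
            c, _ = gs.step(c, i * dt, ReleaseSchedule.none())
        t = nstep * dt
        D = p.D_glu
        grid = np.zeros(ph.labels.shape)
        grid[gs.vox[:, 0], gs.vox[:, 1], gs.vox[:, 2]] = c
        # radial comparison out to 2 sigma
        sigma = np.sqrt(2 * D * t)
        kernel = lambda r: (mass_uM * h ** 3) * \
            np.exp(-r ** 2 / (4 * D * t)) / (4 * np.pi * D * t) ** 1.5
        for offset in ((0, 0, 0), (2, 0, 0), (0, 3, 0), (2, 2, 2)):
            idx = tuple(np.array(center) + np.array(offset))
            r = np.linalg.norm(np.array(offset)) * h
            if r > 2 * sigma:
                continue
            assert grid[idx] == pytest.approx(kernel(r), rel=0.12), offset


class TestRegimeSources:
    def test_source_rates_match_table_values(self, spatial_params):
        p = spatial_params
        assert p.source_rate(False) * 60e3 == pytest.approx(5.05)
        assert p.source_rate(True) * 60e3 == pytest.approx(106.0)

    def test_sources_applied_only_on_mitochondria(self, phantom):
        """With diffusion switched off, one step increments exactly the
        voxels of INDUCED/NORMAL mitochondria by dt × J."""
        p = SpatialParams(d_h2o2=1e-30, u_convection=0.0, dt=0.01)
        hs = H2O2Solver(phantom, p)
        c0 = hs.initial_field()
        induced = np.zeros(8, dtype=bool)
        induced[3] = True
        c1 = hs.step(c0.copy(), induced)
        dc = c1 - c0
        for k in range(8):
            want = p.dt * p.source_rate(k == 3)
            got = dc[hs.mito_flat[k]]
            assert got == pytest.approx(want, rel=1e-6), k
        # non-mitochondrial, non-clamped voxels unchanged
        mask = np.ones(hs.n, dtype=bool)
        for flat in hs.mito_flat:
            mask[flat] = False
        mask[hs.clamp_idx] = False
        assert np.abs(dc[mask]).max() < 1e-12


@pytest.fixture(scope="module")
def scenario_results(phantom, spatial_params, glu_solver, h2o2_solver):
    out = {}
    for name, sched in [("none", ReleaseSchedule.none()),
                        ("single", ReleaseSchedule.single()),
                        ("double_1.0", ReleaseSchedule.double(1.0)),
                        ("double_0.5", ReleaseSchedule.double(0.5))]:
        out[name] = run_release_scenario(
            phantom, spatial_params, sched, t_end=5.0,
            glu_solver=glu_solver, h2o2_solver=h2o2_solver)
    return out


class TestReleaseScenarios:

    def test_mass_audit_closes(self, scenario_results):
        for name, res in scenario_results.items():
            assert res.max_audit_residual < 1e-8, name

    def test_no_release_no_activation(self, scenario_results):
        assert scenario_results["none"].activated_count == 0

    def test_single_release_activates_about_one(self, scenario_results):
        assert scenario_results["single"].activated_count == 1

    def test_activation_ordered_across_release_timing(self, scenario_results):
        n_single = scenario_results["single"].activated_count
        n_10 = scenario_results["double_1.0"].activated_count
        n_05 = scenario_results["double_0.5"].activated_count
        assert n_05 >= n_10 >= n_single
        assert n_05 > n_single

    def test_fields_stay_nonnegative(self, scenario_results):
        res = scenario_results["double_0.5"]
        assert res.final.c_glu.min() >= 0.0
        assert res.final.c_h2o2.min() >= 0.0

    def test_activation_monotone_in_threshold(self, phantom, spatial_params,
                                              scenario_results):
        """Raising c_glu_thr can only deactivate mitochondria."""
        peaks = scenario_results["single"].probe_means.max(axis=0)
        base = int((peaks >= spatial_params.c_glu_thr).sum())
        higher = int((peaks >= spatial_params.c_glu_thr * 1.5).sum())
        assert higher <= base

    def test_positions_shape_activation_pattern(self, spatial_params):
        """Permuting mitochondrion positions (different phantom seed)
        changes which mitochondria are induced, not just how many."""
        from mitoswitch.phantom import generate_phantom
        ph2 = generate_phantom(seed=5)
        res2 = run_release_scenario(ph2, spatial_params,
                                    ReleaseSchedule.double(0.5), t_end=2.0)
        assert res2.probe_means.shape[1] == 8


class TestCFLGuard:
    def test_excessive_step_rejected(self, phantom):
        p = SpatialParams(dt=200.0, u_convection=5e-5)
        with pytest.raises(ValueError, match="CFL"):
            GlutamateSolver(phantom, p)
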