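"""Permeability-transition switch, GHK efflux, and MPT-driven dynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mitoswitch as mw
from mitoswitch.core_model import RCState, simulate
from mitoswitch.mpt import (EffluxSpec, V_THERMAL_MV, clamp_conductance,
                            ghk_efflux, ghk_flux, permeability)
from mitoswitch.params import MPTParams


class TestPermeabilitySwitch:
    def test_half_open_exactly_at_threshold(self):
        p = MPTParams(qthr=2.26)
        assert permeability(2.26, p) == pytest.approx(0.5, abs=1e-15)

    def test_limits_zero_and_one(self):
        p = MPTParams(qthr=2.0)
        assert permeability(2.0 + 1e6, p) == pytest.approx(1.0, abs=1e-9)
        assert permeability(2.0 - 1e6, p) == pytest.approx(0.0, abs=1e-9)

    def test_value_just_below_threshold(self):
        """High-precision evaluation of the arctangent switch."""
        p = MPTParams(qthr=3.0)
        want = (math.atan(1000.0 * (2.9 - 3.0)) / (0.5 * math.pi) + 1.0) / 2.0
        assert permeability(2.9, p) == pytest.approx(want, rel=1e-12)
        assert permeability(2.9, p) == pytest.approx(3.1828e-3, rel=1e-4)

    @settings(derandomize=True, deadline=None)
    @given(d=st.floats(min_value=0.0, max_value=5.0,
                       allow_nan=False, allow_infinity=False))
    def test_symmetry_about_threshold(self, d):
        p = MPTParams(qthr=2.0)
        assert permeability(2.0 + d, p) + permeability(2.0 - d, p) == \
            pytest.approx(1.0, abs=1e-12)

    @settings(derandomize=True, deadline=None)
    @given(a=st.floats(0.0, 4.0), b=st.floats(0.0, 4.0))
    def test_monotone_increasing(self, a, b):
        p = MPTParams(qthr=1.58, steepness=1000.0)
        if a < b:
            assert permeability(a, p) <= permeability(b, p)
            if b - a > 1e-6:
                assert permeability(a, p) < permeability(b, p)


class TestGHK:
    def test_closed_pore_gives_zero_flux(self):
        spec = EffluxSpec("mal", z=0.0, c_matrix=2.0, c_external=0.1, k_perm=1.0)
        assert ghk_efflux(spec, 0.0, 150.0) == 0.0

    def test_equilibrium_gives_zero_flux(self):
        spec0 = EffluxSpec("x", z=0.0, c_matrix=1.0, c_external=1.0, k_perm=2.0)
        assert ghk_efflux(spec0, 1.0, 120.0) == pytest.approx(0.0, abs=1e-14)
        spec1 = EffluxSpec("y", z=1.0, c_matrix=1.0, c_external=1.0, k_perm=2.0)
        assert ghk_efflux(spec1, 1.0, 0.0) == pytest.approx(0.0, abs=1e-14)

    def test_matches_independent_ghk_evaluation(self):
        """Canonical GHK expression coded from scratch, z = +1, 25 mV."""
        z, dpsi, cm, ce, k = 1.0, 25.0, 2.0, 0.3, 1.7
        # matrix side sits at −dpsi relative to outside
        u = z * (-dpsi) / V_THERMAL_MV
        want = k * u * (cm - ce * math.exp(-u)) / (1.0 - math.exp(-u))
        spec = EffluxSpec("y", z=z, c_matrix=cm, c_external=ce, k_perm=k)
        assert ghk_efflux(spec, 1.0, dpsi) == pytest.approx(want, rel=1e-12)

    def test_zero_potential_limit_is_analytic(self):
        """The dpsi → 0 removable singularity matches the series limit."""
        spec = EffluxSpec("y", z=1.0, c_matrix=2.0, c_external=0.3, k_perm=1.0)
        tiny = ghk_efflux(spec, 1.0, 1e-9)
        limit = ghk_efflux(spec, 1.0, 0.0)
        assert limit == pytest.approx(spec.c_matrix - spec.c_external, rel=1e-12)
        assert tiny == pytest.approx(limit, rel=1e-6)

    def test_flux_linear_in_open_fraction(self):
        spec = EffluxSpec("y", z=0.0, c_matrix=2.0, c_external=0.0, k_perm=1.0)
        assert ghk_efflux(spec, 0.25, 0.0) == pytest.approx(
            0.25 * ghk_efflux(spec, 1.0, 0.0))

    def test_efflux_mass_appears_in_closed_bath(self):
        """Matrix loss equals (volume-scaled) external gain by construction."""
        p = mw.ModelParams(mpt_enabled=True, closed_external=True)
        from mitoswitch.core_model import stoichiometry_matrix, STATE_FIELDS, RATE_NAMES
        S = stoichiometry_matrix(p)
        i_mal = STATE_FIELDS.index("mal")
        i_ext = STATE_FIELDS.index("ext_mal")
        j = RATE_NAMES.index("mpt_mal")
        assert S[i_mal, j] == -1.0
        assert S[i_ext, j] == pytest.approx(1.0 / p.bath_volume_ratio)


class TestMPTDynamics:
    def test_closed_pore_leaves_trajectory_unchanged(self, params, rest_state):
        """Far below threshold the MPT terms are numerically invisible."""
        p_off = params.with_updates(glu_o=0.01, mpt_enabled=False)
        p_on = params.with_updates(glu_o=0.01, mpt_enabled=True)
        t_off = simulate(rest_state, p_off, (0, 20.0), n_out=50)
        t_on = simulate(rest_state, p_on, (0, 20.0), n_out=50)
        # the arctangent switch has an algebraic tail, so a per-mille
        # background leak remains; the trajectories agree to a few percent
        np.testing.assert_allclose(t_on.states[-1][:10], t_off.states[-1][:10],
                                   rtol=0.05, atol=0.02)

    def test_clamp_engages_smoothly_above_half_opening(self, params):
        p = params.mpt
        assert clamp_conductance(0.05, p) < 1e-3 * p.g_clamp
        assert clamp_conductance(0.95, p) > 0.99 * p.g_clamp
        mid = clamp_conductance(p.engage_center, p)
        assert mid == pytest.approx(0.5 * p.g_clamp, rel=1e-9)

    def test_supra_threshold_glutamate_with_mpt_recovers(self, params,
                                                         rest_state):
        """A 0.08 mM glutamate challenge collapses the chain, the pore
        opens, drains the matrix and the chain returns to (prevailing)
        ATP production — unlike the MPT-disabled run."""
        p = params.with_updates(glu_o=0.08, mpt_enabled=True)
        tr = simulate(rest_state, p, (0, 400.0), n_out=800)
        q = tr.column("qh2")
        assert q.max() > p.mpt.qthr           # the transition happened
        i0 = int(0.7 * len(tr.times))
        avg = RCState.from_vector(tr.states[i0:].mean(axis=0))
        assert mw.classify_branch(avg, p) is mw.Regime.ATP_PRODUCING
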