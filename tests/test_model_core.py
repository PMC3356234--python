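import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chondrosim.model_core import (ParameterSet, SystemState,
                                   h_identically_one_mode, reaction_rhs,
                                   saturation, threshold_H)

from .conftest import random_positive_state
from .helpers import transcribed_rates


class TestSaturation:
    @pytest.mark.parametrize("x, lam, expected", [
        (0.0, 1.7, 0.0),
        (1.7, 1.7, 0.5),
        (3.0, 1.0, 0.75),
    ])
    def test_reference_points(self, x, lam, expected):
        assert saturation(x, lam) == pytest.approx(expected)

    def test_asymptote(self):
        assert saturation(1e6 * 2.0, 2.0) > 0.999

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            saturation(-0.1, 1.0)
        with pytest.raises(ValueError):
            saturation(1.0, 0.0)

    @given(x1=st.floats(0, 1e6), x2=st.floats(0, 1e6),
           lam=st.floats(1e-6, 1e3))
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_bounded(self, x1, x2, lam):
        lo, hi = sorted((x1, x2))
        s_lo, s_hi = saturation(lo, lam), saturation(hi, lam)
        assert 0.0 <= s_lo <= s_hi < 1.0


class TestThresholdGate:
    def test_orientation(self):
        # the gate PERMITS switching only below the critical level:
        # negative argument (P < P_c) -> 1, at or above -> 0
        assert threshold_H(-0.5) == 1.0
        assert threshold_H(0.0) == 0.0
        assert threshold_H(0.3) == 0.0

    def test_vectorized(self):
        np.testing.assert_array_equal(
            threshold_H(np.array([-1.0, 0.0, 2.0])), [1.0, 0.0, 0.0])


def _states(rng, params, n=5):
    now = random_positive_state(rng, n, t=0.0)
    tau1 = random_positive_state(rng, n, t=-params.tau_1)
    tau2 = random_positive_state(rng, n, t=-params.tau_2)
    return now, tau1, tau2


class TestReactionRhs:
    def test_vacuum_is_fixed_point(self, ref_params):
        n = 4
        zero = SystemState.zeros(n)
        z1 = SystemState.zeros(n, t=-ref_params.tau_1)
        z2 = SystemState.zeros(n, t=-ref_params.tau_2)
        d = reaction_rhs(zero, z1, z2, ref_params)
        for name, arr in d.items():
            np.testing.assert_array_equal(arr, 0.0, err_msg=name)

    def test_healthy_field_is_stationary(self, ref_params):
        # uninjured tissue: C = C0, U = U0, everything else zero
        n = 4
        s = SystemState.zeros(n)
        s.C[:] = 100.0
        s.U[:] = 1.0
        hist1 = SystemState.from_stack(-ref_params.tau_1, s.stack())
        hist2 = SystemState.from_stack(-ref_params.tau_2, s.stack())
        d = reaction_rhs(s, hist1, hist2, ref_params)
        for name, arr in d.items():
            np.testing.assert_array_equal(arr, 0.0, err_msg=name)

    def test_necrotic_pool_only(self, ref_params):
        # with only necrotic cells, the sole fluxes are DAMP release and
        # the decay of the pool itself
        n = 3
        d0 = 42.0
        s = SystemState.zeros(n)
        s.D_N[:] = d0
        z1 = SystemState.zeros(n, t=-ref_params.tau_1)
        z2 = SystemState.zeros(n, t=-ref_params.tau_2)
        d = reaction_rhs(s, z1, z2, ref_params)
        np.testing.assert_allclose(d["M"], ref_params.sigma_M * d0)
        np.testing.assert_allclose(d["D_N"], -ref_params.mu_DN * d0)
        for name in ("R", "F", "P", "U", "C", "S_T", "S_A", "D_A"):
            np.testing.assert_array_equal(d[name], 0.0, err_msg=name)

    def test_catabolic_pool_only(self, ref_params):
        # catabolic cells produce ROS and TNF; with zero TNF at t-tau_1
        # the EPOR-activation term vanishes, and apoptosis needs DAMPs
        n = 3
        s0 = 17.0
        s = SystemState.zeros(n)
        s.S_T[:] = s0
        h1 = SystemState.zeros(n, t=-ref_params.tau_1)
        h1.S_T[:] = s0
        h2 = SystemState.zeros(n, t=-ref_params.tau_2)
        h2.S_T[:] = s0
        d = reaction_rhs(s, h1, h2, ref_params)
        np.testing.assert_allclose(d["R"], ref_params.sigma_R * s0)
        np.testing.assert_allclose(d["F"], ref_params.sigma_F * s0)
        np.testing.assert_array_equal(d["S_A"], 0.0)
        np.testing.assert_array_equal(d["S_T"], 0.0)

    def test_matches_independent_transcription(self, ref_params):
        rng = np.random.default_rng(7)
        for _ in range(20):
            now, t1, t2 = _states(rng, ref_params, n=6)
            got = reaction_rhs(now, t1, t2, ref_params)
            want = transcribed_rates(now.stack(), t1.stack(), t2.stack(),
                                     ref_params)
            for i, name in enumerate(
                    ("R", "M", "F", "P", "U", "C", "S_T", "S_A", "D_N",
                     "D_A")):
                np.testing.assert_allclose(got[name], want[i], rtol=1e-12,
                                           err_msg=name)

    def test_cell_bookkeeping_identity(self, ref_params):
        # cells change state but are never created or destroyed: the
        # pointwise sum of the healthy, sick and apoptotic derivatives
        # vanishes identically
        rng = np.random.default_rng(11)
        for _ in range(50):
            now, t1, t2 = _states(rng, ref_params, n=4)
            d = reaction_rhs(now, t1, t2, ref_params)
            total = d["C"] + d["S_T"] + d["S_A"] + d["D_A"]
            np.testing.assert_allclose(
                total, 0.0,
                atol=1e-13 * max(1.0, np.abs(d["C"]).max()))

    def test_grid_mismatch_raises(self, ref_params):
        a = SystemState.zeros(4)
        b = SystemState.zeros(5, t=-ref_params.tau_1)
        c = SystemState.zeros(4, t=-ref_params.tau_2)
        with pytest.raises(ValueError, match="grid mismatch"):
            reaction_rhs(a, b, c, ref_params)

    def test_nan_names_field_and_node(self, ref_params):
        s = SystemState.zeros(4)
        s.F[2] = np.nan
        z1 = SystemState.zeros(4, t=-ref_params.tau_1)
        z2 = SystemState.zeros(4, t=-ref_params.tau_2)
        with pytest.raises(FloatingPointError, match=r"F at node 2"):
            reaction_rhs(s, z1, z2, ref_params)

    def test_delayed_stamp_checked(self, ref_params):
        s = SystemState.zeros(4)
        wrong = SystemState.zeros(4, t=-1.0)
        z2 = SystemState.zeros(4, t=-ref_params.tau_2)
        with pytest.raises(ValueError, match="tau_1"):
            reaction_rhs(s, wrong, z2, ref_params)


class TestHIdenticallyOne:
    def test_gate_always_open(self, ref_params):
        variant = h_identically_one_mode(ref_params)
        assert np.isinf(variant.P_c)
        # the gate evaluates to one for any finite EPO level
        assert threshold_H(1e9 - variant.P_c) == 1.0

    def test_irrelevant_when_switch_terms_vanish(self, ref_params):
        # H multiplies only the beta terms, so with beta_1 = beta_2 = 0
        # the variant changes nothing
        rng = np.random.default_rng(3)
        p0 = ref_params.with_updates(beta_1=0.0, beta_2=0.0)
        p1 = h_identically_one_mode(p0)
        now, t1, t2 = _states(rng, p0, n=5)
        d0 = reaction_rhs(now, t1, t2, p0)
        d1 = reaction_rhs(now, t1, t2, p1)
        for name in d0:
            np.testing.assert_array_equal(d0[name], d1[name], err_msg=name)


class TestParameterSet:
    def test_strict_positivity_enforced(self):
        with pytest.raises(ValueError, match="lambda_F"):
            ParameterSet(lambda_F=0.0)
        with pytest.raises(ValueError, match="alpha"):
            ParameterSet(alpha=-0.1)

    def test_nonnegativity_enforced(self):
        with pytest.raises(ValueError, match="sigma_P"):
            ParameterSet(sigma_P=-1e-3)

    def test_zero_rates_allowed(self):
        p = ParameterSet(sigma_P=0.0, gamma=0.0)
        assert p.sigma_P == 0.0

    def test_with_updates_rejects_unknown(self, ref_params):
        with pytest.raises(ValueError, match="unknown parameter"):
            ref_params.with_updates(sigma_X=1.0)

    def test_roundtrip(self, ref_params):
        again = ParameterSet.from_dict(ref_params.to_dict())
        assert again == ref_params
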