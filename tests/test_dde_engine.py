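import numpy as np
import pytest

from chondrosim.dde_engine import (ConstantHistory, checkpoint_roundtrip,
                                   integrate, make_checkpoint, resume,
                                   solve_dde)
from chondrosim.model_core import SystemState
from chondrosim.scenarios import make_injury_initial_condition, run_scenario

from .helpers import lumped_dde_solution, scalar_delay_exact


class TestScalarProblems:
    def test_exponential_decay(self):
        delta, u0 = 0.8, 3.0
        t_eval = np.linspace(0, 10, 21)
        sol = solve_dde(lambda t, y, d: -delta * y, (0, 10.0),
                        np.array([u0]), t_eval=t_eval, rtol=1e-8,
                        atol=1e-12)
        np.testing.assert_allclose(sol.y[:, 0], u0 * np.exp(-delta * t_eval),
                                   rtol=1e-6)

    def test_delayed_decay_matches_method_of_steps_closed_form(self):
        # u'(t) = -u(t - 1) with unit history: piecewise polynomial,
        # 1 - t on [0, 1] and 1 - t + (t-1)^2/2 on [1, 2]
        tau = 1.0
        t_eval = np.linspace(0, 2 * tau, 41)
        sol = solve_dde(lambda t, y, d: -d[0], (0, 2 * tau),
                        np.array([1.0]), delays=(tau,),
                        history=ConstantHistory(np.array([1.0]),
                                                t_start=0.0),
                        t_eval=t_eval, rtol=1e-8, atol=1e-12)
        np.testing.assert_allclose(sol.y[:, 0], scalar_delay_exact(t_eval),
                                   atol=1e-6)

    def test_rejects_bad_spans_and_delays(self):
        f = lambda t, y, d: -y
        with pytest.raises(ValueError):
            solve_dde(f, (1.0, 0.0), np.array([1.0]))
        with pytest.raises(ValueError):
            solve_dde(f, (0.0, 1.0), np.array([1.0]), delays=(-1.0,),
                      history=ConstantHistory(np.array([1.0])))
        with pytest.raises(ValueError):
            solve_dde(f, (0.0, 1.0), np.array([1.0]), delays=(0.5,))

    def test_nonfinite_rhs_reported(self):
        def blow_up(t, y, d):
            return np.array([np.inf if t > 0.5 else -y[0]])
        with pytest.raises(FloatingPointError, match="component 0"):
            solve_dde(blow_up, (0.0, 1.0), np.array([1.0]))


class TestModelIntegration:
    def test_uniform_field_matches_lumped_system(self, ref_params,
                                                 coarse_spec):
        # spatially uniform data: diffusion vanishes identically and
        # every node must follow the 10-variable lumped delay system
        grid = coarse_spec.build_grid()
        n = grid.n_nodes
        initial = SystemState.zeros(n)
        initial.C[:] = 100.0
        initial.U[:] = 1.0
        initial.D_N[:] = 30.0
        pre = SystemState.zeros(n)
        pre.C[:] = 100.0
        pre.U[:] = 1.0
        t_end = 72.0
        traj = integrate(initial, ConstantHistory(pre.stack()), ref_params,
                         grid, t_end, rtol=1e-8, atol=1e-12, output_dt=6.0)
        # uniformity is preserved exactly
        spread = np.ptp(traj.data, axis=2)
        assert spread.max() == 0.0
        ref = lumped_dde_solution(initial.stack()[:, 0], pre.stack()[:, 0],
                                  ref_params, t_end, traj.times)
        scale = np.maximum(np.abs(ref).max(axis=0), 1e-3)
        err = np.abs(traj.data[:, :, 0] - ref) / scale
        assert err.max() < 1e-5, err.max()

    def test_first_snapshot_is_initial_condition(self, coarse_spec):
        traj = run_scenario(coarse_spec, warn_boundary=False)
        grid = coarse_spec.build_grid()
        initial, _ = make_injury_initial_condition(coarse_spec, grid)
        np.testing.assert_array_equal(traj.data[0], initial.stack())
        assert np.all(np.diff(traj.times) > 0)

    def test_tolerance_halving_convergence(self, ref_params, coarse_spec):
        t1 = run_scenario(coarse_spec, warn_boundary=False)
        tighter = type(coarse_spec)(
            **{**coarse_spec.__dict__, "rtol": coarse_spec.rtol / 4})
        t2 = run_scenario(tighter, warn_boundary=False)
        diff = np.abs(t1.data[-1] - t2.data[-1]).max()
        scale = np.abs(t1.data[-1]).max()
        assert diff < 1e-4 * scale

    def test_nonnegativity_of_reference_run(self, ref_with_epo_traj):
        assert ref_with_epo_traj.data.min() >= 0.0

    def test_matrix_monotone_nonincreasing(self, ref_with_epo_traj):
        U = ref_with_epo_traj.field("U")
        assert np.all(np.diff(U, axis=0) <= 1e-12)

    def test_matrix_constant_without_tnf(self, ref_params, coarse_spec):
        # no catabolic source -> F stays zero -> U never degrades
        grid = coarse_spec.build_grid()
        n = grid.n_nodes
        initial = SystemState.zeros(n)
        initial.C[:] = 50.0
        initial.U[:] = 2.0
        traj = integrate(initial, ConstantHistory(initial.stack()),
                         ref_params, grid, 24.0, atol=1e-12)
        np.testing.assert_array_equal(traj.field("U"),
                                      np.full_like(traj.field("U"), 2.0))
        np.testing.assert_array_equal(traj.field("F"), 0.0)

    def test_smoothed_gate_converges_to_hard_switch(self, ref_params):
        # the logistic gate is a numerical device; as its width shrinks
        # the trajectory approaches the discrete-switch solution
        from chondrosim.metrics import lesion_radius
        from chondrosim.scenarios import ScenarioSpec, run_scenario

        def day3_radius(width):
            spec = ScenarioSpec(
                name="w", params=ref_params.with_updates(h_width=width),
                n_nodes=40, r_max=2.0, horizon=72.0, atol=1e-12)
            traj = run_scenario(spec, warn_boundary=False)
            return lesion_radius(traj.state(-1), traj.grid, 100.0)

        hard = day3_radius(0.0)
        gaps = [abs(day3_radius(w) - hard) for w in (0.2, 0.02)]
        assert gaps[1] <= gaps[0]
        assert gaps[1] < 0.05


class TestCheckpointing:
    @pytest.fixture()
    def dense_traj(self, coarse_spec):
        return run_scenario(coarse_spec, keep_dense=True,
                            warn_boundary=False)

    def test_restart_midway_matches_straight_run(self, dense_traj):
        restarted = checkpoint_roundtrip(dense_traj, 24.0)
        i = np.searchsorted(dense_traj.times, 24.0)
        scale = np.abs(dense_traj.data[-1]).max()
        diff = np.abs(restarted.data[-1] - dense_traj.data[-1]).max()
        assert restarted.times[-1] == dense_traj.times[-1]
        # within a small multiple of the integration tolerance
        assert diff < 10 * dense_traj.rtol * scale * 10

    def test_restart_at_zero_is_identical(self, dense_traj):
        restarted = checkpoint_roundtrip(dense_traj, 0.0)
        np.testing.assert_array_equal(restarted.data, dense_traj.data)

    def test_restart_outside_span_raises(self, dense_traj):
        with pytest.raises(ValueError, match="outside"):
            make_checkpoint(dense_traj, dense_traj.t_end + 1.0)

    def test_missing_history_tail_raises(self, coarse_spec):
        lean = run_scenario(coarse_spec, warn_boundary=False)
        with pytest.raises(ValueError, match="dense history"):
            make_checkpoint(lean, 24.0)

    def test_resume_from_serialized_dict(self, dense_traj, coarse_spec):
        cp = make_checkpoint(dense_traj, 24.0)
        again = resume(cp, dense_traj.grid, dense_traj.t_end)
        assert again.times[-1] == dense_traj.t_end


class TestDeterminism:
    def test_bit_identical_reruns(self, coarse_spec):
        a = run_scenario(coarse_spec, warn_boundary=False)
        b = run_scenario(coarse_spec, warn_boundary=False)
        np.testing.assert_array_equal(a.data, b.data)
        assert a.diagnostics == b.diagnostics
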