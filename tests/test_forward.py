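"""Forward model: bilinear neuronal drift, balloon hemodynamics, BOLD
readout, and the fixed-step RK4 integrator."""

import numpy as np
import pytest

from rtdcm.data import ExperimentDesign
from rtdcm.forward import (ConnectivityParams, HemodynamicParams,
                           NeuralHemoState, SimulationDiverged,
                           _HAVE_NUMBA, assert_stable, bold_observation,
                           hemodynamic_drift, neuronal_drift,
                           simulate_batch_bold, simulate_timeseries)
from rtdcm.synth import TruthSpec, ground_truth_params


def two_region_params(A=None, B=None, C=None):
    n, m = 2, 1
    return ConnectivityParams(
        A=np.array([[-0.5, 0.0], [0.0, -0.5]]) if A is None else A,
        B=np.zeros((m, n, n)) if B is None else B,
        C=np.array([[1.0], [0.0]]) if C is None else C,
        region_labels=("r1", "r2"),
        input_labels=("u",),
    )


class TestNeuronalDrift:
    def test_rest_is_fixed_point(self):
        p = two_region_params()
        assert np.all(neuronal_drift(np.zeros(2), np.zeros(1), p) == 0)

    def test_pure_driving_input(self):
        p = two_region_params()
        dz = neuronal_drift(np.zeros(2), np.ones(1), p)
        np.testing.assert_allclose(dz, [1.0, 0.0])

    def test_matches_matrix_arithmetic_oracle(self):
        rng = np.random.default_rng(7)
        n, m = 4, 1
        A = rng.standard_normal((n, n)) * 0.3 - 0.6 * np.eye(n)
        B = rng.standard_normal((m, n, n)) * 0.2
        C = rng.standard_normal((n, m)) * 0.3
        p = ConnectivityParams(A=A, B=B, C=C,
                               region_labels=tuple("abcd"),
                               input_labels=("u",))
        z = np.array([0.1, 0.2, 0.3, 0.4])
        u = np.array([1.0])
        # independent hand-coded expression
        expected = (A + u[0] * B[0]) @ z + C[:, 0] * u[0]
        np.testing.assert_allclose(neuronal_drift(z, u, p), expected,
                                   atol=1e-12)

    def test_dimension_mismatch_names_field(self):
        p = two_region_params()
        with pytest.raises(ValueError, match="z has shape"):
            neuronal_drift(np.zeros(3), np.zeros(1), p)
        with pytest.raises(ValueError, match="u has shape"):
            neuronal_drift(np.zeros(2), np.zeros(2), p)

    def test_positive_self_decay_rejected(self):
        with pytest.raises(ValueError, match="strictly negative"):
            two_region_params(A=np.array([[0.1, 0.0], [0.0, -0.5]]))


class TestHemodynamics:
    def test_rest_fixed_point(self):
        state = NeuralHemoState.rest(3)
        derivs = hemodynamic_drift(state, HemodynamicParams())
        for d in derivs:
            np.testing.assert_allclose(d, 0.0, atol=1e-15)

    def test_activity_enters_only_vasodilatory_signal(self):
        state = NeuralHemoState.rest(1)
        state.z = np.array([1.0])
        ds, df, dv, dq = hemodynamic_drift(state, HemodynamicParams())
        np.testing.assert_allclose(ds, [1.0])
        np.testing.assert_allclose(df, 0.0, atol=1e-15)
        np.testing.assert_allclose(dv, 0.0, atol=1e-15)
        np.testing.assert_allclose(dq, 0.0, atol=1e-15)

    def test_nonpositive_volume_rejected(self):
        state = NeuralHemoState.rest(1)
        state.v = np.array([-0.1])
        with pytest.raises(ValueError, match="positive"):
            hemodynamic_drift(state, HemodynamicParams())

    def test_inflow_peaks_2_to_8_s_after_step(self):
        # brute-force fine-step Euler integration of one region driven by
        # z(t)=1 on [0,1] s, independent of the packaged integrator
        h = HemodynamicParams()
        dt = 0.001
        t = np.arange(0.0, 15.0, dt)
        state = NeuralHemoState.rest(1)
        f_tr = []
        for ti in t:
            state.z = np.array([1.0 if ti <= 1.0 else 0.0])
            ds, df, dv, dq = hemodynamic_drift(state, h)
            state.s = state.s + dt * ds
            state.f = state.f + dt * df
            state.v = state.v + dt * dv
            state.q = state.q + dt * dq
            f_tr.append(state.f[0])
        t_peak = t[int(np.argmax(f_tr))]
        assert 2.0 < t_peak < 8.0


class TestBoldObservation:
    def test_rest_gives_zero(self):
        y = bold_observation(np.ones(2), np.ones(2), HemodynamicParams())
        np.testing.assert_allclose(y, 0.0, atol=1e-15)

    def test_hand_arithmetic(self):
        h = HemodynamicParams(V0=0.04, k1=2.8, k2=2.0, k3=0.6)
        y = bold_observation(np.array([1.0]), np.array([0.9]), h)
        np.testing.assert_allclose(y, [0.04 * (2.8 * 0.1 + 2 * 0.1)],
                                   atol=1e-15)

    def test_decreasing_in_q_at_fixed_v(self):
        h = HemodynamicParams()
        qs = np.linspace(0.7, 1.3, 25)
        ys = [bold_observation(np.ones(1), np.array([q]), h)[0] for q in qs]
        assert np.all(np.diff(ys) < 0)


class TestSimulateTimeseries:
    def test_zero_input_weights_give_zero_output(self, trial_design):
        p = ground_truth_params(TruthSpec(c=0.0))
        ts = simulate_timeseries(p, HemodynamicParams(), trial_design)
        np.testing.assert_array_equal(ts.values, 0.0)

    def test_step_halving_convergence(self, trial_design):
        p = ground_truth_params()
        h = HemodynamicParams()
        y1 = simulate_timeseries(p, h, trial_design, dt=0.125).values
        y2 = simulate_timeseries(p, h, trial_design, dt=0.0625).values
        assert np.max(np.abs(y1 - y2)) < 1e-4

    def test_rk4_order(self, trial_design):
        # error vs a fine reference should shrink ~16x per step halving
        p = ground_truth_params()
        h = HemodynamicParams()
        ref = simulate_timeseries(p, h, trial_design, dt=1 / 32).values
        e1 = np.abs(simulate_timeseries(p, h, trial_design, dt=1 / 4).values
                    - ref).max()
        e2 = np.abs(simulate_timeseries(p, h, trial_design, dt=1 / 8).values
                    - ref).max()
        assert e1 / e2 > 8.0

    def test_linearity_at_small_amplitude(self, trial_design):
        h = HemodynamicParams()
        lo = ground_truth_params(TruthSpec(c=1e-4))
        hi = ground_truth_params(TruthSpec(c=2e-4))
        y_lo = simulate_timeseries(lo, h, trial_design).values
        y_hi = simulate_timeseries(hi, h, trial_design).values
        scale = np.max(np.abs(y_lo))
        assert np.max(np.abs(y_hi / 2.0 - y_lo)) < 0.05 * scale

    def test_time_shift_equivariance(self):
        # shifting the input train by one TR shifts the response
        p = ground_truth_params()
        h = HemodynamicParams()
        n = 80
        u = np.zeros((n, 2))
        u[20:30, 0] = 1.0
        d1 = ExperimentDesign(TR=1.0, n_scans=n, u=u,
                              input_labels=("aL", "aR"))
        u2 = np.roll(u, 1, axis=0)
        d2 = ExperimentDesign(TR=1.0, n_scans=n, u=u2,
                              input_labels=("aL", "aR"))
        y1 = simulate_timeseries(p, h, d1).values
        y2 = simulate_timeseries(p, h, d2).values
        np.testing.assert_allclose(y2[1:], y1[:-1], atol=1e-12)

    def test_divergence_reports_time(self, trial_design):
        unstable = ground_truth_params(TruthSpec(a=0.3, b=0.4, c=0.3))
        with pytest.raises(SimulationDiverged, match="at t ="):
            simulate_timeseries(unstable, HemodynamicParams(), trial_design,
                                check_stability=False)

    def test_stability_assertion(self):
        assert_stable(np.array([[-0.5, 0.1], [0.1, -0.5]]))
        with pytest.raises(ValueError, match="unstable"):
            assert_stable(np.array([[-0.5, 0.7], [0.7, -0.5]]))

    @pytest.mark.skipif(not _HAVE_NUMBA, reason="numba not installed")
    def test_numba_and_numpy_kernels_agree(self, trial_design):
        p = ground_truth_params()
        h = HemodynamicParams()
        args = (p.A[None], p.B[None], p.C[None], trial_design, h)
        y1, _ = simulate_batch_bold(*args, use_numba=True)
        y2, _ = simulate_batch_bold(*args, use_numba=False)
        np.testing.assert_allclose(y1, y2, atol=1e-12)
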