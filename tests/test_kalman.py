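"""Kalman correction: recursion fidelity, gain limits, noise estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgloc.kalman import (TrackConfig, TrackState, V_VENTRICULAR_MPS,
                           direction_input, estimate_Q, estimate_R,
                           kalman_step, steady_state_gain, track)


class TestDirectionInput:
    def test_reference_arithmetic(self):
        u = direction_input([0, 0, 5], v_mps=1.9, dt_s=1e-3)
        np.testing.assert_allclose(u, [0, 0, 1.9])

    def test_step_length_is_v_dt(self, rng):
        j = rng.standard_normal(3)
        u = direction_input(j, v_mps=1.9, dt_s=2e-3)
        assert np.linalg.norm(u) == pytest.approx(1.9 * 2e-3 * 1e3)

    def test_scale_invariant(self, rng):
        j = rng.standard_normal(3)
        np.testing.assert_allclose(direction_input(j), direction_input(10 * j))

    def test_zero_direction_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            direction_input([0, 0, 0])


class TestKalmanStep:
    def test_huge_r_ignores_observation(self):
        s = TrackState(x_mm=[0, 0, 0], P_mm2=[4, 4, 4])
        out, K = kalman_step(s, [1, 0, 0], [100, 100, 100], q_mm2=1, r_mm2=1e12)
        np.testing.assert_allclose(K, 0, atol=1e-10)
        np.testing.assert_allclose(out.x_mm, [1, 0, 0], atol=1e-8)

    def test_zero_r_trusts_observation(self):
        s = TrackState(x_mm=[0, 0, 0], P_mm2=[4, 4, 4])
        out, K = kalman_step(s, [1, 0, 0], [7, -3, 2], q_mm2=1, r_mm2=0)
        np.testing.assert_allclose(K, 1)
        np.testing.assert_allclose(out.x_mm, [7, -3, 2])

    def test_indeterminate_gain_raises(self):
        s = TrackState(x_mm=[0, 0, 0], P_mm2=[0, 0, 0])
        with pytest.raises(ZeroDivisionError):
            kalman_step(s, [0, 0, 0], [1, 1, 1], q_mm2=0, r_mm2=0)

    def test_matches_independent_scalar_filter(self, rng):
        """50-step random sequence vs an independently coded 1-D filter."""
        q, r, dt = 2.5, 9.0, 1e-3
        us = rng.standard_normal(50)
        zs = rng.standard_normal(50) * 5
        # textbook scalar filter, written straight from the recursion
        x_o, P_o = 0.0, q
        xs_oracle = []
        for t in range(50):
            x_pred = x_o + us[t]
            P_pred = P_o + dt**2 * q
            K = P_pred / (P_pred + r)
            P_o = (1 - K) * P_pred
            x_o = x_pred + K * (zs[t] - x_pred)
            xs_oracle.append(x_o)
        # package filter run on the x axis only
        s = TrackState(x_mm=[0, 0, 0], P_mm2=[q, q, q])
        for t in range(50):
            s, _ = kalman_step(s, [us[t], 0, 0], [zs[t], 0, 0],
                               q_mm2=q, r_mm2=r, dt_s=dt)
            assert s.x_mm[0] == pytest.approx(xs_oracle[t], abs=1e-12)

    @settings(max_examples=60, derandomize=True)
    @given(P=st.floats(0, 1e4), q=st.floats(0, 1e4), r=st.floats(1e-6, 1e4))
    def test_gain_in_unit_interval_and_convexity(self, P, q, r):
        s = TrackState(x_mm=[0, 0, 0], P_mm2=[P, P, P])
        out, K = kalman_step(s, [0, 0, 0], [10, 10, 10], q_mm2=q, r_mm2=r)
        assert np.all((0 <= K) & (K <= 1))
        # update is a convex combination of prediction and observation
        np.testing.assert_allclose(out.x_mm, K * 10, rtol=1e-12, atol=1e-12)

    def test_variance_nonincreasing_without_process_noise(self):
        s = TrackState(x_mm=[0, 0, 0], P_mm2=[25, 25, 25])
        prev = s.P_mm2.copy()
        for _ in range(20):
            s, _ = kalman_step(s, [0, 0, 0], [1, 1, 1], q_mm2=0, r_mm2=4)
            assert np.all(s.P_mm2 <= prev + 1e-15)
            prev = s.P_mm2.copy()


class TestTrack:
    def test_single_step_with_zero_r_equals_observation(self):
        cfg = TrackConfig(x0_mm=[5, 5, 5], q_mm2=1.0, r_mm2=0.0)
        out = track(np.array([[9.0, 1.0, 2.0]]), np.array([[0, 0, 1.0]]), cfg)
        np.testing.assert_allclose(out[["x_mm", "y_mm", "z_mm"]].iloc[0],
                                   [9.0, 1.0, 2.0])

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            track(np.zeros((0, 3)), np.zeros((0, 3)), TrackConfig())

    def test_filter_beats_raw_observations(self):
        """Constant-velocity source, noisy observations: the filtered track
        must have a lower mean distance error than the raw estimates."""
        v, dt, n, sigma, runs = V_VENTRICULAR_MPS, 1e-3, 30, 10.0, 50
        step = v * dt * 1e3
        direction = np.array([1.0, 0, 0])
        truth = np.arange(1, n + 1)[:, None] * step * direction
        j_series = np.tile(direction, (n, 1))
        raw_err, filt_err = [], []
        cfg = TrackConfig(x0_mm=[0, 0, 0], v_mps=v, dt_s=dt,
                          q_mm2=4.0, r_mm2=sigma**2)
        rng = np.random.default_rng(11)
        for _ in range(runs):
            obs = truth + rng.normal(0, sigma, size=truth.shape)
            out = track(obs, j_series, cfg)
            est = out[["x_mm", "y_mm", "z_mm"]].to_numpy()
            raw_err.append(np.linalg.norm(obs - truth, axis=1).mean())
            filt_err.append(np.linalg.norm(est - truth, axis=1).mean())
        assert np.mean(filt_err) < np.mean(raw_err)

    def test_steady_state_gain_matches_riccati_fixed_point(self):
        for q, r, dt in [(2.0, 9.0, 1.0), (100.0, 25.0, 1e-3), (5.0, 5.0, 0.1)]:
            s = TrackState(x_mm=[0, 0, 0], P_mm2=[q] * 3)
            K = None
            for _ in range(20_000):
                s, K = kalman_step(s, [0, 0, 0], [0, 0, 0],
                                   q_mm2=q, r_mm2=r, dt_s=dt)
            assert K[0] == pytest.approx(steady_state_gain(q, r, dt), abs=1e-6)


class TestNoiseEstimation:
    def test_q_zero_for_perfect_study(self):
        import pandas as pd
        table = pd.DataFrame({"ex": [0.0] * 5, "ey": [0.0] * 5, "ez": [0.0] * 5,
                              "LE_mm": [0.0] * 5})
        np.testing.assert_allclose(estimate_Q(table), 0.0)

    def test_q_zero_for_constant_offset(self):
        import pandas as pd
        table = pd.DataFrame({"ex": [3.0] * 6, "ey": [-1.0] * 6, "ez": [2.0] * 6,
                              "LE_mm": [np.sqrt(14.0)] * 6})
        np.testing.assert_allclose(estimate_Q(table), 0.0, atol=1e-12)
        np.testing.assert_allclose(estimate_Q(table, per_axis=False), 0.0,
                                   atol=1e-12)

    def test_q_matches_two_pass_variance_oracle(self, rng):
        import pandas as pd
        e = rng.standard_normal((30, 3)) * [2, 5, 1]
        table = pd.DataFrame(e, columns=["ex", "ey", "ez"])
        table["LE_mm"] = np.linalg.norm(e, axis=1)
        got = estimate_Q(table)
        for a, col in enumerate(e.T):
            m = sum(col) / len(col)
            var = sum((x - m) ** 2 for x in col) / (len(col) - 1)
            assert got[a] == pytest.approx(var)

    def test_q_needs_two_trials(self):
        import pandas as pd
        with pytest.raises(ValueError, match="2"):
            estimate_Q(pd.DataFrame({"ex": [1.0], "ey": [0.0], "ez": [0.0],
                                     "LE_mm": [1.0]}))

    def test_r_zero_for_identical_subdictionaries(self, small_lfm):
        r = estimate_R(small_lfm, n_subsets=5, subset_size=small_lfm.N,
                       rng=np.random.default_rng(0))
        np.testing.assert_allclose(r, 0.0)

    def test_r_subset_size_bound(self, small_lfm):
        with pytest.raises(ValueError, match="exceeds"):
            estimate_R(small_lfm, subset_size=small_lfm.N + 1,
                       rng=np.random.default_rng(0))

    def test_r_shrinks_as_subsets_grow(self, small_lfm):
        rng = np.random.default_rng(2)
        r_small = estimate_R(small_lfm, n_subsets=8, subset_size=5, rng=rng).mean()
        r_big = estimate_R(small_lfm, n_subsets=8, subset_size=small_lfm.N - 1,
                           rng=np.random.default_rng(2)).mean()
        assert r_big <= r_small
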