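"""Pulse metrics against brute-force oracles; shift/peak-normalization
variability decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from campnet.metrics import (
    compute_pulse_metrics,
    peak_normalize,
    population_mean_sd,
    pulse_metrics_for_protocol,
    shift_traces,
)


def brute_force_metrics(time, signal, t_on, t_off, ss_fraction=0.3):
    """Exhaustive index-scan oracle, independent of the implementation."""
    idx = [k for k, t in enumerate(time) if t_on - 1e-9 <= t <= t_off + 1e-9]
    seg = [signal[k] for k in idx]
    s_start, s_end = seg[0], seg[-1]
    s_max = max(seg)
    k_max = min(k for k, v in enumerate(seg) if v == s_max)
    t2m = time[idx[k_max]] - t_on
    band = ss_fraction * (s_max - s_end)
    k_ss = None
    for k in range(k_max, len(seg)):
        if abs(seg[k] - s_end) <= band + 1e-15:
            k_ss = k
            break
    t2ss = time[idx[k_ss if k_ss is not None else -1]] - t_on
    return s_start, s_max, s_end, t2m, t2ss


class TestPulseMetrics:
    def test_analytic_overshoot_ratio_two(self):
        # 0 at onset, peak 2 at t=10, settles to 1 by t=20
        t = np.arange(0.0, 41.0)
        s = np.interp(t, [0, 10, 20, 40], [0, 2, 1, 1])
        m = compute_pulse_metrics(t, s, (0.0, 40.0))
        assert m.overshoot_ratio == pytest.approx(2.0)
        assert m.time_to_max == 10.0
        # the signal first enters the 30%-of-(S_max - S_end) band around
        # S_end at S = 1.3, i.e. t = 17 on the linear descent
        assert m.time_to_ss == 17.0
        assert m.valid

    def test_monotone_saturating_signal(self):
        t = np.arange(0.0, 41.0)
        s = 1 - np.exp(-t / 5.0)
        m = compute_pulse_metrics(t, s, (0.0, 40.0))
        assert m.overshoot_ratio == pytest.approx(1.0)
        assert m.time_to_ss == m.time_to_max

    def test_flat_signal_flagged_invalid(self):
        t = np.arange(0.0, 41.0)
        m = compute_pulse_metrics(t, np.ones_like(t), (0.0, 40.0), eps=0.01)
        assert not m.valid
        assert np.isnan(m.overshoot_ratio)

    def test_random_signals_match_index_scan_oracle(self):
        rng = np.random.default_rng(42)
        t = np.arange(0.0, 61.0, 1.0)
        for _ in range(200):
            knots_t = np.sort(rng.choice(np.arange(5, 56), 6, replace=False))
            knots_v = rng.uniform(-1, 3, size=6)
            s = np.interp(t, [0, *knots_t, 60], [0, *knots_v, knots_v[-1]])
            m = compute_pulse_metrics(t, s, (5.0, 55.0), eps=1e-12)
            s0, smax, send, t2m, t2ss = brute_force_metrics(t, s, 5.0, 55.0)
            assert m.s_start == s0 and m.s_max == smax and m.s_end == send
            assert m.time_to_max == t2m
            assert m.time_to_ss == t2ss
            if abs(send - s0) >= 1e-12:
                assert m.overshoot_ratio == pytest.approx(
                    (smax - s0) / (send - s0)
                )

    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5))
    @settings(max_examples=40, deadline=None)
    def test_affine_invariance(self, a, b):
        t = np.arange(0.0, 41.0)
        s = np.interp(t, [0, 8, 25, 40], [0.2, 1.7, 0.9, 1.0])
        m0 = compute_pulse_metrics(t, s, (0.0, 40.0), eps=1e-12)
        m1 = compute_pulse_metrics(t, a * s + b, (0.0, 40.0), eps=1e-12)
        assert m1.overshoot_ratio == pytest.approx(m0.overshoot_ratio, rel=1e-9)
        assert m1.time_to_max == m0.time_to_max
        assert m1.time_to_ss == m0.time_to_ss

    def test_earliest_index_wins_ties(self):
        t = np.arange(0.0, 11.0)
        s = np.array([0, 1, 2, 2, 2, 1, 1, 1, 1, 1, 1.0])
        m = compute_pulse_metrics(t, s, (0.0, 10.0), eps=1e-12)
        assert m.time_to_max == 2.0

    def test_undershoot_depth_over_off_period(self):
        t = np.arange(0.0, 81.0)
        s = np.interp(t, [0, 5, 40, 50, 60, 80], [1.0, 2.0, 2.0, 0.7, 1.0, 1.0])
        m = compute_pulse_metrics(t, s, (0.0, 40.0), off_end=80.0)
        assert m.undershoot_depth == pytest.approx(0.3)

    def test_window_validation(self):
        t = np.arange(0.0, 41.0)
        with pytest.raises(ValueError):
            compute_pulse_metrics(t, t, (-5.0, 20.0))
        with pytest.raises(ValueError):
            compute_pulse_metrics(t, t, (0.0, 1.0))


class TestVariabilityDecomposition:
    def make_cohort(self, n_cells=30, seed=0):
        """Common shape x random per-pulse gains + baseline offsets."""
        rng = np.random.default_rng(seed)
        t = np.arange(0.0, 160.0, 1.0)
        shape = np.zeros_like(t)
        for on, off in ((40, 80), (120, 160)):
            seg = (t >= on) & (t < off)
            shape[seg] = 1 - np.exp(-(t[seg] - on) / 5.0)
        gains = rng.lognormal(0, 0.4, size=(n_cells, 2))
        base = rng.normal(0, 0.3, size=n_cells)
        traces = np.empty((n_cells, t.size))
        for i in range(n_cells):
            tr = np.array(shape)
            tr[(t >= 40) & (t < 120)] *= gains[i, 0]
            tr[t >= 120] *= gains[i, 1]
            traces[i] = tr + base[i]
        return t, traces

    def test_shift_zeroes_onset_and_sd(self):
        t, traces = self.make_cohort()
        shifted = shift_traces(traces, t, 40.0)
        k = 40
        assert np.all(shifted[:, k] == 0.0)
        assert shifted[:, k].std() == 0.0

    def test_constant_trace_shifts_to_zero(self):
        t = np.arange(0.0, 10.0)
        out = shift_traces(np.full((3, 10), 7.0), t, 0.0)
        assert np.all(out == 0.0)

    def test_peak_normalize_sets_unit_peak(self):
        t, traces = self.make_cohort()
        normed, kept = peak_normalize(traces, t, (40.0, 80.0))
        assert kept.all()
        window = (t >= 40) & (t <= 80)
        assert np.allclose(normed[:, window].max(axis=1), 1.0)

    def test_amplitude_scaled_copies_collapse(self):
        t = np.arange(0.0, 81.0)
        shape = np.interp(t, [0, 40, 50, 80], [0, 0, 1, 1])
        traces = np.outer([0.5, 1.0, 2.0, 3.0], shape)
        normed, _ = peak_normalize(traces, t, (40.0, 80.0))
        assert normed.std(axis=0).max() < 1e-12

    def test_normalization_constrains_its_own_pulse_most(self):
        t, traces = self.make_cohort()
        in_p1 = (t >= 45) & (t <= 80)
        in_p2 = (t >= 125) & (t <= 159)
        n1, _ = peak_normalize(traces, t, (40.0, 80.0))
        n2, _ = peak_normalize(traces, t, (120.0, 159.0))
        sd1 = n1.std(axis=0, ddof=1)
        sd2 = n2.std(axis=0, ddof=1)
        assert sd1[in_p1].mean() < sd2[in_p1].mean()
        assert sd2[in_p2].mean() < sd1[in_p2].mean()

    def test_flat_traces_excluded_with_warning(self):
        t = np.arange(0.0, 81.0)
        shape = np.interp(t, [0, 40, 50, 80], [0, 0, 1, 1])
        traces = np.vstack([shape, np.zeros_like(t)])
        with pytest.warns(UserWarning, match="flat"):
            normed, kept = peak_normalize(traces, t, (40.0, 80.0))
        assert kept.tolist() == [True, False]
        assert normed.shape[0] == 1


class TestPopulationMeanSd:
    def test_identical_traces_have_zero_sd(self):
        t = np.arange(0.0, 30.0)
        traces = np.tile(np.sin(t / 5), (4, 1))
        mean, sd = population_mean_sd(traces, t)
        assert np.allclose(sd, 0.0)
        assert np.allclose(mean, np.sin(t / 5))

    def test_mirror_traces_have_zero_mean(self):
        t = np.arange(0.0, 30.0)
        f = np.cos(t / 3)
        mean, _ = population_mean_sd(np.vstack([f, -f]), t)
        assert np.allclose(mean, 0.0)

    def test_matches_two_pass_oracle_segmentwise(self):
        rng = np.random.default_rng(5)
        t = np.arange(0.0, 160.0)
        traces = rng.normal(size=(12, t.size))
        onsets = (40.0, 120.0)
        mean, sd = population_mean_sd(traces, t, onsets)
        # direct recomputation
        for onset, nxt in ((40.0, 120.0), (120.0, 160.0)):
            seg = (t >= onset) & (t < nxt)
            shifted = traces - traces[:, int(onset)][:, None]
            assert np.allclose(mean[seg], shifted[:, seg].mean(axis=0))
            assert np.allclose(sd[seg], shifted[:, seg].std(axis=0, ddof=1))
        assert sd[int(onsets[0])] == 0.0 and sd[int(onsets[1])] == 0.0

    def test_single_trace_rejected(self):
        t = np.arange(0.0, 10.0)
        with pytest.raises(ValueError):
            population_mean_sd(np.ones((1, 10)), t)
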