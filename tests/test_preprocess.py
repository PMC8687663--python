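"""Detrending, smoothing, feature detection, damping, actograms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import perwave as pw
from perwave.core import Trace
from perwave.preprocess import (
    amplitude_fold_change,
    build_actogram,
    detrend_running_mean,
    fit_damping,
    find_features,
    smooth_moving_average,
    _window_samples,
)
from perwave.synth import GeneratorConfig, WaveformProgram, programmed_extrema


def brute_force_trapezoid_mean(values, n):
    """Independent windowed-mean oracle: explicit loop, shrinking at edges."""
    half = (n - 1) // 2
    out = np.empty_like(values)
    m = len(values)
    for i in range(m):
        k = min(half, i, m - 1 - i)
        if k == 0:
            out[i] = values[i]
            continue
        w = np.ones(2 * k + 1)
        w[0] = w[-1] = 0.5
        out[i] = np.dot(values[i - k : i + k + 1], w) / w.sum()
    return out


def make_trace(values, dt=0.1):
    return Trace(np.arange(len(values)) * dt, values)


class TestDetrend:
    def test_constant_maps_to_zero(self):
        tr = make_trace(np.full(600, 7.3))
        assert np.allclose(detrend_running_mean(tr).values, 0.0, atol=1e-12)

    def test_full_cycle_window_preserves_cosine(self):
        # a centered window spanning exactly one period averages a cosine
        # to zero, so the rhythm passes through untouched (interior)
        t = np.arange(0, 150.0001, 0.1)
        tr = Trace(t, np.cos(2 * np.pi * t / 24))
        out = detrend_running_mean(tr, 24.0)
        interior = (t > 13) & (t < 137)
        assert np.max(np.abs(out.values[interior] - tr.values[interior])) < 1e-6

    def test_linear_ramp_removed_vs_brute_force(self):
        t = np.arange(0, 150.0001, 0.1)
        v = np.cos(2 * np.pi * t / 24) + 0.5 * t
        tr = Trace(t, v)
        out = detrend_running_mean(tr, 24.0)
        oracle = v - brute_force_trapezoid_mean(v, _window_samples(24.0, 0.1))
        assert np.allclose(out.values, oracle, atol=1e-10)
        interior = (t > 13) & (t < 137)
        assert np.max(np.abs(out.values[interior] - np.cos(2 * np.pi * t / 24)[interior])) < 1e-6

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            detrend_running_mean(make_trace(np.ones(100)), 24.0)


class TestSmooth:
    def test_linear_signal_is_fixed_point(self):
        t = np.arange(0, 50.0001, 0.1)
        tr = Trace(t, 3.0 + 0.7 * t)
        out = smooth_moving_average(tr, 2.4)
        interior = (t > 2) & (t < 48)
        assert np.allclose(out.values[interior], tr.values[interior], atol=1e-10)

    def test_cosine_attenuation_matches_closed_form_and_brute_force(self):
        t = np.arange(0, 150.0001, 0.1)
        v = np.cos(2 * np.pi * t / 24)
        out = smooth_moving_average(Trace(t, v), 2.4)
        oracle = brute_force_trapezoid_mean(v, _window_samples(2.4, 0.1))
        assert np.allclose(out.values, oracle, atol=1e-12)
        x = np.pi * 2.4 / 24
        interior = (t > 24) & (t < 126)
        ratio = np.max(np.abs(out.values[interior])) / 1.0
        assert ratio == pytest.approx(np.sin(x) / x, abs=5e-3)

    def test_impulse_spreads_to_window_width(self):
        v = np.zeros(401)
        v[200] = 1.0
        out = smooth_moving_average(make_trace(v), 2.4)
        n = _window_samples(2.4, 0.1)
        support = np.flatnonzero(out.values > 0)
        assert len(support) == n
        assert np.allclose(out.values[support][1:-1], out.values[201], atol=1e-12)

    def test_window_below_three_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            smooth_moving_average(make_trace(np.ones(100), dt=2.0), 2.4)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(window=st.floats(0.5, 30.0), period=st.floats(18.0, 30.0))
    def test_running_mean_equals_brute_force_oracle(self, window, period):
        t = np.arange(0, 120.0001, 0.1)
        v = np.cos(2 * np.pi * t / period) + 0.1 * t
        out = smooth_moving_average(Trace(t, v), window)
        oracle = brute_force_trapezoid_mean(v, _window_samples(window, 0.1))
        assert np.allclose(out.values, oracle, atol=1e-10)

    def test_detrend_and_smooth_commute_interior(self):
        t = np.arange(0, 240.0001, 0.1)
        rng = np.random.default_rng(0)
        v = np.cos(2 * np.pi * t / 24) + 0.2 * t + rng.normal(0, 0.05, t.shape)
        tr = Trace(t, v)
        a = smooth_moving_average(detrend_running_mean(tr))
        b = detrend_running_mean(smooth_moving_average(tr))
        interior = (t > 30) & (t < 210)
        assert np.max(np.abs(a.values[interior] - b.values[interior])) < 1e-9


class TestFindFeatures:
    def test_pure_cosine_peaks_at_programmed_times(self, cosine_trace):
        tr, cfg = cosine_trace
        proc = pw.preprocess_trace(tr)
        feats = find_features(proc)
        pk_true, _ = programmed_extrema(cfg)
        for pt in feats.peak_times:
            assert np.min(np.abs(pk_true - pt)) <= 0.1

    def test_damped_synthetic_matches_generator_truth(self, damped_trace):
        tr, cfg = damped_trace
        feats = find_features(pw.preprocess_trace(tr))
        pk_true, tq_true = programmed_extrema(cfg)
        for pt in feats.peak_times:
            assert np.min(np.abs(pk_true - pt)) <= 0.1
        for tt in feats.trough_times:
            assert np.min(np.abs(tq_true - tt)) <= 0.1
        ratios = feats.amplitudes[1:] / feats.amplitudes[:-1]
        assert np.allclose(ratios[np.isfinite(ratios)], 0.95, atol=0.01)

    def test_small_induction_bump_rejected_by_prominence(self):
        cfg = GeneratorConfig(duration_hr=240.0)
        prog = WaveformProgram(stim_time_hr=86.0, induction_amplitude=0.1,
                               induction_decay_hr=2.0)
        feats = find_features(pw.preprocess_trace(pw.make_trace(cfg, prog)))
        # no peak called inside the transient
        assert not np.any((feats.peak_times > 86.0) & (feats.peak_times < 92.0))

    def test_large_bump_cannot_suppress_adjacent_peak(self):
        exp = pw.make_experiment("IND-CT14")
        feats = find_features(pw.preprocess_trace(exp.stimulated), stim_time_hr=86.0)
        assert np.min(np.abs(feats.peak_times - 84.0)) <= 0.2
        assert not np.any((feats.peak_times > 86.0) & (feats.peak_times <= 92.0))

    def test_flat_trace_flagged_insufficient(self):
        feats = find_features(make_trace(np.zeros(500)))
        assert feats.insufficient_for_period

    def test_halfmax_lies_between_trough_and_peak(self, damped_trace):
        tr, _ = damped_trace
        feats = find_features(pw.preprocess_trace(tr))
        for hm in feats.halfmax_rising:
            prior_trough = feats.trough_times[feats.trough_times < hm]
            next_peak = feats.peak_times[feats.peak_times > hm]
            assert len(prior_trough) and len(next_peak)
            assert next_peak[0] - prior_trough[-1] < 16.0


class TestDamping:
    def test_exact_geometric_sequence(self):
        assert fit_damping([1.0, 0.85, 0.7225]) == pytest.approx(0.85, abs=1e-9)

    def test_constant_amplitudes_give_unity(self):
        assert fit_damping([2.0, 2.0, 2.0, 2.0]) == pytest.approx(1.0)

    def test_recovery_under_multiplicative_noise(self):
        rng = np.random.default_rng(7)
        errs = []
        for _ in range(20):
            amps = 0.9 ** np.arange(10) * np.exp(rng.normal(0, 0.05, 10))
            errs.append(fit_damping(amps) - 0.9)
        assert np.max(np.abs(errs)) < 0.03 * 0.9

    def test_nonpositive_amplitudes_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fit_damping([1.0, -0.5, 0.2])


class TestActogram:
    def test_constant_rows_map_to_zero(self):
        acto = build_actogram(make_trace(np.ones(1000)), 24.0)
        assert np.all(acto[np.isfinite(acto)] == 0.0)

    def test_cosine_rows_identical(self):
        t = np.arange(0, 120, 0.1)
        acto = build_actogram(Trace(t, np.cos(2 * np.pi * t / 24)), 24.0,
                              double_plot=False)
        for row in acto[1:-1]:
            assert np.allclose(row, acto[0], atol=1e-9)

    def test_t22_ridge_drifts_two_hours_per_row(self):
        t = np.arange(0, 240, 0.1)
        tr = Trace(t, np.cos(2 * np.pi * (t - 11) / 22))
        acto = build_actogram(tr, 24.0, double_plot=False)
        cols = np.argmax(acto, axis=1) * 0.1
        drift = np.diff(cols)
        drift = drift[np.abs(drift + 2.0) < 4.0]  # ignore wrap rows
        assert np.allclose(drift, -2.0, atol=0.15)

    def test_double_plot_concatenates_next_window(self):
        t = np.arange(0, 96, 0.1)
        acto = build_actogram(Trace(t, np.cos(2 * np.pi * t / 24)), 24.0)
        m = 240
        assert acto.shape[1] == 2 * m
        assert np.allclose(acto[0, m:], acto[1, :m], atol=1e-9)

    def test_row_normalization_idempotent(self):
        t = np.arange(0, 120, 0.1)
        acto = build_actogram(Trace(t, np.cos(2 * np.pi * t / 24)), 24.0)
        finite = np.isfinite(acto)
        assert np.nanmin(acto) == 0.0 and np.nanmax(acto) == 1.0
        renorm = build_actogram(
            Trace(np.arange(acto.shape[1]) * 0.1, acto[0][np.isfinite(acto[0])]),
            acto.shape[1] * 0.1, double_plot=False,
        )
        assert np.allclose(renorm[0], acto[0][np.isfinite(acto[0])], atol=1e-12)


class TestAmplitudeFoldChange:
    def test_unperturbed_damping_ratio(self, damped_trace):
        tr, _ = damped_trace
        feats = find_features(pw.preprocess_trace(tr))
        assert amplitude_fold_change(feats, 100.0) == pytest.approx(0.95, abs=0.01)

    def test_amplitude_collapse_recovered_vs_truth(self):
        cfg = GeneratorConfig(duration_hr=240.0)
        prog = WaveformProgram(stim_time_hr=86.0, post_amplitude_scale=0.1)
        feats = find_features(pw.preprocess_trace(pw.make_trace(cfg, prog)),
                              stim_time_hr=86.0)
        fc = amplitude_fold_change(feats, 86.0)
        assert fc == pytest.approx(0.1 * 0.95, rel=0.05)

    def test_treatment_at_trace_start_rejected(self, damped_trace):
        tr, _ = damped_trace
        feats = find_features(pw.preprocess_trace(tr))
        with pytest.raises(ValueError, match="each side"):
            amplitude_fold_change(feats, 0.0)
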