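"""Single-stimulus response metrics.

Quantifies how one optogenetic pulse resets a PER2::LUC rhythm:

* **phase shift** — predicted minus observed first post-stimulus peak, where
  the prediction extrapolates a linear regression of at least three
  pre-stimulus peak times (advance positive, delay negative);
* **period** — by regression of peak times, regression of rising half-max
  times, or a Lomb–Scargle periodogram on a dense 16–32 h grid;
* **envelope normalization** — mapping the damped rhythm into [0, 1] between
  geometric peak/trough envelopes extrapolated from the pre-stimulus cycles
  (or anchored on actual troughs with interpolated peaks);
* **normalized induction** — the first-cycle amplitude (max − min) of the
  difference between the envelope-normalized stimulated and unstimulated
  rhythms;
* **rising/falling durations** — spans between zero crossings of the
  smoothed first derivative, with the stimulated cycle expressed as a fold
  change over the mean pre-stimulus cycle.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lombscargle

from .core import PhaseShiftResult, RhythmFeatures, StimSchedule, Trace, WaveformMetrics
from .preprocess import _running_mean, _window_samples, detrend_running_mean, find_features, smooth_moving_average

__all__ = [
    "phase_shift",
    "period_estimate",
    "period_change",
    "pulse_period_change",
    "envelope_normalize",
    "induction_metrics",
    "cycle_durations",
    "fold_changes_single_pulse",
    "fold_changes_entrained",
]

PERIOD_SEARCH_HR = (16.0, 32.0)
PERIOD_GRID_STEP_HR = 0.01
EDGE_EXCLUSION_HR = 12.0

#: fraction of the fitted period after pulse onset within which detected
#: peaks are treated as part of the acute induction transient
INDUCTION_EXCLUSION_FRAC = 0.25


def phase_shift(
    features: RhythmFeatures,
    stim_time_hr: float,
    exclusion_frac: float = INDUCTION_EXCLUSION_FRAC,
) -> PhaseShiftResult:
    """Phase shift by regression extrapolation of pre-stimulus peaks.

    shift = predicted − observed; positive = advance, negative = delay.
    """
    pre = features.peaks_before(stim_time_hr)
    if len(pre) < 3:
        raise ValueError("phase shift requires >= 3 pre-stimulus peaks")
    idx = np.arange(len(pre))
    slope, intercept = np.polyfit(idx, pre, 1)
    predicted = intercept + slope * len(pre)

    post = features.peaks_after(stim_time_hr + exclusion_frac * slope)
    post = post[post <= stim_time_hr + 1.5 * slope]
    if len(post) == 0:
        raise ValueError("no post-stimulus peak within 1.5 predicted periods")
    observed = float(post[0])
    return PhaseShiftResult(
        predicted_peak_hr=float(predicted),
        observed_peak_hr=observed,
        shift_hr=float(predicted - observed),
        n_pre_peaks=len(pre),
        pre_period_hr=float(slope),
    )


def _marker_regression_period(times: np.ndarray) -> float:
    """Slope of marker time vs cycle index; robust to a missed cycle."""
    times = np.asarray(times, dtype=float)
    if len(times) < 3:
        raise ValueError("period regression needs >= 3 markers")
    spacing = np.median(np.diff(times))
    index = np.concatenate([[0.0], np.cumsum(np.rint(np.diff(times) / spacing))])
    return float(np.polyfit(index, times, 1)[0])


def period_estimate(
    data: Trace | RhythmFeatures,
    method: str = "peak_regression",
    search_range_hr: tuple[float, float] = PERIOD_SEARCH_HR,
) -> float:
    """Period in hours by one of the three supported estimators.

    ``peak_regression`` and ``halfmax_regression`` take a
    :class:`RhythmFeatures`; ``lomb_scargle`` takes a detrended
    :class:`Trace` and scans periods on a <= 0.01 h grid.
    """
    if method == "peak_regression":
        if not isinstance(data, RhythmFeatures):
            raise TypeError("peak_regression needs RhythmFeatures")
        return _marker_regression_period(data.peak_times)
    if method == "halfmax_regression":
        if not isinstance(data, RhythmFeatures):
            raise TypeError("halfmax_regression needs RhythmFeatures")
        return _marker_regression_period(data.halfmax_rising)
    if method == "lomb_scargle":
        if not isinstance(data, Trace):
            raise TypeError("lomb_scargle needs a Trace")
        lo, hi = search_range_hr
        periods = np.arange(lo, hi + PERIOD_GRID_STEP_HR / 2, PERIOD_GRID_STEP_HR)
        y = data.values - data.values.mean()
        power = lombscargle(data.time_hr, y, 2.0 * np.pi / periods)
        best = int(np.argmax(power))
        if best in (0, len(periods) - 1):
            raise ValueError("periodogram maximum on the search-range boundary")
        return float(periods[best])
    raise ValueError(f"unknown period method {method!r}")


def period_change(pre_period_hr: float, post_period_hr: float) -> float:
    """Signed change: positive = lengthening, negative = shortening."""
    return float(post_period_hr - pre_period_hr)


def _segment_features(trace: Trace, stim_time_hr: float | None = None) -> tuple[Trace, RhythmFeatures]:
    proc = smooth_moving_average(detrend_running_mean(trace, passes=2))
    return proc, find_features(proc, stim_time_hr=stim_time_hr)


def pulse_period_change(
    trace: Trace, stim_time_hr: float, method: str = "peak_regression"
) -> float:
    """Period change across a single pulse, excluding the stimulated cycle.

    The pre segment ends at the last trough before the pulse; the post
    segment starts at the first trough after the first post-stimulus peak.
    """
    proc, feats = _segment_features(trace, stim_time_hr)
    shift = phase_shift(feats, stim_time_hr)
    pre_end = feats.trough_times[feats.trough_times < stim_time_hr]
    post_start = feats.trough_times[feats.trough_times > shift.observed_peak_hr]
    if len(pre_end) == 0 or len(post_start) == 0:
        raise ValueError("cannot delimit pre/post segments around the pulse")
    t0, t1 = float(pre_end[-1]), float(post_start[0])

    if method == "lomb_scargle":
        # keep the edge-distorted filter spans out of the periodogram
        pre = period_estimate(
            proc.crop(proc.time_hr[0] + EDGE_EXCLUSION_HR, t0), "lomb_scargle"
        )
        post = period_estimate(
            proc.crop(t1, proc.time_hr[-1] - EDGE_EXCLUSION_HR), "lomb_scargle"
        )
    else:
        # marker regressions: every pre-stimulus peak is usable (the
        # stimulated cycle only contaminates the trace segment, not the
        # pre-pulse peak times); post markers start at the observed peak,
        # where the new period takes hold
        pre_feats = _mask_features(feats, upper=stim_time_hr)
        post_feats = _mask_features(feats, lower=shift.observed_peak_hr - 0.1)
        pre = period_estimate(pre_feats, method)
        post = period_estimate(post_feats, method)
    return period_change(pre, post)


def _mask_features(
    feats: RhythmFeatures, lower: float = -np.inf, upper: float = np.inf
) -> RhythmFeatures:
    def sel(times, values=None):
        m = (times >= lower) & (times <= upper)
        return (times[m], values[m]) if values is not None else times[m]

    pt, pv = sel(feats.peak_times, feats.peak_values)
    tt, tv = sel(feats.trough_times, feats.trough_values)
    _, amp = sel(feats.peak_times, feats.amplitudes)
    return RhythmFeatures(
        peak_times=pt, peak_values=pv, trough_times=tt, trough_values=tv,
        halfmax_rising=sel(feats.halfmax_rising), amplitudes=amp,
        damping_per_cycle=feats.damping_per_cycle,
        insufficient_for_period=len(pt) < 2,
    )


# ---------------------------------------------------------------------------
# envelope normalization and induction


def _geometric_fit(times: np.ndarray, values: np.ndarray):
    """Log-linear fit returning a callable envelope; constant if one point."""
    if np.any(values <= 0):
        raise ValueError("envelope fit needs positive magnitudes")
    if len(times) == 1:
        v = float(values[0])
        return lambda t: np.full_like(np.asarray(t, dtype=float), v)
    b1, b0 = np.polyfit(times, np.log(values), 1)
    return lambda t: np.exp(b0 + b1 * np.asarray(t, dtype=float))


def envelope_normalize(
    trace: Trace,
    features: RhythmFeatures,
    mode: str = "extrapolated",
    stim_time_hr: float | None = None,
    schedule_span: tuple[float, float] | None = None,
) -> Trace:
    """Map a detrended rhythm into [0, 1] between peak and trough envelopes.

    ``extrapolated`` fits geometric (log-linear) envelopes through the
    pre-stimulus peaks and troughs — the average damping of the rhythm — and
    extrapolates them over the whole trace.  ``interpolated_peaks`` anchors
    the lower envelope on the actual troughs and interpolates the peak
    envelope across the stimulated epoch from the surrounding free-running
    peaks (the variant used for long-T entrainment, where peak values during
    entrainment are not representative).
    """
    t = trace.time_hr
    if mode == "extrapolated":
        pk_t, pk_v = features.peak_times, features.peak_values
        tr_t, tr_v = features.trough_times, features.trough_values
        if stim_time_hr is not None:
            pre_p = pk_t < stim_time_hr
            pre_t = tr_t < stim_time_hr
            if pre_p.sum() >= 2 and pre_t.sum() >= 2:
                pk_t, pk_v = pk_t[pre_p], pk_v[pre_p]
                tr_t, tr_v = tr_t[pre_t], tr_v[pre_t]
        if len(pk_t) < 2 or len(tr_t) < 2:
            raise ValueError("envelope extrapolation needs >= 2 pre-stimulus cycles")
        if np.any(tr_v >= 0):
            raise ValueError("trough envelope fit expects detrended (negative) troughs")
        P = _geometric_fit(pk_t, pk_v)(t)
        Q = -_geometric_fit(tr_t, -tr_v)(t)
    elif mode == "interpolated_peaks":
        if len(features.trough_times) < 2:
            raise ValueError("need >= 2 troughs for the interpolated variant")
        Q = np.interp(t, features.trough_times, features.trough_values)
        pk_t, pk_v = features.peak_times, features.peak_values
        if schedule_span is not None:
            lo, hi = schedule_span
            before = pk_t < lo
            after = pk_t > hi
            keep = before.copy()
            if after.any():
                keep[np.argmax(after)] = True  # first free-running peak after release
            if keep.sum() >= 2:
                pk_t, pk_v = pk_t[keep], pk_v[keep]
        log_p = np.log(pk_v)
        P = np.exp(np.interp(t, pk_t, log_p))
    else:
        raise ValueError(f"unknown envelope mode {mode!r}")
    if np.any(P <= Q):
        raise ValueError("peak envelope does not exceed trough envelope everywhere")
    out = (trace.values - Q) / (P - Q)
    return trace.copy_with(
        out,
        units="normalized (envelope)",
        timing_basis=trace.meta.get("raw_values"),
    )


def induction_metrics(
    stim_norm: Trace,
    ref_norm: Trace,
    stim_time_hr: float,
    period_hr: float = 24.0,
) -> dict:
    """Difference profile and normalized induction of a stimulated rhythm.

    Both inputs must be envelope-normalized on a common time base.  The
    normalized induction is the max − min of (stimulated − reference) over
    the first cycle after pulse onset, in envelope amplitude units (AU).
    """
    if len(stim_norm.time_hr) != len(ref_norm.time_hr) or np.max(
        np.abs(stim_norm.time_hr - ref_norm.time_hr)
    ) > stim_norm.sampling_interval_hr:
        raise ValueError("time bases differ by more than one sample")
    diff = stim_norm.values - ref_norm.values
    win = (stim_norm.time_hr >= stim_time_hr) & (
        stim_norm.time_hr <= stim_time_hr + period_hr
    )
    if not win.any():
        raise ValueError("no samples in the first post-stimulus cycle")
    induction = float(diff[win].max() - diff[win].min())
    return {
        "difference": stim_norm.copy_with(diff, units="normalized difference"),
        "normalized_induction": induction,
    }


# ---------------------------------------------------------------------------
# rising / falling durations


def _derivative_boundaries(
    trace: Trace,
    schedule: StimSchedule | None,
    smooth_window_hr: float = 2.4,
    eps_frac: float = 0.05,
) -> list[tuple[float, str]]:
    """Times where the smoothed first derivative crosses zero.

    Returns (time, kind) with kind 'peak' for downward and 'trough' for
    upward crossings.  Crossings within ``EDGE_EXCLUSION_HR`` of either end
    are dropped (shrinking filter windows distort them).  When the trace
    carries a baseline-restored ``timing_basis`` (recorded by the detrender
    and propagated through envelope normalization), each crossing time is
    refined by a local quadratic fit on that basis, making the timing immune
    to baseline-subtraction artifacts.  Where the derivative dips close to
    zero after a pulse without changing sign (PER2 induction propping up the
    signal), the local minimum of the derivative ends the rising phase.
    """
    t, v = trace.time_hr, trace.values
    dt = trace.sampling_interval_hr
    d = np.gradient(v, dt)
    d = _running_mean(d, _window_samples(smooth_window_hr, dt))

    boundaries: list[tuple[float, str]] = []
    idx = np.flatnonzero((d[:-1] > 0) & (d[1:] <= 0))
    for i in idx:
        frac = d[i] / (d[i] - d[i + 1]) if d[i] != d[i + 1] else 0.5
        boundaries.append((float(t[i] + frac * dt), "peak"))
    idx = np.flatnonzero((d[:-1] < 0) & (d[1:] >= 0))
    for i in idx:
        frac = d[i] / (d[i] - d[i + 1]) if d[i] != d[i + 1] else 0.5
        boundaries.append((float(t[i] + frac * dt), "trough"))

    lo_t, hi_t = t[0] + EDGE_EXCLUSION_HR, t[-1] - EDGE_EXCLUSION_HR
    boundaries = [b for b in boundaries if lo_t <= b[0] <= hi_t]

    basis = trace.meta.get("timing_basis")
    if basis is not None:
        from .preprocess import _refine_extremum, _refine_half_hr

        half = max(2, int(round(_refine_half_hr(v, basis) / dt)))
        refined = []
        for bt, kind in boundaries:
            i = int(round((bt - t[0]) / dt))
            i = min(max(i, 0), len(t) - 1)
            sign = 1.0 if kind == "peak" else -1.0
            rt, _ = _refine_extremum(t, sign * v, i, half,
                                     timing_basis=sign * basis)
            refined.append((rt, kind))
        boundaries = refined

    if schedule is not None:
        eps = eps_frac * float(np.percentile(np.abs(d), 98))
        have_peak = np.array([b[0] for b in boundaries if b[1] == "peak"])
        for pulse in schedule.pulses:
            lo, hi = pulse.onset_hr, pulse.onset_hr + 6.0
            if np.any((have_peak >= lo - 2.0) & (have_peak <= hi)):
                continue
            win = (t >= lo) & (t <= hi)
            if not win.any():
                continue
            dw = d[win]
            tw = t[win]
            j = int(np.argmin(dw))
            if 0.0 < dw[j] < eps and 0 < j < len(dw) - 1:
                boundaries.append((float(tw[j]), "peak"))
    boundaries.sort(key=lambda b: b[0])
    # drop duplicate kinds that can arise from an inserted fallback boundary
    cleaned: list[tuple[float, str]] = []
    for b in boundaries:
        if cleaned and cleaned[-1][1] == b[1]:
            continue
        cleaned.append(b)
    return cleaned


def cycle_durations(
    trace: Trace,
    schedule: StimSchedule | None = None,
    eps_frac: float = 0.05,
) -> WaveformMetrics:
    """Per-cycle rising and falling durations from derivative zero crossings.

    ``trace`` should be the smoothed, envelope-normalized rhythm.  Each cycle
    is anchored at a peak: rising = preceding upward crossing to the peak,
    falling = peak to the next upward crossing.
    """
    bounds = _derivative_boundaries(trace, schedule, eps_frac=eps_frac)
    if not any(k == "peak" for _, k in bounds):
        raise ValueError("no derivative zero crossings found")
    rising, falling, anchors = [], [], []
    for i, (bt, kind) in enumerate(bounds):
        if kind != "peak":
            continue
        r = f = np.nan
        if i > 0 and bounds[i - 1][1] == "trough":
            r = bt - bounds[i - 1][0]
        if i + 1 < len(bounds) and bounds[i + 1][1] == "trough":
            f = bounds[i + 1][0] - bt
        rising.append(r)
        falling.append(f)
        anchors.append(bt)
    return WaveformMetrics(
        rising_hr=np.array(rising),
        falling_hr=np.array(falling),
        cycle_peak_times=np.array(anchors),
    )


def fold_changes_single_pulse(
    metrics: WaveformMetrics, stim_time_hr: float
) -> WaveformMetrics:
    """Stimulated-cycle durations over the mean pre-stimulus cycle.

    The stimulated rising (falling) segment is the first one whose ending
    peak (trough) falls after pulse onset; baselines average every complete
    pre-stimulus cycle.
    """
    pk = metrics.cycle_peak_times
    rise_end = pk                      # rising ends at its anchor peak
    fall_end = pk + metrics.falling_hr  # falling ends at the next trough

    stim_r = np.flatnonzero((rise_end > stim_time_hr) & np.isfinite(metrics.rising_hr))
    stim_f = np.flatnonzero((fall_end > stim_time_hr) & np.isfinite(metrics.falling_hr))
    pre_r = metrics.rising_hr[(rise_end < stim_time_hr) & np.isfinite(metrics.rising_hr)]
    pre_f = metrics.falling_hr[(fall_end < stim_time_hr) & np.isfinite(metrics.falling_hr)]
    if len(stim_r) == 0 or len(stim_f) == 0 or len(pre_r) == 0 or len(pre_f) == 0:
        raise ValueError("need complete cycles before and after the pulse")
    rising_fc = float(metrics.rising_hr[stim_r[0]] / pre_r.mean())
    falling_fc = float(metrics.falling_hr[stim_f[0]] / pre_f.mean())
    return WaveformMetrics(
        rising_hr=metrics.rising_hr,
        falling_hr=metrics.falling_hr,
        cycle_peak_times=pk,
        rising_fc=rising_fc,
        falling_fc=falling_fc,
    )


def fold_changes_entrained(
    metrics: WaveformMetrics, schedule: StimSchedule
) -> WaveformMetrics:
    """Mean entrained-cycle durations over the mean pre-entrainment cycle."""
    lo, hi = schedule.span
    pk = metrics.cycle_peak_times
    during = (pk >= lo) & (pk <= hi)
    pre = pk < lo
    r_during = metrics.rising_hr[during & np.isfinite(metrics.rising_hr)]
    f_during = metrics.falling_hr[during & np.isfinite(metrics.falling_hr)]
    r_pre = metrics.rising_hr[pre & np.isfinite(metrics.rising_hr)]
    f_pre = metrics.falling_hr[pre & np.isfinite(metrics.falling_hr)]
    if min(map(len, (r_during, f_during, r_pre, f_pre))) == 0:
        raise ValueError("need complete cycles before and during entrainment")
    return WaveformMetrics(
        rising_hr=metrics.rising_hr,
        falling_hr=metrics.falling_hr,
        cycle_peak_times=pk,
        rising_fc=float(r_during.mean() / r_pre.mean()),
        falling_fc=float(f_during.mean() / f_pre.mean()),
    )
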