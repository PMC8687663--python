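"""Detrending, smoothing, extremum detection and actograms.

The raw luminometer signal is baseline-subtracted with a centered 24 h
running average and smoothed with a centered 2.4 h moving average, mirroring
standard luminometry practice.  Both filters use a trapezoid-weighted window
(half-weight endpoints) spanning exactly the requested number of hours: a
trapezoid window integrates any pure cosine over one full period to exactly
zero, so detrending with a window equal to the period leaves the rhythm
untouched away from the edges, and linear trends are exact fixed points of
the smoother.  At the edges the window shrinks symmetrically to the
available span.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import find_peaks

from .core import RhythmFeatures, Trace

__all__ = [
    "detrend_running_mean",
    "smooth_moving_average",
    "find_features",
    "fit_damping",
    "build_actogram",
    "amplitude_fold_change",
]


def _window_samples(window_hr: float, dt: float) -> int:
    """Window span in samples: hours rounded up to an odd sample count."""
    n_intervals = int(np.ceil(round(window_hr / dt, 9)))
    if n_intervals % 2 == 1:
        n_intervals += 1
    return n_intervals + 1  # odd


def _running_mean(values: np.ndarray, n: int) -> np.ndarray:
    """Centered trapezoid-weighted running mean, shrinking at the edges."""
    half = (n - 1) // 2
    w = np.ones(n)
    w[0] = w[-1] = 0.5
    w /= w.sum()
    out = np.convolve(values, w, mode="same")
    # recompute the edge samples with a symmetrically shrunken window
    m = len(values)
    for i in range(min(half, m)):
        k = min(i, m - 1 - i)
        if k == 0:
            out[i] = values[i]
            out[m - 1 - i] = values[m - 1 - i]
            continue
        wk = np.ones(2 * k + 1)
        wk[0] = wk[-1] = 0.5
        wk /= wk.sum()
        out[i] = values[i - k : i + k + 1] @ wk
        out[m - 1 - i] = values[m - 1 - i - k : m - i + k] @ wk
    return out


def detrend_running_mean(
    trace: Trace, window_hr: float = 24.0, passes: int = 1
) -> Trace:
    """Subtract a centered running-average baseline (default 24 h).

    With ``passes > 1`` the running mean is iterated before subtraction:
    a single 24 h mean of a rhythm whose local period deviates from 24 h
    retains a fraction of the oscillation in the baseline (which then
    distorts extremum timing when subtracted); each extra pass suppresses
    that leakage quadratically while still removing constant and linear
    drift exactly away from the edges.  The subtracted baseline is kept in
    ``meta['baseline']`` so later stages can time extrema against the
    undistorted raw signal.
    """
    dt = trace.sampling_interval_hr
    n = _window_samples(window_hr, dt)
    if len(trace.values) < n:
        raise ValueError("trace shorter than one detrending window")
    baseline = trace.values
    for _ in range(passes):
        baseline = _running_mean(baseline, n)
    return trace.copy_with(
        trace.values - baseline,
        units="counts (detrended)",
        baseline=baseline,
        raw_values=trace.values.copy(),
    )


def smooth_moving_average(trace: Trace, window_hr: float = 2.4) -> Trace:
    """Centered moving average (default 2.4 h); linear signals are fixed points."""
    dt = trace.sampling_interval_hr
    if window_hr < 2.0 * dt:
        raise ValueError("smoothing window must span at least 3 samples")
    n = _window_samples(window_hr, dt)
    if len(trace.values) < n:
        raise ValueError("trace shorter than one smoothing window")
    return trace.copy_with(_running_mean(trace.values, n))


def _noise_sd_estimate(values: np.ndarray) -> float:
    """Robust noise SD from second differences (MAD-based).

    Second differences of a smooth rhythm are tiny (|y''| dt^2) while white
    noise contributes sqrt(6) sigma, so this cleanly separates measurement
    noise from signal.
    """
    d2 = np.diff(values, 2)
    return float(1.4826 * np.median(np.abs(d2 - np.median(d2))) / np.sqrt(6.0))


def _refine_half_hr(detrended: np.ndarray, basis: np.ndarray | None) -> float:
    """Half-width (hours) of the local cubic fit used to time extrema.

    Noise-free data favors a narrow window — the cubic then tracks strongly
    asymmetric cycles with minimal higher-order bias — while noisy data
    needs a wide window to average the noise out of the vertex estimate.
    """
    src = detrended if basis is None else basis
    sd = _noise_sd_estimate(src)
    lo, hi = np.percentile(detrended, [2.5, 97.5])
    scale = max((hi - lo) / 2.0, 1e-12)
    rel = sd / scale
    if rel < 0.005:
        return 1.2
    if rel < 0.02:
        return 2.5
    return 4.0


def _refine_extremum(
    t: np.ndarray,
    v: np.ndarray,
    idx: int,
    half_samples: int,
    timing_basis: np.ndarray | None = None,
    exclude: np.ndarray | None = None,
) -> tuple[float, float]:
    """Sub-sample extremum time/value by local quadratic least squares.

    When ``timing_basis`` is given (the baseline-restored raw signal), the
    vertex *time* is taken from a fit on it — a quadratic absorbs any
    locally linear baseline, so timing is immune to detrending artifacts —
    while the extremum *value* is read off the detrended signal.
    """
    lo = max(0, idx - half_samples)
    hi = min(len(v), idx + half_samples + 1)
    keep = np.ones(hi - lo, dtype=bool)
    if exclude is not None:
        keep = ~exclude[lo:hi]
    x = (t[lo:hi] - t[idx])[keep]
    y = v[lo:hi][keep]
    if len(x) < 5:
        return float(t[idx]), float(v[idx])
    span = 0.6 * (x[-1] - x[0]) / 2.0
    basis = y if timing_basis is None else timing_basis[lo:hi][keep]

    # cubic fit: the odd term absorbs rising/falling asymmetry around the
    # extremum, which would bias a plain parabola's vertex
    vertex = None
    b3, b2, b1, _ = np.polyfit(x, basis, 3)
    roots = np.roots([3.0 * b3, 2.0 * b2, b1])
    real = roots[np.abs(roots.imag) < 1e-12].real
    real = real[(real >= -span) & (real <= span) & (6.0 * b3 * real + 2.0 * b2 < 0)]
    if len(real):
        vertex = float(real[np.argmin(np.abs(real))])
    else:  # degenerate cubic; fall back to the parabola vertex
        c2, c1, _ = np.polyfit(x, basis, 2)
        if c2 != 0 and -span <= -c1 / (2.0 * c2) <= span:
            vertex = float(-c1 / (2.0 * c2))
    if vertex is None:
        return float(t[idx]), float(v[idx])
    c2, c1, c0 = np.polyfit(x, y, 2)
    return float(t[idx] + vertex), float(c0 + c1 * vertex + c2 * vertex**2)


def find_features(
    trace: Trace,
    min_prominence_frac: float = 0.2,
    min_separation_hr: float = 16.0,
    stim_time_hr: float | None = None,
    edge_exclusion_hr: float = 12.0,
    induction_exclusion_hr: float = 6.0,
) -> RhythmFeatures:
    """Detect peaks, troughs, rising half-max crossings and per-cycle amplitudes.

    Expects a detrended, smoothed trace.  Extrema must be separated by at
    least ``min_separation_hr`` and have prominence of at least
    ``min_prominence_frac`` times the median per-cycle amplitude; the
    separation default (16 h) keeps acute induction transients from being
    called peaks.  Extremum times are refined to sub-sample precision with a
    local quadratic fit on the baseline-restored signal when the detrender
    recorded its baseline.  Extrema within ``edge_exclusion_hr`` of either
    end are dropped: there the shrinking detrend/smoothing windows distort
    timing.  When ``stim_time_hr`` is given, extrema inside the acute
    induction window (``induction_exclusion_hr`` after the pulse) are
    discarded *before* the separation rule is applied, so a large PER2
    induction transient can neither be called a peak nor suppress the
    genuine peak next to it; the damping rate is then fitted on pre-stimulus
    cycles only.
    """
    t, v = trace.time_hr, trace.values
    dt = trace.sampling_interval_hr
    dist = max(1, int(round(min_separation_hr / dt)))

    # first pass without a prominence floor, to scale the cycle amplitude
    pk0, _ = find_peaks(v, distance=dist)
    tr0, _ = find_peaks(-v, distance=dist)
    if len(pk0) == 0 or len(tr0) == 0:
        return RhythmFeatures(
            peak_times=np.array([]), peak_values=np.array([]),
            trough_times=np.array([]), trough_values=np.array([]),
            halfmax_rising=np.array([]), amplitudes=np.array([]),
            insufficient_for_period=True,
        )
    amps0 = [
        v[p] - v[tr0[tr0 < p][-1]] for p in pk0 if np.any(tr0 < p)
    ] or [np.ptp(v)]
    prom = min_prominence_frac * float(np.median(amps0))

    pk, _ = find_peaks(v, prominence=prom)
    tr, _ = find_peaks(-v, prominence=prom)

    bump_zone = None
    if stim_time_hr is not None and induction_exclusion_hr > 0:
        # A PER2 induction bump right after the pulse is a spurious peak and
        # can also gut the prominence of the genuine peak beside it.  When
        # the acute window shows clear excess signal over a linear bridge
        # across it: detect additionally on the bridged copy (recovers the
        # genuine peak), take the union, discard any peak inside the window,
        # and remember the contaminated zone so the extremum fits skip it.
        # The dip the bump carves out is resolved by the alternation rule.
        # The window starts before onset because smoothing spreads the
        # transient backwards by about half the smoothing window.
        lo_win = stim_time_hr - 1.5
        hi_win = stim_time_hr + induction_exclusion_hr
        in_win = (t > lo_win) & (t <= hi_win)
        flank = ((t > lo_win - 5.0) & (t <= lo_win)) | (
            (t > hi_win) & (t <= hi_win + 5.0)
        )
        if in_win.any() and flank.sum() >= 8:
            # predict the window from a quartic fitted to its flanks; a
            # plain chord would mistake waveform curvature for induction
            coef = np.polyfit(t[flank] - stim_time_hr, v[flank], 4)
            bridged = np.polyval(coef, t[in_win] - stim_time_hr)
            excess = float(np.max(v[in_win] - bridged))
            lo_p, hi_p = np.percentile(v, [2.5, 97.5])
            threshold = max(0.1 * (hi_p - lo_p) / 2.0,
                            4.0 * _noise_sd_estimate(v))
            if excess > threshold:
                v_bridged = v.copy()
                v_bridged[in_win] = np.interp(t[in_win], t[~in_win], v[~in_win])
                pk_b, _ = find_peaks(v_bridged, prominence=prom)
                pk = np.union1d(pk, pk_b)
                pk = np.array(
                    [i for i in pk if not (lo_win < t[i] <= hi_win)],
                    dtype=int,
                )
                bump_zone = in_win

    def enforce_separation(idx: np.ndarray, sign: float) -> np.ndarray:
        keep: list[int] = []
        for i in idx:
            if keep and (t[i] - t[keep[-1]]) < min_separation_hr:
                if sign * v[i] > sign * v[keep[-1]]:
                    keep[-1] = i
            else:
                keep.append(i)
        return np.array(keep, dtype=int)

    pk = enforce_separation(pk, 1.0)
    tr = enforce_separation(tr, -1.0)

    # enforce alternation: within a same-type run keep the most extreme event
    events = sorted(
        [(i, 1) for i in pk] + [(i, 0) for i in tr], key=lambda e: e[0]
    )
    kept: list[tuple[int, int]] = []
    for i, kind in events:
        if kept and kept[-1][1] == kind:
            prev = kept[-1][0]
            better = v[i] > v[prev] if kind == 1 else v[i] < v[prev]
            if better:
                kept[-1] = (i, kind)
        else:
            kept.append((i, kind))
    pk = np.array([i for i, k in kept if k == 1], dtype=int)
    tr = np.array([i for i, k in kept if k == 0], dtype=int)

    # drop extrema whose windows hang off the recording
    lo_t = t[0] + edge_exclusion_hr
    hi_t = t[-1] - edge_exclusion_hr
    pk = pk[(t[pk] >= lo_t) & (t[pk] <= hi_t)]
    tr = tr[(t[tr] >= lo_t) & (t[tr] <= hi_t)]

    # time extrema against the raw signal: smoothing and baseline
    # subtraction both displace the extrema of asymmetric cycles, while a
    # local cubic fit on the raw signal absorbs the baseline and the
    # asymmetry at once
    raw = trace.meta.get("raw_values")
    half = max(2, int(round(_refine_half_hr(v, raw) / dt)))
    peak_times, peak_values = [], []
    for i in pk:
        pt, pv = _refine_extremum(t, v, i, half, timing_basis=raw,
                                  exclude=bump_zone)
        peak_times.append(pt)
        peak_values.append(pv)
    trough_times, trough_values = [], []
    for i in tr:
        tt, tv = _refine_extremum(t, -v, i, half,
                                  timing_basis=None if raw is None else -raw,
                                  exclude=bump_zone)
        trough_times.append(tt)
        trough_values.append(-tv)

    peak_times = np.array(peak_times)
    peak_values = np.array(peak_values)
    trough_times = np.array(trough_times)
    trough_values = np.array(trough_values)

    # per-cycle amplitude: peak minus the preceding trough.  Measured on the
    # raw signal when available: mesor and slow drift cancel in the
    # difference, and the raw signal carries no baseline-subtraction
    # transient (which can be large around abrupt amplitude changes).
    def value_at(time_hr: float, source: np.ndarray) -> float:
        sel = np.abs(t - time_hr) <= 0.5  # short mean averages noise out
        return float(source[sel].mean()) if sel.any() else float(
            np.interp(time_hr, t, source)
        )

    amp_src = raw if raw is not None else v
    amplitudes = []
    for ptime in peak_times:
        prior = trough_times < ptime
        if np.any(prior):
            ttime = trough_times[prior][np.argmax(trough_times[prior])]
            amplitudes.append(value_at(ptime, amp_src) - value_at(ttime, amp_src))
        else:
            amplitudes.append(np.nan)
    amplitudes = np.array(amplitudes)

    # rising half-max: first crossing of (trough+peak)/2 between the pair
    halfmax = []
    for ptime, pval in zip(peak_times, peak_values):
        prior = trough_times < ptime
        if not np.any(prior):
            continue
        j = np.argmax(trough_times[prior])
        ttime = trough_times[prior][j]
        tval = trough_values[prior][j]
        level = 0.5 * (tval + pval)
        sel = (t >= ttime) & (t <= ptime)
        idx = np.flatnonzero(sel)
        seg = v[idx]
        above = seg >= level
        if not above.any() or above[0]:
            continue
        k = int(np.argmax(above))
        i0, i1 = idx[k - 1], idx[k]
        frac = (level - v[i0]) / (v[i1] - v[i0])
        halfmax.append(t[i0] + frac * (t[i1] - t[i0]))
    halfmax = np.array(halfmax)
    # half-max crossings are read off the detrended signal and cannot be
    # re-timed against the raw one, so keep a full detrend window clear of
    # the ends where the shrinking baseline distorts them
    if len(halfmax):
        halfmax = halfmax[
            (halfmax >= t[0] + 2 * edge_exclusion_hr)
            & (halfmax <= t[-1] - 2 * edge_exclusion_hr)
        ]

    feats = RhythmFeatures(
        peak_times=peak_times, peak_values=peak_values,
        trough_times=trough_times, trough_values=trough_values,
        halfmax_rising=halfmax, amplitudes=amplitudes,
        insufficient_for_period=len(peak_times) < 2,
    )
    ok = np.isfinite(feats.amplitudes)
    if stim_time_hr is not None:
        ok &= feats.peak_times < stim_time_hr
    if ok.sum() >= 3:
        feats.damping_per_cycle = fit_damping(feats.amplitudes[ok])
    return feats


def fit_damping(amplitudes) -> float:
    """Per-cycle damping: exp of the slope of log amplitude vs cycle index.

    Equivalent to the geometric mean of successive amplitude ratios when no
    cycles are missing.
    """
    a = np.asarray(
        amplitudes.amplitudes if isinstance(amplitudes, RhythmFeatures) else amplitudes,
        dtype=float,
    )
    a = a[np.isfinite(a)]
    if len(a) < 3:
        raise ValueError("damping fit needs >= 3 per-cycle amplitudes")
    if np.any(a <= 0):
        raise ValueError("per-cycle amplitudes must be positive")
    slope = np.polyfit(np.arange(len(a)), np.log(a), 1)[0]
    return float(np.exp(slope))


def build_actogram(
    trace: Trace, modulo_hr: float = 24.0, double_plot: bool = True
) -> np.ndarray:
    """Raster matrix of the trace, one ``modulo_hr`` window per row.

    Each row is independently min-max normalized to [0, 1]; degenerate rows
    (min == max) map to 0.  When double-plotting, each row is concatenated
    with the following window; missing samples in the final row are NaN.
    """
    dt = trace.sampling_interval_hr
    m = int(round(modulo_hr / dt))
    if len(trace.values) < m:
        raise ValueError("trace spans less than one modulo")
    n_rows = len(trace.values) // m
    width = 2 * m if double_plot else m
    out = np.full((n_rows, width), np.nan)
    for i in range(n_rows):
        seg = trace.values[i * m : i * m + width]
        out[i, : len(seg)] = seg
    for i in range(n_rows):
        row = out[i]
        finite = np.isfinite(row)
        lo, hi = np.nanmin(row), np.nanmax(row)
        if hi > lo:
            out[i, finite] = (row[finite] - lo) / (hi - lo)
        else:
            out[i, finite] = 0.0
    return out


def amplitude_fold_change(features: RhythmFeatures, treatment_time_hr: float) -> float:
    """First post-treatment cycle amplitude over the last pre-treatment one."""
    ok = np.isfinite(features.amplitudes)
    times = features.peak_times[ok]
    amps = features.amplitudes[ok]
    pre = times < treatment_time_hr
    post = times > treatment_time_hr
    if not pre.any() or not post.any():
        raise ValueError("need a full cycle on each side of the treatment")
    last_pre = amps[pre][-1]
    first_post = amps[post][0]
    return float(first_post / last_pre)
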