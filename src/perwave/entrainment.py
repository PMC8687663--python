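"""Entrainment metrics for repeated stimulation schedules.

Covers circadian-time bookkeeping (CT12 = PER2::LUC peak), the phase angle
of entrainment (dusk pulse onset minus the rising half-max of the same
cycle) and its stability, the entrained period from half-max regression,
period after-effects across an entrainment epoch, and classification of
skeleton-photoperiod runs into entrained / phase-jumped / free-running.

A run counts as entrained when the half-max period matches the schedule's
cycle length within ``PERIOD_TOL_HR`` and the phase-angle drift stays within
``SLOPE_TOL_HR`` per cycle.  A phase jump is the characteristic rapid
advance of the rising phase across the nominal dawn pulse: the cumulative
advance must exceed ``jump_threshold_hr`` within ``max_jump_cycles`` cycles,
the rising half-max must cross the dawn pulse, and the rhythm must hold a
stable angle afterwards (otherwise the run is simply free-running through
the schedule).
"""

from __future__ import annotations

import numpy as np

from .core import EntrainmentResult, RhythmFeatures, StimSchedule, Trace
from .resetting import period_estimate, _mask_features, _segment_features

__all__ = [
    "circadian_time",
    "next_stim_time",
    "phase_angles",
    "entrained_period",
    "detect_phase_jump",
    "aftereffect",
    "classify_entrainment",
]

PERIOD_TOL_HR = 0.25
SLOPE_TOL_HR = 0.15
JUMP_THRESHOLD_HR = 4.0
MAX_JUMP_CYCLES = 4
POST_JUMP_DRIFT_TOL_HR = 0.5


def circadian_time(
    features: RhythmFeatures, t_hr: float, free_running_period_hr: float
) -> float:
    """Circadian time of clock hour ``t_hr``; CT12 is the PER2::LUC peak."""
    prior = features.peak_times[features.peak_times <= t_hr]
    if len(prior) == 0:
        raise ValueError("no peak before the requested time")
    last_peak = float(prior[-1])
    return float(
        (12.0 + 24.0 * (t_hr - last_peak) / free_running_period_hr) % 24.0
    )


def next_stim_time(
    features: RhythmFeatures, target_ct: float, free_running_period_hr: float
) -> float:
    """Earliest time after the last detected peak with the requested CT."""
    if features.n_peaks == 0:
        raise ValueError("no peak to anchor circadian time")
    last_peak = float(features.peak_times[-1])
    offset_ct = (target_ct - 12.0) % 24.0
    if offset_ct == 0.0:
        offset_ct = 24.0
    return last_peak + offset_ct / 24.0 * free_running_period_hr


def _reference_pulses(schedule: StimSchedule) -> np.ndarray:
    if schedule.structure == "skeleton":
        return np.array([p.onset_hr for p in schedule.labelled("dusk")])
    return schedule.onsets


def phase_angles(
    features: RhythmFeatures, schedule: StimSchedule
) -> tuple[np.ndarray, np.ndarray, float | None]:
    """Per-cycle phase angle of entrainment and its regression slope.

    angle = reference (dusk) pulse onset − nearest rising half-max.  Cycles
    without a detected half-max are skipped.  The slope is in hours per
    cycle; 0 means a stable phase angle.
    """
    refs = _reference_pulses(schedule)
    half = features.halfmax_rising
    if len(half) == 0:
        raise ValueError("no rising half-max markers detected")
    cycle = schedule.cycle_hr or schedule.T_hr or 24.0
    angles, indices = [], []
    for i, onset in enumerate(refs):
        d = onset - half
        j = int(np.argmin(np.abs(d)))
        if abs(d[j]) > cycle:
            continue
        angles.append(float(d[j]))
        indices.append(i)
    angles = np.array(angles)
    indices = np.array(indices)
    slope = (
        float(np.polyfit(indices, angles, 1)[0]) if len(angles) >= 3 else None
    )
    return angles, indices, slope


def entrained_period(features: RhythmFeatures, schedule: StimSchedule) -> float:
    """Period during the stimulated epoch from rising half-max regression."""
    lo, hi = schedule.span
    half = features.halfmax_rising
    half = half[(half >= lo - 2.0) & (half <= hi + 2.0)]
    if len(half) < 3:
        raise ValueError("need >= 3 rising half-maxes during entrainment")
    spacing = np.median(np.diff(half))
    index = np.concatenate([[0.0], np.cumsum(np.rint(np.diff(half) / spacing))])
    return float(np.polyfit(index, half, 1)[0])


def detect_phase_jump(
    features: RhythmFeatures,
    schedule: StimSchedule,
    jump_threshold_hr: float = JUMP_THRESHOLD_HR,
    max_jump_cycles: int = MAX_JUMP_CYCLES,
) -> tuple[str, int | None, dict]:
    """Classify a skeleton-photoperiod run; see module docstring for criteria."""
    cycle = schedule.cycle_hr or 24.0
    lo, hi = schedule.span
    half = features.halfmax_rising
    half = half[(half >= lo - cycle) & (half <= hi + 2.0)]
    diagnostics: dict = {}
    if len(half) < 4:
        return "free_running", None, {"reason": "too few half-max markers"}

    drift = np.diff(half) - cycle  # negative = advancing
    diagnostics["drift_hr_per_cycle"] = drift

    # cumulative advance over any window of at most max_jump_cycles steps
    best_adv, best_end = 0.0, None
    for i in range(len(drift)):
        for j in range(i, min(i + max_jump_cycles, len(drift))):
            adv = -np.sum(drift[i : j + 1])
            if adv > best_adv:
                best_adv, best_end = adv, j + 1
    diagnostics["max_cumulative_advance_hr"] = best_adv

    dawns = np.array([p.onset_hr for p in schedule.labelled("dawn")])
    crossed = False
    if len(dawns) > 0:
        rel = []
        for h in half:
            d = h - dawns
            rel.append(d[np.argmin(np.abs(d))])
        rel = np.array(rel)
        diagnostics["halfmax_minus_dawn_hr"] = rel
        # an advance carries the half-max from after a dawn pulse to before
        # it within one cycle (large steps are wrap-around artifacts)
        crossed = bool(
            np.any(
                (rel[:-1] > 0)
                & (rel[1:] <= 0)
                & (rel[:-1] - rel[1:] < cycle / 2.0)
            )
        )

    if best_adv >= jump_threshold_hr and crossed and best_end is not None:
        # stable phase angle over the cycles right after the jump
        tail = drift[best_end : best_end + 3]
        if len(tail) >= 2 and np.all(np.abs(tail) <= POST_JUMP_DRIFT_TOL_HR):
            return "phase_jumped", int(best_end), diagnostics
    return "ambiguous", None, diagnostics


def classify_entrainment(
    features: RhythmFeatures,
    schedule: StimSchedule,
    period_tol_hr: float = PERIOD_TOL_HR,
    slope_tol_hr: float = SLOPE_TOL_HR,
    jump_threshold_hr: float = JUMP_THRESHOLD_HR,
    max_jump_cycles: int = MAX_JUMP_CYCLES,
) -> EntrainmentResult:
    """Full entrainment read-out: angles, period, classification."""
    cycle = schedule.cycle_hr or schedule.T_hr or 24.0
    angles, indices, slope = phase_angles(features, schedule)
    try:
        period = entrained_period(features, schedule)
    except ValueError:
        period = None

    classification = "free_running"
    jump_idx = None
    diagnostics: dict = {}
    stable = (
        period is not None
        and abs(period - cycle) <= period_tol_hr
        and slope is not None
        and abs(slope) <= slope_tol_hr
    )
    if stable:
        classification = "entrained"
    elif schedule.structure == "skeleton":
        verdict, jump_idx, diagnostics = detect_phase_jump(
            features, schedule, jump_threshold_hr, max_jump_cycles
        )
        if verdict == "phase_jumped":
            classification = "phase_jumped"
    return EntrainmentResult(
        phase_angle_hr=angles,
        angle_cycle_index=indices,
        angle_slope_hr_per_cycle=slope,
        entrained_period_hr=period,
        classification=classification,
        jump_cycle_index=jump_idx,
        diagnostics=diagnostics,
    )


def aftereffect(
    trace: Trace, schedule: StimSchedule, method: str = "peak_regression"
) -> float:
    """Period after-effect: post-release minus pre-entrainment period.

    Both epochs are measured with the same estimator; the stimulated epoch
    itself is excluded.
    """
    lo, hi = schedule.span
    proc, feats = _segment_features(trace)
    if method == "lomb_scargle":
        from .resetting import EDGE_EXCLUSION_HR

        pre = period_estimate(
            proc.crop(proc.time_hr[0] + EDGE_EXCLUSION_HR, lo), "lomb_scargle"
        )
        post = period_estimate(
            proc.crop(hi, proc.time_hr[-1] - EDGE_EXCLUSION_HR), "lomb_scargle"
        )
    else:
        pre_feats = _mask_features(feats, upper=lo)
        post_feats = _mask_features(feats, lower=hi)
        pre = period_estimate(pre_feats, method)
        post = period_estimate(post_feats, method)
    return float(post - pre)
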