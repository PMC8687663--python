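"""Domain containers for bioluminescence rhythm analysis.

The central objects are :class:`Trace` (a uniformly sampled luminescence time
series), :class:`StimSchedule` (an ordered list of optogenetic pulses plus
cycle-structure metadata), and :class:`RhythmFeatures` (detected extrema,
half-max crossings, per-cycle amplitudes and the damping rate).  All times are
in hours from the start of recording; values are luminometer counts unless a
trace has been detrended or envelope-normalized, in which case the units are
noted in ``meta``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "Trace",
    "StimSchedule",
    "Pulse",
    "RhythmFeatures",
    "PhaseShiftResult",
    "WaveformMetrics",
    "EntrainmentResult",
]

#: relative tolerance on sampling uniformity accepted at ingestion
UNIFORMITY_RTOL = 0.01


@dataclass
class Trace:
    """A uniformly sampled single-channel bioluminescence time series."""

    time_hr: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_hr = np.asarray(self.time_hr, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time_hr.ndim != 1 or self.time_hr.shape != self.values.shape:
            raise ValueError("time_hr and values must be 1-D arrays of equal length")
        if len(self.time_hr) < 2:
            raise ValueError("a trace needs at least two samples")
        dt = np.diff(self.time_hr)
        if np.any(dt <= 0):
            raise ValueError("time_hr must be strictly increasing")
        step = float(np.median(dt))
        if np.any(np.abs(dt - step) > UNIFORMITY_RTOL * step):
            raise ValueError("sampling must be uniform within 1%")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("trace contains missing values; interpolate at read time")

    @property
    def sampling_interval_hr(self) -> float:
        return float(np.median(np.diff(self.time_hr)))

    @property
    def duration_hr(self) -> float:
        return float(self.time_hr[-1] - self.time_hr[0])

    def copy_with(self, values: np.ndarray, **meta) -> "Trace":
        new_meta = {**self.meta, **meta}
        return Trace(self.time_hr.copy(), np.asarray(values, dtype=float), new_meta)

    def crop(self, t_min: float, t_max: float) -> "Trace":
        sel = (self.time_hr >= t_min) & (self.time_hr <= t_max)
        if sel.sum() < 2:
            raise ValueError("crop window contains fewer than two samples")
        return Trace(self.time_hr[sel], self.values[sel], dict(self.meta))


@dataclass(frozen=True)
class Pulse:
    """A single optogenetic stimulation pulse."""

    onset_hr: float
    duration_hr: float
    label: str = "pulse"  # "dawn" / "dusk" for skeleton photoperiods

    def __post_init__(self) -> None:
        if self.duration_hr <= 0:
            raise ValueError("pulse duration must be positive")


@dataclass
class StimSchedule:
    """Ordered stimulation pulses plus cycle-structure metadata.

    ``structure`` is one of ``single``, ``t_cycle`` (with ``T_hr``) or
    ``skeleton`` (with ``day_interval_hr`` between dawn and dusk pulses and
    ``cycle_hr``, normally 24).
    """

    pulses: list[Pulse]
    structure: Literal["single", "t_cycle", "skeleton"] = "single"
    T_hr: float | None = None
    day_interval_hr: float | None = None
    cycle_hr: float | None = None

    def __post_init__(self) -> None:
        onsets = [p.onset_hr for p in self.pulses]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("pulse onsets must be strictly increasing")
        if self.structure == "t_cycle" and not self.T_hr:
            raise ValueError("t_cycle structure requires T_hr")
        if self.structure == "skeleton":
            if not (self.day_interval_hr and self.cycle_hr):
                raise ValueError("skeleton structure requires day_interval_hr and cycle_hr")
            labels = {p.label for p in self.pulses}
            if not {"dawn", "dusk"} <= labels:
                raise ValueError("skeleton schedules need pulses labelled dawn and dusk")

    @property
    def onsets(self) -> np.ndarray:
        return np.array([p.onset_hr for p in self.pulses])

    def labelled(self, label: str) -> list[Pulse]:
        return [p for p in self.pulses if p.label == label]

    @property
    def span(self) -> tuple[float, float]:
        """Start of the first pulse to end of the last stimulated cycle."""
        first = self.pulses[0].onset_hr
        last = self.pulses[-1].onset_hr + self.pulses[-1].duration_hr
        if self.structure == "t_cycle" and self.T_hr:
            last = self.pulses[-1].onset_hr + self.T_hr
        elif self.structure == "skeleton" and self.cycle_hr:
            last = self.pulses[-1].onset_hr + self.cycle_hr / 2.0
        return first, last


@dataclass
class RhythmFeatures:
    """Extrema and derived per-cycle quantities of a detrended rhythm.

    Peaks and troughs alternate in time.  ``halfmax_rising[i]`` is the first
    time the signal exceeds the midpoint between trough ``i`` and the peak
    that follows it.  ``amplitudes[k]`` is peak ``k`` minus its preceding
    trough; ``damping_per_cycle`` is the fitted geometric amplitude ratio of
    successive cycles (1.0 = undamped).
    """

    peak_times: np.ndarray
    peak_values: np.ndarray
    trough_times: np.ndarray
    trough_values: np.ndarray
    halfmax_rising: np.ndarray
    amplitudes: np.ndarray
    damping_per_cycle: float | None = None
    insufficient_for_period: bool = False

    def __post_init__(self) -> None:
        for name in ("peak_times", "peak_values", "trough_times",
                     "trough_values", "halfmax_rising", "amplitudes"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        merged = np.concatenate([self.peak_times, self.trough_times])
        kinds = np.concatenate([np.ones_like(self.peak_times),
                                np.zeros_like(self.trough_times)])
        order = np.argsort(merged)
        if np.any(np.diff(kinds[order]) == 0):
            raise ValueError("peaks and troughs must alternate in time")

    @property
    def n_peaks(self) -> int:
        return len(self.peak_times)

    def peaks_before(self, t_hr: float) -> np.ndarray:
        return self.peak_times[self.peak_times < t_hr]

    def peaks_after(self, t_hr: float) -> np.ndarray:
        return self.peak_times[self.peak_times > t_hr]


@dataclass
class PhaseShiftResult:
    """Phase shift by regression extrapolation: predicted − observed peak.

    The sign convention follows the field: a positive shift is a phase
    advance (observed peak earlier than predicted), a negative shift a delay.
    """

    predicted_peak_hr: float
    observed_peak_hr: float
    shift_hr: float
    n_pre_peaks: int
    pre_period_hr: float

    def __post_init__(self) -> None:
        if self.n_pre_peaks < 3:
            raise ValueError("phase shift requires >= 3 pre-stimulus peaks")


@dataclass
class WaveformMetrics:
    """Per-cycle rising/falling durations and stimulated-cycle fold changes."""

    rising_hr: np.ndarray          # per-cycle trough->peak duration
    falling_hr: np.ndarray         # per-cycle peak->trough duration
    cycle_peak_times: np.ndarray   # peak anchoring each (rising, falling) pair
    rising_fc: float | None = None
    falling_fc: float | None = None
    normalized_induction: float | None = None


@dataclass
class EntrainmentResult:
    """Phase-angle series and entrainment classification for one schedule."""

    phase_angle_hr: np.ndarray     # per stimulated cycle: pulse onset - rising half-max
    angle_cycle_index: np.ndarray
    angle_slope_hr_per_cycle: float | None
    entrained_period_hr: float | None
    aftereffect_period_change_hr: float | None = None
    classification: Literal["entrained", "phase_jumped", "free_running"] = "free_running"
    jump_cycle_index: int | None = None
    diagnostics: dict = field(default_factory=dict)
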