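"""Ground-truthed synthetic PER2::LUC bioluminescence traces.

The generator represents a reporter rhythm through a monotone phase function
built from extremum knots: extremum *k* of the rhythm is pinned to an exact
clock time and to phase ``k*pi``, and the phase between knots is interpolated
with a monotone cubic (PCHIP), so instantaneous frequency varies smoothly
across extrema instead of kinking at the very points the analysis pipeline
must time.  Programmed effects — step phase shifts, rising/falling segment
warps, period after-effects, entrained cycles of arbitrary rising/falling
durations — are therefore *exact* re-parameterizations of time: the
programmed extremum times, segment durations, and post-stimulus periods are
analytically known and serve as recovery targets.

The signal model is::

    y(t) = mesor + drift*t + A * d**c(t) * cos(pi * phi(t)) + induction + noise

where ``phi`` is the knot-interpolated phase in half-cycle units
(``phi = 0`` at the first peak), ``c = phi/2`` the cycle index driving the
multiplicative per-cycle damping ``d``, and the induction transient is a
purely additive exponential decay starting at pulse onset.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import yaml
from scipy.interpolate import PchipInterpolator

from .core import Pulse, StimSchedule, Trace

__all__ = [
    "GeneratorConfig",
    "WaveformProgram",
    "EntrainedProgram",
    "Experiment",
    "make_trace",
    "apply_program",
    "make_experiment",
    "load_presets",
    "preset_names",
]

_MIN_SEGMENT_HR = 0.5  # a warped half-cycle shorter than this is rejected


@dataclass
class GeneratorConfig:
    """Parameters of the damped free-running reporter rhythm.

    ``damping_per_cycle`` is the peak-to-peak amplitude ratio of successive
    cycles (1.0 = undamped).  ``first_peak_hr`` defaults to half the base
    period so recordings start mid-falling phase, as explant recordings
    typically do.
    """

    base_period_hr: float = 24.0
    amplitude: float = 1.0
    damping_per_cycle: float = 0.95
    mesor: float = 0.0
    drift_slope: float = 0.0
    noise_sd: float = 0.0
    sampling_interval_hr: float = 0.1
    duration_hr: float = 240.0
    first_peak_hr: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sampling_interval_hr <= 0:
            raise ValueError("sampling_interval_hr must be positive")
        if not (0.0 < self.damping_per_cycle <= 1.0):
            raise ValueError("damping_per_cycle must lie in (0, 1]")
        if self.duration_hr < 3.0 * self.base_period_hr:
            raise ValueError(
                "duration_hr must cover at least 3 cycles; phase-shift "
                "estimation requires >= 3 pre-stimulus cycles"
            )

    @property
    def peak1_hr(self) -> float:
        return self.base_period_hr / 2.0 if self.first_peak_hr is None else self.first_peak_hr


@dataclass
class WaveformProgram:
    """Ground-truth effects of a single stimulation pulse.

    Sign conventions match the field: positive ``step_phase_shift_hr`` is a
    phase advance (post-stimulus peaks earlier than the pre-stimulus
    regression prediction), positive ``post_period_delta_hr`` lengthens the
    period of every cycle after the stimulated one.  The warps multiply the
    duration of the stimulated cycle's rising (trough->peak) and falling
    (peak->trough) limbs.  ``induction_amplitude`` scales an additive
    exponential PER2 induction transient as a fraction of the current cycle
    amplitude.  ``post_amplitude_scale`` multiplies the damping envelope after
    the stimulated cycle (used to emulate amplitude collapse after long light
    exposure).
    """

    stim_time_hr: float
    step_phase_shift_hr: float = 0.0
    rising_warp: float = 1.0
    falling_warp: float = 1.0
    post_period_delta_hr: float = 0.0
    induction_amplitude: float = 0.0
    induction_decay_hr: float = 3.0
    post_amplitude_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.rising_warp <= 0 or self.falling_warp <= 0:
            raise ValueError("segment warps must be positive")
        if self.induction_decay_hr <= 0:
            raise ValueError("induction_decay_hr must be positive")

    @property
    def is_neutral(self) -> bool:
        return (
            self.step_phase_shift_hr == 0.0
            and self.rising_warp == 1.0
            and self.falling_warp == 1.0
            and self.post_period_delta_hr == 0.0
            and self.induction_amplitude == 0.0
            and self.post_amplitude_scale == 1.0
        )


@dataclass
class EntrainedProgram:
    """Ground truth for repeated stimulation (T-cycles, skeleton photoperiods).

    Entrainment starts at the trough following free-running peak number
    ``anchor_peak_index`` (0-based).  Each entrained cycle runs trough to
    trough with the given (rising, falling) durations in hours; after the last
    entrained trough the rhythm free-runs at ``base_period + release delta``.
    """

    anchor_peak_index: int
    cycles: list[tuple[float, float]]
    release_period_delta_hr: float = 0.0
    induction_amplitude: float = 0.0
    induction_decay_hr: float = 3.0
    stim_time_hr: float | None = None  # onset of the first pulse, for bookkeeping

    def __post_init__(self) -> None:
        for r, f in self.cycles:
            if r < _MIN_SEGMENT_HR or f < _MIN_SEGMENT_HR:
                raise ValueError("entrained segment durations too short")


# ---------------------------------------------------------------------------
# knot construction


def _neutral_knots(cfg: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    """Extremum times and phases (half-cycle units) covering the recording."""
    half = cfg.base_period_hr / 2.0
    p1 = cfg.peak1_hr
    j_min = int(np.floor((-2.0 * cfg.base_period_hr - p1) / half)) - 1
    j_max = int(np.ceil((cfg.duration_hr + 2.0 * cfg.base_period_hr - p1) / half)) + 1
    j = np.arange(j_min, j_max + 1)
    return p1 + j * half, j.astype(float)


def _pulse_knots(
    cfg: GeneratorConfig, prog: WaveformProgram
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Apply a single-pulse program to the neutral extremum schedule.

    The rising/falling warps act on the first rising/falling segment ending
    after the pulse; the step shift is realized by stretching the segment that
    ends at the first post-stimulus peak, so that peak lands exactly at
    (regression prediction − shift); all later extrema follow at half the
    post-stimulus period.
    """
    times, phases = _neutral_knots(cfg)
    ts = prog.stim_time_hr
    if not (0.0 < ts < cfg.duration_hr):
        raise ValueError("stim_time_hr must fall inside the trace")
    half = cfg.base_period_hr / 2.0
    durations = np.diff(times).copy()

    is_peak = (phases.astype(int) % 2) == 0
    # segment i runs knot i -> knot i+1; rising iff it ends at a peak
    seg_rising = is_peak[1:]

    def first_seg_ending_after(rising: bool) -> int:
        for i in range(len(durations)):
            if seg_rising[i] == rising and times[i + 1] > ts:
                return i
        raise ValueError("pulse too close to the end of the trace")

    i_fall = first_seg_ending_after(False)
    i_rise = first_seg_ending_after(True)
    durations[i_fall] *= prog.falling_warp
    durations[i_rise] *= prog.rising_warp

    # first post-stimulus peak knot in the neutral schedule
    post_peaks = np.where(is_peak & (times > ts))[0]
    if len(post_peaks) == 0:
        raise ValueError("no post-stimulus peak inside the trace")
    jp = int(post_peaks[0])
    durations[jp - 1] -= prog.step_phase_shift_hr

    post_half = (cfg.base_period_hr + prog.post_period_delta_hr) / 2.0
    if post_half < _MIN_SEGMENT_HR:
        raise ValueError("post_period_delta_hr makes the phase function non-monotone")
    durations[jp:] = post_half

    if np.any(durations < _MIN_SEGMENT_HR):
        raise ValueError("program makes the phase function non-monotone")

    new_times = np.empty_like(times)
    new_times[0] = times[0]
    new_times[1:] = times[0] + np.cumsum(durations)
    extras = {"first_post_peak_knot": jp, "amp_scale_seg": jp - 2}
    return new_times, phases, extras


def _entrained_knots(
    cfg: GeneratorConfig, prog: EntrainedProgram
) -> tuple[np.ndarray, np.ndarray, dict]:
    half = cfg.base_period_hr / 2.0
    p1 = cfg.peak1_hr
    anchor = p1 + prog.anchor_peak_index * cfg.base_period_hr + half
    # free-running extrema strictly before the anchor trough, plus lead-in
    j_min = int(np.floor((-2.0 * cfg.base_period_hr - p1) / half)) - 1
    j_anchor = 2 * prog.anchor_peak_index + 1
    j = np.arange(j_min, j_anchor + 1)
    times = list(p1 + j * half)
    t = anchor
    for rising, falling in prog.cycles:
        times.append(t + rising)
        t += rising + falling
        times.append(t)
    release_half = (cfg.base_period_hr + prog.release_period_delta_hr) / 2.0
    if release_half < _MIN_SEGMENT_HR:
        raise ValueError("release period delta makes the phase function non-monotone")
    while t < cfg.duration_hr + 2.0 * cfg.base_period_hr:
        t += release_half
        times.append(t)
    times = np.asarray(times)
    phases = np.arange(j_min, j_min + len(times)).astype(float)
    if np.any(np.diff(times) < _MIN_SEGMENT_HR):
        raise ValueError("entrained program makes the phase function non-monotone")
    return times, phases, {}


# ---------------------------------------------------------------------------
# evaluation


def _phase_interpolator(times: np.ndarray, phases: np.ndarray) -> PchipInterpolator:
    return PchipInterpolator(times, phases, extrapolate=True)


def evaluate_signal(
    cfg: GeneratorConfig,
    t: np.ndarray,
    program: WaveformProgram | EntrainedProgram | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Evaluate the programmed rhythm on an arbitrary time grid."""
    extras: dict = {}
    if program is None:
        times, phases = _neutral_knots(cfg)
    elif isinstance(program, WaveformProgram):
        if program.is_neutral:
            times, phases = _neutral_knots(cfg)
        else:
            times, phases, extras = _pulse_knots(cfg, program)
    elif isinstance(program, EntrainedProgram):
        times, phases, extras = _entrained_knots(cfg, program)
    else:  # pragma: no cover - defensive
        raise TypeError(f"unsupported program type {type(program)!r}")

    phi = _phase_interpolator(times, phases)(t)
    cycle = phi / 2.0  # cycle index relative to the first peak
    envelope = cfg.amplitude * cfg.damping_per_cycle ** cycle

    if (
        isinstance(program, WaveformProgram)
        and program.post_amplitude_scale != 1.0
    ):
        # fade the scale in over the middle half of the falling segment that
        # precedes the first post-stimulus cycle, so both the last
        # pre-stimulus and the first post-stimulus cycle amplitudes are pure
        seg = extras["amp_scale_seg"]
        a = phases[seg] + 0.25
        b = phases[seg + 1] - 0.25
        w = np.clip((phi - a) / (b - a), 0.0, 1.0)
        envelope = envelope * program.post_amplitude_scale ** w

    y = cfg.mesor + cfg.drift_slope * t + envelope * np.cos(np.pi * phi)

    if program is not None and getattr(program, "induction_amplitude", 0.0):
        ts = program.stim_time_hr
        if ts is None:
            raise ValueError("induction requires a stim_time_hr")
        amp_at_stim = cfg.amplitude * cfg.damping_per_cycle ** (float(phi_at(cfg, program, ts)) / 2.0)
        mask = t >= ts
        y = y + np.where(
            mask,
            program.induction_amplitude
            * amp_at_stim
            * np.exp(-(t - ts) / program.induction_decay_hr),
            0.0,
        )

    if cfg.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        y = y + rng.normal(0.0, cfg.noise_sd, size=t.shape)
    return y


def phi_at(cfg: GeneratorConfig, program, t) -> np.ndarray:
    """Phase (half-cycle units) of the programmed rhythm at time(s) ``t``."""
    if program is None or (isinstance(program, WaveformProgram) and program.is_neutral):
        times, phases = _neutral_knots(cfg)
    elif isinstance(program, WaveformProgram):
        times, phases, _ = _pulse_knots(cfg, program)
    else:
        times, phases, _ = _entrained_knots(cfg, program)
    return _phase_interpolator(times, phases)(t)


def programmed_extrema(
    cfg: GeneratorConfig, program=None
) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth (peak_times, trough_times) inside the recording window."""
    if program is None or (isinstance(program, WaveformProgram) and program.is_neutral):
        times, phases = _neutral_knots(cfg)
    elif isinstance(program, WaveformProgram):
        times, phases, _ = _pulse_knots(cfg, program)
    else:
        times, phases, _ = _entrained_knots(cfg, program)
    inside = (times >= 0.0) & (times <= cfg.duration_hr)
    is_peak = (phases.astype(int) % 2) == 0
    return times[inside & is_peak], times[inside & ~is_peak]


def make_trace(
    cfg: GeneratorConfig,
    program: WaveformProgram | EntrainedProgram | None = None,
) -> Trace:
    """Generate a trace; with ``noise_sd=0`` the output is exactly reproducible."""
    n = int(round(cfg.duration_hr / cfg.sampling_interval_hr)) + 1
    t = np.arange(n) * cfg.sampling_interval_hr
    y = evaluate_signal(cfg, t, program)
    return Trace(t, y, meta={"units": "counts", "synthetic": True})


def apply_program(cfg: GeneratorConfig, program: WaveformProgram) -> Trace:
    """Generate the stimulated counterpart of ``make_trace(cfg)``.

    The neutral program returns a trace identical to the unstimulated one.
    """
    return make_trace(cfg, program)


# ---------------------------------------------------------------------------
# presets


@dataclass
class Experiment:
    """A simulated recording with its unstimulated reference and ground truth."""

    name: str
    stimulated: Trace
    reference: Trace
    schedule: StimSchedule
    truth: WaveformProgram | EntrainedProgram
    config: GeneratorConfig


def load_presets() -> dict:
    with importlib.resources.files("perwave").joinpath("presets.yaml").open() as fh:
        return yaml.safe_load(fh)


def preset_names() -> list[str]:
    return sorted(load_presets().keys())


_CONFIG_FIELDS = set(GeneratorConfig.__dataclass_fields__)
_PULSE_FIELDS = set(WaveformProgram.__dataclass_fields__)
_ENTRAIN_FIELDS = set(EntrainedProgram.__dataclass_fields__)


def _build_schedule(entry: dict) -> StimSchedule:
    pulses = [Pulse(**p) for p in entry["pulses"]]
    kwargs = {k: v for k, v in entry.items() if k != "pulses"}
    return StimSchedule(pulses=pulses, **kwargs)


def make_experiment(preset_name: str, **overrides) -> Experiment:
    """Instantiate a named preset, optionally overriding config/program fields.

    Overrides are routed by field name to the generator config (e.g.
    ``noise_sd``, ``seed``) or to the program (e.g. ``step_phase_shift_hr``).
    """
    presets = load_presets()
    # colons are awkward in file names; accept both SK-16:8 and SK-16-8
    preset_name = preset_name.replace(":", "-")
    if preset_name not in presets:
        raise KeyError(
            f"unknown preset {preset_name!r}; available: {', '.join(sorted(presets))}"
        )
    entry = presets[preset_name]
    cfg_kwargs = dict(entry.get("config", {}))
    prog_kwargs = dict(entry.get("program", {}))
    prog_kind = prog_kwargs.pop("kind", "pulse")
    if prog_kind == "entrained":
        prog_kwargs["cycles"] = [tuple(c) for c in prog_kwargs["cycles"]]

    for key, value in overrides.items():
        if key in _CONFIG_FIELDS:
            cfg_kwargs[key] = value
        elif prog_kind == "pulse" and key in _PULSE_FIELDS:
            prog_kwargs[key] = value
        elif prog_kind == "entrained" and key in _ENTRAIN_FIELDS:
            prog_kwargs[key] = value
        else:
            raise TypeError(f"unknown override {key!r} for preset {preset_name}")

    cfg = GeneratorConfig(**cfg_kwargs)
    if prog_kind == "pulse":
        truth: WaveformProgram | EntrainedProgram = WaveformProgram(**prog_kwargs)
    else:
        truth = EntrainedProgram(**prog_kwargs)
    schedule = _build_schedule(entry["schedule"])
    stimulated = make_trace(cfg, truth)
    reference = make_trace(cfg, None)
    return Experiment(preset_name, stimulated, reference, schedule, truth, cfg)
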