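"""Synthetic bioluminescence image stacks with planted regional structure.

Emulates time-lapse imaging of an SCN explant: a contiguous foreground of
rhythmic pixels split into labelled regions, each carrying its own baseline
phase offset and its own programmed stimulation response (phase shift,
period change), over a dark background.  Pixel noise and sparse single-frame
bright-pixel artifacts (cosmic-ray-like spikes) can be added on top.  Truth
maps record the programmed per-pixel quantities for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .synth import GeneratorConfig, WaveformProgram, evaluate_signal

__all__ = [
    "SpatialConfig",
    "SpatialSlice",
    "make_spatial_stack",
    "make_spatial_experiment",
    "spatial_preset_truth",
]


@dataclass
class SpatialConfig:
    """Layout and programs of one synthetic imaging slice."""

    region_map: np.ndarray                      # 0 = background, 1..k = regions
    base: GeneratorConfig
    region_phase_offsets_hr: dict[int, float]
    region_programs: dict[int, WaveformProgram | None]
    frame_interval_hr: float = 1.0 / 6.0
    n_frames: int = 1080
    pixel_noise_sd: float = 0.0
    spike_rate: float = 0.0                     # per pixel-frame probability
    spike_amplitude: float = 5.0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.region_map = np.asarray(self.region_map, dtype=int)
        labels = set(np.unique(self.region_map)) - {0}
        if not labels:
            raise ValueError("region map has no foreground pixels")
        missing = labels - set(self.region_phase_offsets_hr)
        if missing:
            raise ValueError(f"no phase offset for regions {sorted(missing)}")


@dataclass
class SpatialSlice:
    """A generated stack plus its ground truth."""

    stack: np.ndarray          # (n_frames, height, width)
    time_hr: np.ndarray
    region_map: np.ndarray
    truth_shift_map: np.ndarray
    truth_period_change_map: np.ndarray
    truth_phase_offset_map: np.ndarray
    config: SpatialConfig
    stim_time_hr: float | None = None


def make_spatial_stack(config: SpatialConfig) -> SpatialSlice:
    t = np.arange(config.n_frames) * config.frame_interval_hr
    h, w = config.region_map.shape
    stack = np.zeros((config.n_frames, h, w))
    shift_map = np.full((h, w), np.nan)
    pc_map = np.full((h, w), np.nan)
    off_map = np.full((h, w), np.nan)
    stim_time = None

    duration = float(t[-1])
    for label in sorted(set(np.unique(config.region_map)) - {0}):
        offset = config.region_phase_offsets_hr[label]
        program = config.region_programs.get(label)
        cfg = replace(
            config.base,
            first_peak_hr=config.base.peak1_hr + offset,
            duration_hr=duration,
            sampling_interval_hr=config.frame_interval_hr,
            noise_sd=0.0,
        )
        values = evaluate_signal(cfg, t, program)
        mask = config.region_map == label
        stack[:, mask] = values[:, None]
        off_map[mask] = offset
        if program is not None:
            shift_map[mask] = program.step_phase_shift_hr
            pc_map[mask] = program.post_period_delta_hr
            stim_time = program.stim_time_hr
        else:
            shift_map[mask] = 0.0
            pc_map[mask] = 0.0

    rng = np.random.default_rng(config.seed)
    if config.pixel_noise_sd > 0:
        stack = stack + rng.normal(0.0, config.pixel_noise_sd, size=stack.shape)
    if config.spike_rate > 0:
        spikes = rng.random(stack.shape) < config.spike_rate
        stack = stack + spikes * config.spike_amplitude

    return SpatialSlice(
        stack=stack,
        time_hr=t,
        region_map=config.region_map.copy(),
        truth_shift_map=shift_map,
        truth_period_change_map=pc_map,
        truth_phase_offset_map=off_map,
        config=config,
        stim_time_hr=stim_time,
    )


# ---------------------------------------------------------------------------
# the SPATIAL-CT14 preset

#: programmed regional responses to a CT14 pulse: (shift, period delta,
#: baseline phase offset) for lateral shell, lateral core, medial.
_SPATIAL_CT14_REGIONS = {
    1: {"name": "lateral_shell", "shift": -1.33, "period_delta": 0.36, "offset": 0.75},
    2: {"name": "lateral_core", "shift": -1.64, "period_delta": 0.08, "offset": 0.0},
    3: {"name": "medial", "shift": -0.64, "period_delta": 0.31, "offset": -0.75},
}

#: deterministic slice-to-slice variability of the lateral-shell shift
#: (mean exactly 0): inter-slice spread is what lets the group-average
#: clustering stage resolve three regions, as in real explants.
_SHELL_SLICE_ADJ = (0.28, -0.28, 0.28, -0.28, 0.0)

_STIM_HR = 86.0  # CT14 on the 4th recorded cycle (peak 84 + 2 h)


def _ct14_region_map(
    frame_px: int = 96, margin_px: int = 3, roi_px: int = 15
) -> np.ndarray:
    """Three contiguous vertical bands aligned to the ROI lattice."""
    fg = frame_px - 2 * margin_px
    if fg % (3 * roi_px) != 0:
        raise ValueError("foreground width must tile into 3 bands of ROIs")
    band = fg // 3
    m = np.zeros((frame_px, frame_px), dtype=int)
    for i in range(3):
        m[margin_px : margin_px + fg,
          margin_px + i * band : margin_px + (i + 1) * band] = i + 1
    return m


def make_spatial_experiment(
    preset_name: str = "SPATIAL-CT14",
    n_slices: int = 5,
    pixel_noise_sd: float = 0.0,
    spike_rate: float = 0.0,
    seed: int | None = None,
) -> list[SpatialSlice]:
    """Generate the planted-region imaging cohort for a spatial preset."""
    if preset_name != "SPATIAL-CT14":
        raise KeyError(f"unknown spatial preset {preset_name!r}")
    if n_slices > len(_SHELL_SLICE_ADJ):
        raise ValueError(f"preset defines at most {len(_SHELL_SLICE_ADJ)} slices")
    region_map = _ct14_region_map()
    base = GeneratorConfig(
        base_period_hr=24.0,
        amplitude=1.0,
        damping_per_cycle=0.95,
        mesor=1.5,
        duration_hr=240.0,  # replaced per-slice by the stack duration
    )
    slices = []
    ss = np.random.SeedSequence(seed).spawn(n_slices) if seed is not None else [None] * n_slices
    for s in range(n_slices):
        programs = {}
        offsets = {}
        for label, region in _SPATIAL_CT14_REGIONS.items():
            shift = region["shift"]
            if label == 1:
                shift = shift + _SHELL_SLICE_ADJ[s]
            programs[label] = WaveformProgram(
                stim_time_hr=_STIM_HR,
                step_phase_shift_hr=shift,
                post_period_delta_hr=region["period_delta"],
            )
            offsets[label] = region["offset"]
        cfg = SpatialConfig(
            region_map=region_map,
            base=base,
            region_phase_offsets_hr=offsets,
            region_programs=programs,
            pixel_noise_sd=pixel_noise_sd,
            spike_rate=spike_rate,
            seed=None if ss[s] is None else int(ss[s].generate_state(1)[0] % (2**31)),
        )
        slices.append(make_spatial_stack(cfg))
    return slices


def spatial_preset_truth(preset_name: str = "SPATIAL-CT14") -> dict:
    """Programmed regional means of the spatial preset (cohort averages)."""
    if preset_name != "SPATIAL-CT14":
        raise KeyError(f"unknown spatial preset {preset_name!r}")
    return {
        region["name"]: {
            "shift_hr": region["shift"],
            "period_delta_hr": region["period_delta"],
            "phase_offset_hr": region["offset"],
        }
        for region in _SPATIAL_CT14_REGIONS.values()
    }
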