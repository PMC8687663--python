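"""Readers and writers for traces (CSV), schedules (JSON) and stacks (TIFF)."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import Pulse, StimSchedule, Trace

__all__ = [
    "read_trace",
    "write_trace",
    "read_schedule",
    "write_schedule",
    "read_stack",
    "write_stack",
]

log = logging.getLogger("perwave")

MAX_GAP_SAMPLES = 3


def read_trace(path, channel: str | None = None) -> Trace:
    """Read a trace CSV (header ``time_hr,value[,channel]``).

    Time must be strictly increasing and uniform within 1%.  Runs of up to
    three missing values are linearly interpolated with a logged warning;
    longer gaps are an error.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if "time_hr" not in df.columns or "value" not in df.columns:
        raise ValueError("trace CSV needs 'time_hr' and 'value' columns")
    if channel is not None:
        if "channel" not in df.columns:
            raise ValueError("no 'channel' column in trace CSV")
        df = df[df["channel"] == channel]
    t = df["time_hr"].to_numpy(dtype=float)
    v = df["value"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time_hr must be strictly increasing")
    missing = ~np.isfinite(v)
    if missing.any():
        # reject runs longer than MAX_GAP_SAMPLES
        run = 0
        for m in missing:
            run = run + 1 if m else 0
            if run > MAX_GAP_SAMPLES:
                raise ValueError(
                    f"gap longer than {MAX_GAP_SAMPLES} samples; refusing to interpolate"
                )
        v = np.interp(t, t[~missing], v[~missing])
        log.warning("interpolated %d missing sample(s) in %s", missing.sum(), path)
    return Trace(t, v, meta={"source": str(path)})


def write_trace(trace: Trace, path) -> None:
    pd.DataFrame({"time_hr": trace.time_hr, "value": trace.values}).to_csv(
        path, index=False
    )


def write_schedule(schedule: StimSchedule, path) -> None:
    payload = {
        "pulses": [
            {"onset_hr": p.onset_hr, "duration_hr": p.duration_hr, "label": p.label}
            for p in schedule.pulses
        ],
        "structure": {
            "kind": schedule.structure,
            "T_hr": schedule.T_hr,
            "day_interval_hr": schedule.day_interval_hr,
            "cycle_hr": schedule.cycle_hr,
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_schedule(path) -> StimSchedule:
    payload = json.loads(Path(path).read_text())
    pulses = [Pulse(**p) for p in payload["pulses"]]
    structure = payload.get("structure", {})
    return StimSchedule(
        pulses=pulses,
        structure=structure.get("kind", "single"),
        T_hr=structure.get("T_hr"),
        day_interval_hr=structure.get("day_interval_hr"),
        cycle_hr=structure.get("cycle_hr"),
    )


def write_stack(stack: np.ndarray, path, frame_interval_hr: float) -> None:
    tifffile.imwrite(
        path,
        np.asarray(stack, dtype=np.float32),
        metadata={"frame_interval_hr": frame_interval_hr},
    )


def read_stack(path, frame_interval_hr: float | None = None):
    """Read a multi-frame TIFF; returns (stack, time_hr)."""
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray().astype(float)
        if frame_interval_hr is None:
            meta = tif.shaped_metadata or ({},)
            frame_interval_hr = meta[0].get("frame_interval_hr")
    if frame_interval_hr is None:
        raise ValueError("frame_interval_hr not in metadata; pass it explicitly")
    t = np.arange(stack.shape[0]) * float(frame_interval_hr)
    return stack, t
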