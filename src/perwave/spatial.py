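"""Spatial analysis of bioluminescence image stacks.

Pipeline: grouped minimum-intensity denoising (group size two) to strip
single-frame bright-pixel artifacts, 15 x 15-pixel ROI tiling over the
foreground of the average-intensity projection, per-ROI rhythm metrics
(peak phases relative to the grid mean, three-peak period, phase shift and
period change via the single-pulse estimators), circular statistics of peak
phases, and the two-stage Ward clustering used to delineate functional SCN
subregions: per-slice 2-clustering of a scalar response map, group-averaging
of the binary memberships across slices, re-clustering of the average into
three regions, and re-extraction of per-cluster means from the raw maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import AgglomerativeClustering

from .core import Trace
from .preprocess import detrend_running_mean, find_features, smooth_moving_average
from .resetting import phase_shift, _marker_regression_period

__all__ = [
    "ROIGrid",
    "ResponseMaps",
    "ClusterResult",
    "denoise_stack",
    "extract_roi_traces",
    "response_maps",
    "circular_stats",
    "cluster_responses",
    "cluster_phase_difference",
]

DEFAULT_ROI_PX = 15


def denoise_stack(
    stack: np.ndarray, time_hr: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Grouped Z-projection with group size two, minimum-intensity method.

    Output frame k is the pixelwise minimum of input frames 2k and 2k+1;
    time stamps become group midpoints.  A trailing odd frame is dropped.
    Never increases any pixel value, and removes any artifact confined to a
    single frame of a pair.
    """
    if stack.shape[0] < 2:
        raise ValueError("grouped denoising needs at least two frames")
    n = stack.shape[0] // 2
    out = np.minimum(stack[0 : 2 * n : 2], stack[1 : 2 * n : 2])
    t = 0.5 * (time_hr[0 : 2 * n : 2] + time_hr[1 : 2 * n : 2])
    return out, t


@dataclass
class ROIGrid:
    """Square ROI tiling of a stack's foreground with mean-intensity traces."""

    origins: np.ndarray        # (n_roi, 2) top-left pixel of each ROI
    grid_index: np.ndarray     # (n_roi, 2) (row, col) on the ROI lattice
    grid_shape: tuple[int, int]
    traces: np.ndarray         # (n_roi, n_frames) mean intensity per frame
    time_hr: np.ndarray
    roi_size_px: int
    mean_projection: np.ndarray

    @property
    def n_roi(self) -> int:
        return len(self.origins)

    def to_map(self, values: np.ndarray) -> np.ndarray:
        """Scatter per-ROI values onto the (grid_shape) lattice (NaN elsewhere)."""
        out = np.full(self.grid_shape, np.nan)
        out[self.grid_index[:, 0], self.grid_index[:, 1]] = values
        return out


def extract_roi_traces(
    stack: np.ndarray,
    time_hr: np.ndarray,
    roi_size_px: int = DEFAULT_ROI_PX,
    smooth_window_hr: float = 2.4,
) -> ROIGrid:
    """Tile the foreground with ROIs and extract smoothed mean traces.

    The foreground is thresholded at half the median of the average-intensity
    projection over nonzero pixels; ROIs tile from the top-left of the
    foreground bounding box, and a tile is retained when its mean projection
    intensity clears the threshold.
    """
    proj = stack.mean(axis=0)
    nz = proj[proj > 0]
    if nz.size == 0:
        raise ValueError("stack has no foreground (all-zero projection)")
    threshold = 0.5 * float(np.median(nz))
    mask = proj >= threshold
    if not mask.any():
        raise ValueError("no pixels above the foreground threshold")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, c0 = rows[0], cols[0]
    n_rows = (rows[-1] - r0 + 1) // roi_size_px
    n_cols = (cols[-1] - c0 + 1) // roi_size_px

    origins, grid_index, traces = [], [], []
    for i in range(n_rows):
        for j in range(n_cols):
            rs = r0 + i * roi_size_px
            cs = c0 + j * roi_size_px
            block = stack[:, rs : rs + roi_size_px, cs : cs + roi_size_px]
            if proj[rs : rs + roi_size_px, cs : cs + roi_size_px].mean() < threshold:
                continue
            origins.append((rs, cs))
            grid_index.append((i, j))
            traces.append(block.mean(axis=(1, 2)))
    if not traces:
        raise ValueError("no ROI passed the foreground threshold")
    traces = np.array(traces)
    smoothed = np.array(
        [
            smooth_moving_average(Trace(time_hr, tr), smooth_window_hr).values
            for tr in traces
        ]
    )
    return ROIGrid(
        origins=np.array(origins),
        grid_index=np.array(grid_index),
        grid_shape=(n_rows, n_cols),
        traces=smoothed,
        time_hr=time_hr.copy(),
        roi_size_px=roi_size_px,
        mean_projection=proj,
    )


@dataclass
class ResponseMaps:
    """Per-ROI rhythm metrics on the ROI lattice (NaN = undetectable ROI)."""

    phase_pre: np.ndarray        # last pre-stim peak time relative to grid mean
    phase_post: np.ndarray       # first post-stim peak time relative to grid mean
    period: np.ndarray           # three-peak regression period, hours
    shift: np.ndarray            # signed phase shift, hours (advance positive)
    period_change: np.ndarray    # signed hours (lengthening positive)
    peak_pre_abs: np.ndarray     # absolute last pre-stim peak times
    peak_post_abs: np.ndarray
    grid: ROIGrid = field(repr=False)
    n_failed: int = 0


def response_maps(grid: ROIGrid, stim_time_hr: float) -> ResponseMaps:
    """Compute phase/period/shift/period-change maps from ROI traces.

    Phase maps are peak times normalized to the grid mean (map mean = 0);
    the period map uses a regression of the three pre-stimulus cycle peaks;
    shifts and period changes reuse the single-pulse estimators per ROI.
    """
    n = grid.n_roi
    pre_peak = np.full(n, np.nan)
    post_peak = np.full(n, np.nan)
    period = np.full(n, np.nan)
    shift = np.full(n, np.nan)
    pchange = np.full(n, np.nan)
    failed = 0
    for k in range(n):
        trace = Trace(grid.time_hr, grid.traces[k])
        try:
            proc = smooth_moving_average(detrend_running_mean(trace))
            feats = find_features(proc, stim_time_hr=stim_time_hr)
            res = phase_shift(feats, stim_time_hr)
            pre = feats.peaks_before(stim_time_hr)
            pre_peak[k] = pre[-1]
            post_peak[k] = res.observed_peak_hr
            shift[k] = res.shift_hr
            period[k] = _marker_regression_period(pre[-3:])
            post = feats.peaks_after(res.observed_peak_hr - 0.1)
            if len(post) >= 3:
                pchange[k] = _marker_regression_period(post[:3]) - period[k]
        except (ValueError, TypeError):
            failed += 1
    return ResponseMaps(
        phase_pre=grid.to_map(pre_peak - np.nanmean(pre_peak)),
        phase_post=grid.to_map(post_peak - np.nanmean(post_peak)),
        period=grid.to_map(period),
        shift=grid.to_map(shift),
        period_change=grid.to_map(pchange),
        peak_pre_abs=grid.to_map(pre_peak),
        peak_post_abs=grid.to_map(post_peak),
        grid=grid,
        n_failed=failed,
    )


def circular_stats(peak_times, period_hr: float = 24.0) -> dict:
    """Rayleigh statistics of peak phases on a ``period_hr`` circle.

    circular variance = 1 − mean resultant vector length; 0 = perfect
    synchrony, 1 = complete dispersion.
    """
    t = np.asarray(peak_times, dtype=float)
    t = t[np.isfinite(t)]
    if len(t) < 2:
        raise ValueError("circular statistics need >= 2 phases")
    theta = 2.0 * np.pi * np.mod(t, period_hr) / period_hr
    z = np.exp(1j * theta).mean()
    r = float(np.abs(z))
    return {
        "mean_vector_length": r,
        "mean_angle_rad": float(np.angle(z) % (2.0 * np.pi)),
        "circular_variance": 1.0 - r,
    }


@dataclass
class ClusterResult:
    """Output of the two-stage Ward clustering of response maps."""

    per_slice_labels: list[np.ndarray]   # binary membership maps (1 = larger values)
    averaged_membership: np.ndarray
    group_labels: np.ndarray             # 0..k-1 on the common lattice, NaN-safe (-1)
    cluster_means: np.ndarray            # (k,) mean of raw values per cluster
    cluster_sems: np.ndarray
    per_slice_cluster_means: np.ndarray  # (n_slices, k)


def _ward_1d(values: np.ndarray, n_clusters: int) -> np.ndarray:
    """Ward's minimum-variance clustering of scalar values."""
    if len(np.unique(values)) < n_clusters:
        raise ValueError("fewer distinct values than requested clusters")
    model = AgglomerativeClustering(n_clusters=n_clusters, linkage="ward")
    return model.fit_predict(values.reshape(-1, 1))


def _resample_to(map_2d: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resample of an ROI-lattice map onto a common grid.

    Registration across slices uses the lattice bounding box: each slice's
    grid is affinely scaled onto the reference shape.
    """
    if map_2d.shape == tuple(shape):
        return map_2d
    ri = np.clip((np.arange(shape[0]) + 0.5) * map_2d.shape[0] / shape[0], 0, map_2d.shape[0] - 1).astype(int)
    ci = np.clip((np.arange(shape[1]) + 0.5) * map_2d.shape[1] / shape[1], 0, map_2d.shape[1] - 1).astype(int)
    return map_2d[np.ix_(ri, ci)]


def cluster_responses(
    maps_across_slices: list[np.ndarray], n_group_clusters: int = 3
) -> ClusterResult:
    """Two-stage Ward clustering of one response dimension across slices.

    Stage 1: each slice's map is Ward 2-clustered on raw values, separating
    larger-value from smaller-value ROIs (membership 1 = larger).  Stage 2:
    binary memberships are averaged across slices on a common lattice.
    Stage 3: the averaged membership is Ward-clustered into
    ``n_group_clusters`` regions.  Stage 4: per-cluster means are recomputed
    from each slice's raw map restricted to the cluster, then averaged.
    """
    if not maps_across_slices:
        raise ValueError("need at least one slice")
    ref_shape = maps_across_slices[0].shape
    memberships, registered_raw = [], []
    for m in maps_across_slices:
        m = _resample_to(np.asarray(m, dtype=float), ref_shape)
        registered_raw.append(m)
        valid = np.isfinite(m)
        vals = m[valid]
        if np.ptp(vals) == 0:
            warnings.warn("all map values equal; single cluster assumed")
            lab = np.zeros(len(vals), dtype=int)
        else:
            lab = _ward_1d(vals, 2)
            if vals[lab == 0].mean() > vals[lab == 1].mean():
                lab = 1 - lab
        mem = np.full(ref_shape, np.nan)
        mem[valid] = lab
        memberships.append(mem)

    averaged = np.nanmean(np.stack(memberships), axis=0)
    common = np.all(np.isfinite(np.stack(memberships)), axis=0)
    vals = averaged[common]
    n_distinct = len(np.unique(vals))
    if n_distinct < n_group_clusters:
        warnings.warn(
            f"only {n_distinct} distinct membership value(s); "
            f"reducing to {n_distinct} cluster(s)"
        )
        n_group_clusters = n_distinct
    if n_group_clusters == 1:
        labels_flat = np.zeros(len(vals), dtype=int)
    else:
        labels_flat = _ward_1d(vals, n_group_clusters)
    group_labels = np.full(ref_shape, -1, dtype=int)
    group_labels[common] = labels_flat

    # order cluster ids by averaged-membership mean for reproducibility
    order = np.argsort(
        [vals[labels_flat == c].mean() for c in range(n_group_clusters)]
    )
    remap = np.empty(n_group_clusters, dtype=int)
    remap[order] = np.arange(n_group_clusters)
    group_labels[common] = remap[labels_flat]

    per_slice_means = np.full((len(registered_raw), n_group_clusters), np.nan)
    for s, raw in enumerate(registered_raw):
        for c in range(n_group_clusters):
            sel = (group_labels == c) & np.isfinite(raw)
            if sel.any():
                per_slice_means[s, c] = raw[sel].mean()
    cluster_means = np.nanmean(per_slice_means, axis=0)
    n_eff = np.sum(np.isfinite(per_slice_means), axis=0)
    cluster_sems = np.nanstd(per_slice_means, axis=0, ddof=1) / np.sqrt(
        np.maximum(n_eff, 1)
    )
    return ClusterResult(
        per_slice_labels=memberships,
        averaged_membership=averaged,
        group_labels=group_labels,
        cluster_means=cluster_means,
        cluster_sems=cluster_sems,
        per_slice_cluster_means=per_slice_means,
    )


def cluster_phase_difference(
    pre_phase_map: np.ndarray,
    post_phase_map: np.ndarray,
    cluster_labels: np.ndarray,
) -> dict:
    """Peak-time gap between the phase-leading and phase-lagging clusters.

    Clusters are identified from the pre-stimulus phase map: leading = the
    cluster with the earliest mean peak time.  Returns the gap before and
    after stimulation (positive = lagging later than leading).
    """
    labels = np.unique(cluster_labels[cluster_labels >= 0])
    if len(labels) < 2:
        raise ValueError("need at least two clusters")
    pre_means = {
        c: np.nanmean(pre_phase_map[cluster_labels == c]) for c in labels
    }
    leading = min(pre_means, key=pre_means.get)
    lagging = max(pre_means, key=pre_means.get)
    pre = pre_means[lagging] - pre_means[leading]
    post = np.nanmean(post_phase_map[cluster_labels == lagging]) - np.nanmean(
        post_phase_map[cluster_labels == leading]
    )
    return {
        "pre_hr": float(pre),
        "post_hr": float(post),
        "leading_cluster": int(leading),
        "lagging_cluster": int(lagging),
    }
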