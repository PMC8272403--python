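"""Per-frame fish centerline extraction and the signed tail angle.

Each frame is reduced to a 20-point body centerline (morphological skeleton,
pruned to its longest geodesic path, smoothed with a spline and resampled at
equal arc length) and then to a single signed angle: the direction of the
total-least-squares line through the last five centerline points, measured
against the restrained head axis.  This distal-chord angle relative to the
rest position is the core kinematic signal from which escape events are
detected.

Per-frame failures (blank frame, fragmented mask, ring-shaped skeleton) are
flagged, never raised: a trial keeps its full time base and short gaps are
filled by linear interpolation so latency measurements stay on the frame grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import splev, splprep
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import skeletonize

from startletrack.acquisition_io import FrameStack, decode_timestamps, extract_stimuli
from startletrack.errors import DegeneratePathError, ParameterError

logger = logging.getLogger(__name__)

QUALITY_TRACKED = "tracked"
QUALITY_FALLBACK = "fallback"
QUALITY_FAILED = "failed"


@dataclass(frozen=True)
class HeadAnchor:
    """Pixel position of the restrained head end and its axis direction (x, y)."""

    xy: tuple[float, float]
    axis: tuple[float, float] = (1.0, 0.0)


@dataclass
class TrackingConfig:
    """Parameters of the centerline/tail-angle computation.

    ``n_points`` and ``n_tail_points`` default to the 20-point body
    segmentation with the distal five points carrying the angle.  When
    ``head_anchor`` is None it is estimated from the first frame (the head is
    the thick end of the silhouette).
    """

    n_points: int = 20
    n_tail_points: int = 5
    head_anchor: HeadAnchor | None = None
    intensity_threshold_method: str = "otsu"  # "otsu" | "fixed"
    fixed_threshold: float = 100.0
    min_fish_area_px: int = 120
    reserved_rows: int = 8  # metadata band masked out before segmentation
    spline_smooth_per_point: float = 0.1
    subpixel_refine: bool = True  # snap centerline points to local intensity centroids
    median_filter: bool = False  # optional 3-frame median of the angle trace
    baseline_window_ms: float = 50.0
    max_gap_frames: int = 3

    def __post_init__(self) -> None:
        if not (2 <= self.n_tail_points < self.n_points):
            raise ParameterError("need 2 <= n_tail_points < n_points")
        if self.intensity_threshold_method not in ("otsu", "fixed"):
            raise ParameterError("intensity_threshold_method must be 'otsu' or 'fixed'")


@dataclass
class Centerline:
    """Equal-arc-length body centerline; index 0 is the head end."""

    points: np.ndarray  # (n_points, 2) as (x, y)
    arc_length: np.ndarray  # cumulative arc length per point (px)


@dataclass
class TailAngleTrace:
    """Per-frame signed tail angle (degrees) relative to the rest position."""

    times_ms: np.ndarray
    angles_deg: np.ndarray  # rest-relative; NaN where tracking failed unrecoverably
    rest_angle_deg: float
    quality: list[str]
    fps: float
    low_quality: bool = False
    stimulus_times_ms: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self.angles_deg)),
                "time_ms": self.times_ms,
                "angle_deg": self.angles_deg,
                "quality": self.quality,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def segment_fish(frame: np.ndarray, config: TrackingConfig) -> np.ndarray | None:
    """Largest bright connected component; None when the frame fails.

    The metadata band (timestamp row + TTL block) is masked out before
    thresholding so saturated marker pixels cannot contaminate the silhouette.
    """
    img = np.asarray(frame, dtype=np.float64).copy()
    img[: config.reserved_rows] = 0.0
    if config.intensity_threshold_method == "fixed":
        thr = config.fixed_threshold
    else:
        vals = img[config.reserved_rows :]
        if vals.max() <= vals.min():
            return None
        thr = threshold_otsu(vals)
    fg = img > thr
    if not fg.any():
        return None
    labels, n = cc_label(fg, return_num=True, connectivity=2)
    if n == 0:
        return None
    sizes = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < config.min_fish_area_px:
        return None
    return labels == best


# ---------------------------------------------------------------------------
# centerline
# ---------------------------------------------------------------------------

_NEIGHBOR_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    rows, cols = np.nonzero(skel)
    nodes = set(zip(rows.tolist(), cols.tolist()))
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for r, c in nodes:
        for dr, dc in _NEIGHBOR_OFFSETS:
            nb = (r + dr, c + dc)
            if nb in nodes and not g.has_edge((r, c), nb):
                g.add_edge((r, c), nb, weight=float(np.hypot(dr, dc)))
    return g


def extract_centerline(
    mask: np.ndarray, head_anchor: HeadAnchor | tuple[float, float]
) -> np.ndarray | None:
    """Skeletonize the mask and reduce it to a single head-to-tail pixel path.

    The path is the longest geodesic path between skeleton endpoints (side
    branches from fins or rendering artifacts are thereby pruned); ties are
    broken toward the head anchor.  Returns an (k, 2) float array of (x, y)
    coordinates with the head end first, or None on failure (empty mask or a
    ring-shaped skeleton with no endpoints).
    """
    if mask is None or not mask.any():
        return None
    anchor_xy = head_anchor.xy if isinstance(head_anchor, HeadAnchor) else head_anchor
    skel = skeletonize(mask)
    if skel.sum() < 2:
        return None
    g = _skeleton_graph(skel)
    endpoints = [n for n in g.nodes if g.degree(n) == 1]
    if not endpoints:
        return None
    best: tuple[float, float, list] | None = None
    ax, ay = anchor_xy
    for src in endpoints:
        lengths, paths = nx.single_source_dijkstra(g, src, weight="weight")
        for dst in endpoints:
            if dst == src:
                continue
            dist = lengths.get(dst)
            if dist is None:
                continue
            path = paths[dst]
            ends_anchor_dist = min(
                np.hypot(src[1] - ax, src[0] - ay), np.hypot(dst[1] - ax, dst[0] - ay)
            )
            key = (dist, -ends_anchor_dist)
            if best is None or key > (best[0], -best[1]):
                best = (dist, ends_anchor_dist, path)
    if best is None:
        return None
    path = best[2]
    # orient head end first
    first, last = path[0], path[-1]
    d_first = np.hypot(first[1] - ax, first[0] - ay)
    d_last = np.hypot(last[1] - ax, last[0] - ay)
    if d_last < d_first:
        path = path[::-1]
    return np.array([(c, r) for r, c in path], dtype=float)


def resample_centerline(
    path: np.ndarray, n_points: int, smooth_per_point: float = 0.1
) -> Centerline:
    """Fit a smoothing spline to the pixel path and sample at equal arc length.

    ``smooth_per_point`` scales the spline smoothing condition with the path
    length; the default suppresses single-pixel skeleton jitter without
    flattening the body curvature (large values rotate the distal tail).
    """
    path = np.asarray(path, dtype=float)
    if len(path) < 4:
        raise DegeneratePathError(f"centerline path has only {len(path)} points (need >= 4)")
    if n_points < 2:
        raise ParameterError("n_points must be >= 2")
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] <= 0:
        raise DegeneratePathError("centerline path has zero length")
    u = cum / cum[-1]
    # drop duplicate parameter values (repeated pixels)
    keep = np.concatenate([[True], np.diff(u) > 0])
    path, u = path[keep], u[keep]
    if len(path) < 4:
        raise DegeneratePathError("centerline path degenerate after deduplication")
    smooth = len(path) * smooth_per_point
    tck, _ = splprep([path[:, 0], path[:, 1]], u=u, s=smooth, k=3)
    u_dense = np.linspace(0.0, 1.0, max(8 * len(path), 256))
    xd, yd = splev(u_dense, tck)
    dense = np.column_stack([xd, yd])
    seg_d = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg_d)])
    targets = np.linspace(0.0, arc[-1], n_points)
    u_eq = np.interp(targets, arc, u_dense)
    xs, ys = splev(u_eq, tck)
    pts = np.column_stack([xs, ys])
    seg_r = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return Centerline(points=pts, arc_length=np.concatenate([[0.0], np.cumsum(seg_r)]))


def refine_centerline(
    cl: Centerline,
    frame: np.ndarray,
    halfwidth: float = 5.0,
    iterations: int = 2,
) -> Centerline:
    """Subpixel refinement: snap each point to the local intensity centroid.

    For every centerline point the grayscale profile is sampled along the
    local normal (bilinear interpolation) and the point is shifted to the
    brightness-weighted centroid.  This removes the half-pixel placement
    noise of the morphological skeleton, which otherwise dominates the
    tail-angle error budget.
    """
    img = np.asarray(frame, dtype=np.float64)
    bg = np.median(img)
    pts = cl.points.copy()
    offsets = np.linspace(-halfwidth, halfwidth, 11)
    for _ in range(iterations):
        tangents = np.gradient(pts, axis=0)
        norms = np.linalg.norm(tangents, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        tangents /= norms
        normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
        # sample positions: (n_points, n_offsets, 2) in (x, y)
        pos = pts[:, None, :] + offsets[None, :, None] * normals[:, None, :]
        xs = np.clip(pos[..., 0], 0, img.shape[1] - 1)
        ys = np.clip(pos[..., 1], 0, img.shape[0] - 1)
        vals = ndimage.map_coordinates(img, [ys.ravel(), xs.ravel()], order=1)
        weights = np.clip(vals.reshape(pos.shape[:2]) - bg, 0.0, None)
        total = weights.sum(axis=1)
        ok = total > 0
        shift = np.zeros(len(pts))
        shift[ok] = (weights[ok] * offsets[None, :]).sum(axis=1) / total[ok]
        shift = np.clip(shift, -2.0, 2.0)
        pts = pts + shift[:, None] * normals
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return Centerline(points=pts, arc_length=np.concatenate([[0.0], np.cumsum(seg)]))


def compute_tail_angle(cl: Centerline, config: TrackingConfig) -> float | None:
    """Signed angle of the distal tail direction against the head axis.

    The tail direction is the first principal component of the last
    ``n_tail_points`` centerline points (a total-least-squares line), oriented
    head-to-tail.  Positive angles bend toward +y in image coordinates.
    """
    tail = cl.points[-config.n_tail_points :]
    centered = tail - tail.mean(axis=0)
    if np.allclose(centered, 0.0, atol=1e-9):
        return None  # coincident points
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    v = vt[0]
    chord = tail[-1] - tail[0]
    if np.dot(v, chord) < 0:
        v = -v
    if config.head_anchor is not None:
        hx, hy = config.head_anchor.axis
    else:
        head_vec = cl.points[1] - cl.points[0]
        hx, hy = head_vec
    cross = hx * v[1] - hy * v[0]
    dot = hx * v[0] + hy * v[1]
    return float(np.degrees(np.arctan2(cross, dot)))


# ---------------------------------------------------------------------------
# head-anchor estimation and trial tracking
# ---------------------------------------------------------------------------


def estimate_head_anchor(frame: np.ndarray, config: TrackingConfig) -> HeadAnchor:
    """Locate the restrained head on a single frame.

    The head is the thickest part of the silhouette (the agarose-embedded
    blob): the anchor is the centerline endpoint nearest the maximum of the
    mask's distance transform, and the axis points from the anchor into the
    body.
    """
    mask = segment_fish(frame, config)
    if mask is None:
        raise ParameterError("cannot estimate head anchor: no fish found on the frame")
    edt = ndimage.distance_transform_edt(mask)
    r0, c0 = np.unravel_index(int(np.argmax(edt)), edt.shape)
    path = extract_centerline(mask, (float(c0), float(r0)))
    if path is None:
        raise ParameterError("cannot estimate head anchor: degenerate skeleton")
    head = path[0]
    k = min(10, len(path) - 1)
    axis = path[k] - path[0]
    axis = axis / (np.linalg.norm(axis) or 1.0)
    return HeadAnchor(xy=(float(head[0]), float(head[1])), axis=(float(axis[0]), float(axis[1])))


def _angle_for_frame(frame: np.ndarray, config: TrackingConfig, anchor: HeadAnchor) -> float | None:
    mask = segment_fish(frame, config)
    if mask is None:
        return None
    path = extract_centerline(mask, anchor)
    if path is None or len(path) < 4:
        return None
    try:
        cl = resample_centerline(path, config.n_points, config.spline_smooth_per_point)
    except DegeneratePathError:
        return None
    if config.subpixel_refine:
        masked = np.asarray(frame, dtype=np.float64).copy()
        masked[: config.reserved_rows] = 0.0
        cl = refine_centerline(cl, masked)
    return compute_tail_angle(cl, config)


def track_trial(stack: FrameStack, config: TrackingConfig) -> TailAngleTrace:
    """Track every frame of a trial and return the rest-relative angle trace.

    Failed frames inside gaps of at most ``max_gap_frames`` are filled by
    linear interpolation (flagged ``fallback``); longer gaps stay NaN.  The
    rest angle is the median over the pre-first-stimulus baseline window and
    is subtracted, so rest reads as 0 in the trace.  Trials with more than
    20% failed frames are flagged low-quality; analysis still proceeds.
    """
    if stack.times_ms is None:
        decode_timestamps(stack)
    if stack.stimulus_frames is None:
        extract_stimuli(stack)
    anchor = config.head_anchor
    if anchor is None:
        anchor = estimate_head_anchor(stack.frames[0], config)
    cfg = TrackingConfig(**{**config.__dict__, "head_anchor": anchor})

    n = stack.n_frames
    raw = np.full(n, np.nan)
    quality = [QUALITY_FAILED] * n
    for i in range(n):
        a = _angle_for_frame(stack.frames[i], cfg, anchor)
        if a is not None:
            raw[i] = a
            quality[i] = QUALITY_TRACKED

    n_failed = int(np.isnan(raw).sum())
    raw = _fill_short_gaps(raw, quality, config.max_gap_frames)

    if config.median_filter:
        tracked = ~np.isnan(raw)
        filt = pd.Series(raw).rolling(3, center=True, min_periods=1).median().to_numpy()
        raw[tracked] = filt[tracked]

    times = stack.times_ms
    stim_frames = stack.stimulus_frames
    if stim_frames is not None and len(stim_frames):
        t_first = times[stim_frames[0]]
        window = (times >= t_first - config.baseline_window_ms) & (times < t_first)
        if not window.any():
            window = times < t_first
    else:
        window = times <= times[0] + config.baseline_window_ms
    baseline_vals = raw[window]
    baseline_vals = baseline_vals[~np.isnan(baseline_vals)]
    rest = float(np.median(baseline_vals)) if baseline_vals.size else 0.0

    low_quality = n_failed > 0.2 * n
    if low_quality:
        logger.warning("trial flagged low-quality: %d/%d frames failed tracking", n_failed, n)
    return TailAngleTrace(
        times_ms=times,
        angles_deg=raw - rest,
        rest_angle_deg=rest,
        quality=quality,
        fps=stack.fps,
        low_quality=low_quality,
        stimulus_times_ms=(
            [float(times[i]) for i in stim_frames] if stim_frames is not None else []
        ),
    )


def _fill_short_gaps(angles: np.ndarray, quality: list[str], max_gap: int) -> np.ndarray:
    out = angles.copy()
    n = len(out)
    isnan = np.isnan(out)
    i = 0
    while i < n:
        if not isnan[i]:
            i += 1
            continue
        j = i
        while j < n and isnan[j]:
            j += 1
        gap = j - i
        if gap <= max_gap and i > 0 and j < n:
            left, right = out[i - 1], out[j]
            for k in range(gap):
                out[i + k] = left + (right - left) * (k + 1) / (gap + 1)
                quality[i + k] = QUALITY_FALLBACK
        i = j
    return out
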