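"""Synthetic head-restrained-larva videos with scripted, known tail kinematics.

Real startle recordings from the tapping rig are not redistributable, so every
downstream stage (timestamp decoding, tail tracking, event detection,
statistics) is validated against videos generated here, for which the full
kinematic ground truth is known in closed form.

The emulated scene is a bright larva silhouette on a dark background: an
elliptical head blob fixed at an anchor (the agarose-restrained head) and a
tapered tail whose distal direction makes exactly the scripted bend angle with
the head axis.  The C-bend waveform is a half-sine rise from rest to the peak
angle followed by an exponential relaxation — the simplest smooth, unimodal
shape for which onset, peak and time-to-peak are unambiguous.  Frames embed a
binary frame-counter timestamp row and a TTL stimulus-marker block using the
codecs from :mod:`startletrack.acquisition_io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from startletrack.acquisition_io import (
    FrameStack,
    StimulusMarkerSpec,
    TimestampSpec,
    encode_counter_row,
    set_stimulus_marker,
)
from startletrack.errors import ConfigurationError, ParameterError

# Assay constants duplicated from the event layer on purpose, so the ground
# truth is derived in closed form, independent of the code under test: the
# first-movement threshold and the SLC/LLC latency bounds.
_FIRST_MOVE_THRESHOLD_DEG = 5.0
_SLC_MAX_MS = 13.0
_LLC_MAX_MS = 26.0

# Body geometry as fractions of total centerline length: straight head
# segment, then a constant-curvature arc carrying the whole bend, then a
# straight distal segment whose direction is exactly the bend angle.  The
# distal straight fraction covers the last quarter of the body, so the "last
# five of twenty points" measurement sees a straight segment at the scripted
# angle.
_F_HEAD = 0.30
_F_ARC_END = 0.70


@dataclass(frozen=True)
class KinematicScript:
    """Ground-truth parameters of one scripted C-bend.

    ``latency_ms=None`` scripts a no-response event (the tail never moves
    beyond baseline jitter).
    """

    latency_ms: float | None
    peak_angle_deg: float
    time_to_peak_ms: float
    relaxation_ms: float
    baseline_noise_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.latency_ms is not None and self.latency_ms < 0:
            raise ParameterError("latency_ms must be >= 0 or None")
        if abs(self.peak_angle_deg) > 175:
            raise ParameterError("|peak_angle_deg| must be <= 175 (tail cannot cross the head)")
        if self.time_to_peak_ms <= 0:
            raise ParameterError("time_to_peak_ms must be > 0")
        if self.relaxation_ms <= 0:
            raise ParameterError("relaxation_ms must be > 0")
        if self.baseline_noise_deg < 0:
            raise ParameterError("baseline_noise_deg must be >= 0")

    @property
    def responds(self) -> bool:
        return self.latency_ms is not None


@dataclass(frozen=True)
class RigConfig:
    """Recording-rig geometry and timing.

    Defaults mirror the tapping-rig protocol: 640 frames/s, up to six taps per
    trial at a 10 s inter-stimulus interval.  ``isi_s`` is compressible for
    desk-scale tests — escape kinematics conclude within tens of milliseconds,
    so a shorter quiet period changes nothing downstream.  The sensor
    resolution of the original camera is free; 128x128 keeps runtimes small.
    """

    fps: float = 640.0
    frame_shape: tuple[int, int] = (128, 128)
    n_stimuli: int = 6
    isi_s: float = 10.0
    pre_stimulus_ms: float = 100.0
    post_window_ms: float | None = None  # tail of the trial after the last tap; None -> min(isi, 1 s)
    background_level: int = 12
    fish_level: int = 230
    sensor_noise_sd: float = 2.0
    body_length_frac: float = 0.70  # centerline length / frame width
    reserved_rows: int = 8  # metadata band (timestamp row + TTL block)
    timestamp_spec: TimestampSpec = field(default_factory=TimestampSpec)
    stimulus_marker_spec: StimulusMarkerSpec = field(default_factory=StimulusMarkerSpec)

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ParameterError("fps must be positive")
        if self.n_stimuli < 1:
            raise ParameterError("n_stimuli must be >= 1")
        if self.isi_s <= 0 or self.pre_stimulus_ms < 0:
            raise ParameterError("isi_s must be > 0 and pre_stimulus_ms >= 0")
        h, w = self.frame_shape
        if self.timestamp_spec.row >= self.reserved_rows:
            raise ConfigurationError("timestamp row must lie inside the reserved metadata band")
        if self.stimulus_marker_spec.rows[1] > self.reserved_rows:
            raise ConfigurationError("stimulus marker must lie inside the reserved metadata band")
        if w < self.timestamp_spec.n_bits:
            raise ConfigurationError("frame too narrow for the timestamp code row")

    @property
    def frame_period_ms(self) -> float:
        return 1000.0 / self.fps

    @property
    def body_length_px(self) -> float:
        return self.body_length_frac * self.frame_shape[1]

    @property
    def head_anchor_xy(self) -> tuple[float, float]:
        h, w = self.frame_shape
        return (round(0.14 * w), h // 2)

    def stimulus_frame_indices(self) -> np.ndarray:
        pre = round(self.pre_stimulus_ms / 1000.0 * self.fps)
        isi = round(self.isi_s * self.fps)
        return pre + isi * np.arange(self.n_stimuli)

    def n_frames(self) -> int:
        post_ms = self.post_window_ms
        if post_ms is None:
            post_ms = min(self.isi_s * 1000.0, 1000.0)
        post = round(post_ms / 1000.0 * self.fps)
        return int(self.stimulus_frame_indices()[-1] + post)


@dataclass(frozen=True)
class StimulusTruth:
    """Closed-form truth for one stimulus event of a generated trial.

    Two latency notions are stored.  ``latency_ms`` is the scripted kinematic
    onset (when the tail first leaves rest — a generator-internal parameter).
    ``first_move_latency_ms`` is the assay's observable: the first frame time
    at which the noise-free waveform exceeds the 5-degree first-movement
    threshold, quantized to the frame grid exactly as a camera would see it.
    The ground-truth latency class derives from the latter, because the
    SLC/LLC bounds are defined on the measured latency.
    """

    stimulus_index: int
    stimulus_frame: int
    stimulus_time_ms: float
    responded: bool
    latency_ms: float | None  # scripted movement-onset latency
    onset_frame: int | None  # first frame strictly after movement onset
    first_move_latency_ms: float | None  # frame-grid 5-degree crossing
    peak_angle_deg: float | None
    time_to_peak_ms: float | None  # onset -> peak rise time
    peak_time_ms: float | None  # absolute time of the scripted peak
    latency_class: str  # SLC | LLC | OTHER | NONE
    frame_period_ms: float = 1000.0 / 640.0

    @property
    def onset_latency_grid_ms(self) -> float | None:
        """Scripted onset quantized to the frame grid (time of onset_frame)."""
        if self.onset_frame is None:
            return None
        return (self.onset_frame - self.stimulus_frame) * self.frame_period_ms


@dataclass
class GroundTruth:
    """Per-stimulus and per-frame truth stored alongside every generated trial."""

    stimuli: list[StimulusTruth]
    frame_angles_deg: np.ndarray  # noise-free scripted angle at every frame
    fps: float


def _true_class(latency_ms: float | None) -> str:
    if latency_ms is None:
        return "NONE"
    if latency_ms < _SLC_MAX_MS:
        return "SLC"
    if latency_ms <= _LLC_MAX_MS:
        return "LLC"
    return "OTHER"


def _first_move_crossing_ms(script: KinematicScript, period_ms: float) -> float | None:
    """Frame-grid time (ms post-stimulus) at which the noise-free waveform
    first exceeds the 5-degree first-movement threshold; None if it never does.

    The continuous crossing is on the half-sine rise,
    ``t = latency + (2 rise / pi) asin(threshold / |peak|)``; the observable
    crossing is the first frame strictly after it.
    """
    if not script.responds or abs(script.peak_angle_deg) <= _FIRST_MOVE_THRESHOLD_DEG:
        return None
    frac = _FIRST_MOVE_THRESHOLD_DEG / abs(script.peak_angle_deg)
    t_cross = script.latency_ms + (2 * script.time_to_peak_ms / np.pi) * np.arcsin(frac)
    return (np.floor(t_cross / period_ms) + 1) * period_ms


# ---------------------------------------------------------------------------
# waveform
# ---------------------------------------------------------------------------


def _waveform(script: KinematicScript, t_ms: np.ndarray) -> np.ndarray:
    """Noise-free scripted bend angle at times ``t_ms`` after the stimulus."""
    angle = np.zeros_like(t_ms, dtype=float)
    if not script.responds:
        return angle
    lat, rise, relax = script.latency_ms, script.time_to_peak_ms, script.relaxation_ms
    rising = (t_ms > lat) & (t_ms <= lat + rise)
    angle[rising] = script.peak_angle_deg * np.sin(np.pi / 2 * (t_ms[rising] - lat) / rise)
    decaying = t_ms > lat + rise
    angle[decaying] = script.peak_angle_deg * np.exp(-(t_ms[decaying] - lat - rise) / relax)
    return angle


def generate_tail_angle_profile(
    script: KinematicScript,
    fps: float,
    duration_ms: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Sample the scripted tail-angle waveform at the frame grid.

    Time zero is the stimulus; the returned array holds the angle at
    ``t = k / fps * 1000`` for ``k = 0 .. n-1``.  The waveform is zero before
    movement onset, rises as a half-sine to the peak over ``time_to_peak_ms``
    and relaxes exponentially afterwards.  Baseline jitter is added only when
    ``baseline_noise_deg > 0``.
    """
    if fps <= 0 or duration_ms <= 0:
        raise ParameterError("fps and duration_ms must be positive")
    if script.responds and duration_ms < script.latency_ms + script.time_to_peak_ms:
        raise ParameterError("duration_ms must cover latency + time_to_peak")
    n = round(duration_ms / 1000.0 * fps)
    t = np.arange(n) / fps * 1000.0
    angle = _waveform(script, t)
    if script.baseline_noise_deg > 0:
        rng = np.random.default_rng(0) if rng is None else rng
        angle = angle + rng.normal(0.0, script.baseline_noise_deg, size=n)
    return angle


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def centerline_polyline(bend_angle_deg: float, length: float, n: int = 64) -> np.ndarray:
    """Analytic body centerline for a given bend, as ``(n, 2)`` (x, y) points.

    The body starts at the origin heading along +x (the restrained head axis).
    The first ``_F_HEAD`` of arc length is straight, the bend is carried by a
    constant-curvature arc up to ``_F_ARC_END``, and the distal remainder is
    straight with direction exactly ``bend_angle_deg`` from the head axis
    (positive = towards +y, i.e. downward in image coordinates).
    """
    if abs(bend_angle_deg) > 175:
        raise ParameterError("|bend_angle_deg| must be <= 175")
    phi = np.deg2rad(bend_angle_deg)
    s = np.linspace(0.0, 1.0, n) * length
    s1, s2 = _F_HEAD * length, _F_ARC_END * length
    x = np.empty(n)
    y = np.empty(n)
    head = s <= s1
    x[head], y[head] = s[head], 0.0
    arc = (s > s1) & (s <= s2)
    if abs(phi) < 1e-12:
        x[~head], y[~head] = s[~head], 0.0
        return np.column_stack([x, y])
    radius = (s2 - s1) / phi
    theta = phi * (s[arc] - s1) / (s2 - s1)
    x[arc] = s1 + radius * np.sin(theta)
    y[arc] = radius * (1.0 - np.cos(theta))
    x2 = s1 + radius * np.sin(phi)
    y2 = radius * (1.0 - np.cos(phi))
    distal = s > s2
    x[distal] = x2 + (s[distal] - s2) * np.cos(phi)
    y[distal] = y2 + (s[distal] - s2) * np.sin(phi)
    return np.column_stack([x, y])


def _body_widths(s_frac: np.ndarray, length: float) -> np.ndarray:
    # linear taper from a thick trunk to a fine (2 px) tail tip; the pointed
    # tip keeps the morphological skeleton on the midline all the way out
    return 0.10 * length * (1.0 - s_frac) + 2.0


_SUPERSAMPLE = 4  # rasterize at 4x and average-pool: subpixel body placement


def render_fish_frame(bend_angle_deg: float, config: RigConfig) -> np.ndarray:
    """Render one grayscale frame of the larva at the given bend angle.

    The silhouette is rasterized at 4x resolution and average-pooled, so body
    edges are antialiased and the effective centerline placement is subpixel.
    Deterministic for fixed inputs (no noise, no metadata rows; those are
    applied by :func:`generate_trial`).
    """
    h, w = config.frame_shape
    length = config.body_length_px
    x0, y0 = config.head_anchor_xy
    poly = centerline_polyline(bend_angle_deg, length, n=64)
    poly = poly + np.array([x0, y0])

    # feasibility: body outline (centerline +/- local half-width) and the head
    # ellipse must both fit between the metadata band and the frame edges
    s_frac_fit = np.linspace(0.0, 1.0, len(poly))
    half_w = _body_widths(s_frac_fit, length) / 2.0
    hl, hw = 0.13 * length, 0.075 * length
    cx, cy = x0 + 0.11 * length, y0
    x_min = min(poly[:, 0].min() - half_w.max() * 0, (poly[:, 0] - half_w).min(), cx - hl)
    x_max = max((poly[:, 0] + half_w).max(), cx + hl)
    y_min = min((poly[:, 1] - half_w).min(), cy - hw)
    y_max = max((poly[:, 1] + half_w).max(), cy + hw)
    if (
        x_min < 1
        or x_max > w - 2
        or y_min < config.reserved_rows + 1
        or y_max > h - 2
    ):
        raise ConfigurationError(
            f"frame {config.frame_shape} too small to contain the fish at bend {bend_angle_deg:.1f} deg"
        )

    ss = _SUPERSAMPLE
    img = Image.new("L", (w * ss, h * ss), color=config.background_level)
    draw = ImageDraw.Draw(img)
    # head blob: ellipse centred a bit caudal of the anchor, long axis along +x
    draw.ellipse(
        [(cx - hl) * ss, (cy - hw) * ss, (cx + hl) * ss, (cy + hw) * ss],
        fill=config.fish_level,
    )
    # tapered body: thick line segments with round joints along the centerline
    s_frac = np.linspace(0.0, 1.0, len(poly))
    widths = _body_widths(s_frac, length) * ss
    poly_ss = poly * ss
    for i in range(len(poly) - 1):
        wdt = max(1, int(round(widths[i])))
        p, q = poly_ss[i], poly_ss[i + 1]
        draw.line([tuple(p), tuple(q)], fill=config.fish_level, width=wdt)
        r = wdt / 2.0
        draw.ellipse([q[0] - r, q[1] - r, q[0] + r, q[1] + r], fill=config.fish_level)
    arr = np.asarray(img, dtype=np.float64).reshape(h, ss, w, ss).mean(axis=(1, 3))
    return np.round(arr).astype(np.uint8)


# ---------------------------------------------------------------------------
# trials and cohorts
# ---------------------------------------------------------------------------


def generate_trial(
    script: KinematicScript | Sequence[KinematicScript],
    config: RigConfig,
    seed: int,
) -> tuple[FrameStack, GroundTruth]:
    """Render a full trial: six (by default) taps, each following its script.

    ``script`` may be a single :class:`KinematicScript` (reused for every tap)
    or one script per stimulus.  Frames carry the embedded frame-counter
    timestamp row and the TTL marker block; pixel noise (``sensor_noise_sd``)
    is added below the metadata band only.  Fully reproducible from ``seed``.
    """
    if isinstance(script, KinematicScript):
        scripts = [script] * config.n_stimuli
    else:
        scripts = list(script)
        if len(scripts) != config.n_stimuli:
            raise ParameterError(
                f"need {config.n_stimuli} scripts (one per stimulus), got {len(scripts)}"
            )
    rng = np.random.default_rng(seed)
    period = config.frame_period_ms
    stim_frames = config.stimulus_frame_indices()
    n = config.n_frames()
    t = np.arange(n) * period

    # scripted angle per frame: each tap owns the window up to the next tap
    angles = np.zeros(n)
    for k, (sf, sc) in enumerate(zip(stim_frames, scripts)):
        end = stim_frames[k + 1] if k + 1 < len(stim_frames) else n
        if sc.responds and sc.latency_ms + sc.time_to_peak_ms > (end - sf) * period:
            raise ParameterError(
                f"stimulus {k}: latency + time_to_peak does not fit in the post-stimulus window"
            )
        angles[sf:end] = _waveform(sc, t[sf:end] - t[sf])

    noise_sd = max(sc.baseline_noise_deg for sc in scripts)
    observed = angles.copy()
    if noise_sd > 0:
        observed = observed + rng.normal(0.0, noise_sd, size=n)

    h, w = config.frame_shape
    frames = np.empty((n, h, w), dtype=np.uint8)
    cache: dict[float, np.ndarray] = {}
    marker_dur = config.stimulus_marker_spec.duration_frames
    marker_on = np.zeros(n, dtype=bool)
    for sf in stim_frames:
        marker_on[sf : sf + marker_dur] = True
    for i in range(n):
        key = round(float(observed[i]), 3)
        base = cache.get(key)
        if base is None:
            base = render_fish_frame(key, config)
            cache[key] = base
        frame = base.copy()
        if config.sensor_noise_sd > 0:
            body = frame[config.reserved_rows :].astype(np.float64)
            body += rng.normal(0.0, config.sensor_noise_sd, size=body.shape)
            frame[config.reserved_rows :] = np.clip(body, 0, 255).astype(np.uint8)
        encode_counter_row(frame, i, config.timestamp_spec)
        set_stimulus_marker(frame, bool(marker_on[i]), config.stimulus_marker_spec)
        frames[i] = frame

    stimuli = []
    for k, (sf, sc) in enumerate(zip(stim_frames, scripts)):
        first_move = _first_move_crossing_ms(sc, period)
        if sc.responds and first_move is not None:
            onset_frame = int(sf + np.floor(sc.latency_ms / period) + 1)
            truth = StimulusTruth(
                stimulus_index=k,
                stimulus_frame=int(sf),
                stimulus_time_ms=float(t[sf]),
                responded=True,
                latency_ms=sc.latency_ms,
                onset_frame=onset_frame,
                first_move_latency_ms=float(first_move),
                peak_angle_deg=abs(sc.peak_angle_deg),
                time_to_peak_ms=sc.time_to_peak_ms,
                peak_time_ms=float(t[sf]) + sc.latency_ms + sc.time_to_peak_ms,
                latency_class=_true_class(float(first_move)),
                frame_period_ms=period,
            )
        else:
            truth = StimulusTruth(
                stimulus_index=k,
                stimulus_frame=int(sf),
                stimulus_time_ms=float(t[sf]),
                responded=False,
                latency_ms=None,
                onset_frame=None,
                first_move_latency_ms=None,
                peak_angle_deg=None,
                time_to_peak_ms=None,
                peak_time_ms=None,
                latency_class="NONE",
                frame_period_ms=period,
            )
        stimuli.append(truth)
    stack = FrameStack(frames=frames, fps=config.fps)
    return stack, GroundTruth(stimuli=stimuli, frame_angles_deg=angles, fps=config.fps)


@dataclass(frozen=True)
class ScriptDistribution:
    """Per-tap sampling distribution for a cohort group.

    Latency, peak angle and rise time are sampled uniformly from their ranges;
    each tap elicits a response with probability ``response_prob``.  Defaults
    emulate a healthy control group: ~95% responsiveness, short-latency
    escapes with a median latency of ~7 ms and large C-bend maxima.
    """

    response_prob: float = 0.95
    latency_range_ms: tuple[float, float] = (4.0, 10.0)
    peak_range_deg: tuple[float, float] = (80.0, 140.0)
    time_to_peak_range_ms: tuple[float, float] = (4.0, 8.0)
    relaxation_ms: float = 20.0
    baseline_noise_deg: float = 0.5

    def shifted(self, latency_shift_ms: float) -> "ScriptDistribution":
        lo, hi = self.latency_range_ms
        return replace(self, latency_range_ms=(lo + latency_shift_ms, hi + latency_shift_ms))

    def sample(self, rng: np.random.Generator) -> KinematicScript:
        responds = rng.random() < self.response_prob
        # draw kinematics regardless of response so the RNG stream is aligned
        lat = rng.uniform(*self.latency_range_ms)
        peak = rng.uniform(*self.peak_range_deg)
        rise = rng.uniform(*self.time_to_peak_range_ms)
        return KinematicScript(
            latency_ms=float(lat) if responds else None,
            peak_angle_deg=float(peak),
            time_to_peak_ms=float(rise),
            relaxation_ms=self.relaxation_ms,
            baseline_noise_deg=self.baseline_noise_deg,
        )


@dataclass(frozen=True)
class GroupSpec:
    label: str
    distribution: ScriptDistribution
    n_fish: int


@dataclass
class TrialRecord:
    fish_id: str
    group: str
    stack: FrameStack
    truth: GroundTruth


def iter_cohort_trials(
    group_specs: Sequence[GroupSpec], config: RigConfig, seed: int
) -> Iterator[TrialRecord]:
    """Lazily generate one trial per fish for every group (memory-friendly)."""
    if not group_specs:
        raise ParameterError("at least one group is required")
    for spec in group_specs:
        if spec.n_fish < 1:
            raise ParameterError(f"group {spec.label!r} is empty")
    ss = np.random.SeedSequence(seed)
    fish_counter = 0
    for spec in group_specs:
        for child in ss.spawn(spec.n_fish):
            rng = np.random.default_rng(child)
            scripts = [spec.distribution.sample(rng) for _ in range(config.n_stimuli)]
            trial_seed = int(rng.integers(0, 2**31 - 1))
            stack, truth = generate_trial(scripts, config, trial_seed)
            yield TrialRecord(
                fish_id=f"fish_{fish_counter:04d}", group=spec.label, stack=stack, truth=truth
            )
            fish_counter += 1


def ground_truth_table(records: Sequence[tuple[str, str, GroundTruth]]) -> pd.DataFrame:
    """Flatten per-trial ground truth into one row per stimulus event."""
    rows = []
    for fish_id, group, truth in records:
        for st in truth.stimuli:
            rows.append(
                {
                    "fish_id": fish_id,
                    "group": group,
                    "stimulus_index": st.stimulus_index,
                    "stimulus_time_ms": st.stimulus_time_ms,
                    "responded": st.responded,
                    "true_latency_ms": st.latency_ms,
                    "true_first_move_ms": st.first_move_latency_ms,
                    "true_onset_ms": (
                        None if st.latency_ms is None else st.stimulus_time_ms + st.latency_ms
                    ),
                    "true_peak_deg": st.peak_angle_deg,
                    "true_time_to_peak_ms": st.time_to_peak_ms,
                    "true_class": st.latency_class,
                }
            )
    return pd.DataFrame(rows)


def generate_cohort(
    group_specs: Sequence[GroupSpec],
    config: RigConfig,
    seed: int,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Generate a cohort and (optionally) write TIFF stacks plus the truth CSV.

    Returns the ground-truth table (one row per stimulus event).  When
    ``out_dir`` is given, each fish is written as ``<fish_id>.tif`` and the
    table as ``ground_truth.csv``.
    """
    import tifffile

    records = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for rec in iter_cohort_trials(group_specs, config, seed):
        if out is not None:
            tifffile.imwrite(out / f"{rec.fish_id}.tif", rec.stack.frames, photometric="minisblack")
        records.append((rec.fish_id, rec.group, rec.truth))
    table = ground_truth_table(records)
    if out is not None:
        table.to_csv(out / "ground_truth.csv", index=False)
    return table
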