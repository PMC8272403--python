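"""Frame-stack I/O, per-frame timestamp decoding and stimulus-marker extraction.

High-speed startle recordings carry two in-image metadata channels:

* a per-frame hardware timestamp (emulating the camera's secure-image-signature
  feature), encoded here as a binary frame counter in a reserved pixel row, and
* a TTL stimulus-feedback marker (the rig flags the frames during which the
  tap solenoid fired), encoded as a saturated pixel block in a frame corner.

Both encodings are open and exactly invertible; the encoders live here next to
the decoders so round-trip behaviour is defined in one place.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from startletrack.errors import CorruptStreamError, FrameIOError, ParameterError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TimestampSpec:
    """Layout of the binary frame-counter row.

    Bit ``j`` of the counter (least significant first) is written to column
    ``j`` of row ``row``: ``on_value`` for a set bit, 0 otherwise.
    """

    row: int = 0
    n_bits: int = 32
    on_value: int = 255


@dataclass(frozen=True)
class StimulusMarkerSpec:
    """Layout of the TTL stimulus-feedback block (top-right pixel corner).

    The block spans rows ``rows[0]:rows[1]`` and the last ``cols_from_right``
    columns; it is saturated to ``on_value`` on every frame during which the
    stimulus TTL is high (``duration_frames`` consecutive frames per tap).
    """

    rows: tuple[int, int] = (2, 6)
    cols_from_right: int = 5
    on_value: int = 255
    duration_frames: int = 3


@dataclass
class FrameStack:
    """Ordered grayscale frames plus the decoded trial time base.

    ``times_ms`` and ``stimulus_frames`` are populated by
    :func:`decode_timestamps` and :func:`extract_stimuli`; all times are in
    milliseconds from the first frame.
    """

    frames: np.ndarray  # (n_frames, height, width), grayscale
    fps: float
    times_ms: np.ndarray | None = None
    stimulus_frames: np.ndarray | None = None
    dropped_frame_gaps: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ParameterError(f"fps must be positive, got {self.fps}")
        if self.frames.ndim != 3:
            raise ParameterError(
                f"frames must be a (n, height, width) array, got ndim={self.frames.ndim}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def frame_period_ms(self) -> float:
        return 1000.0 / self.fps


@dataclass
class StimulusLog:
    """Stimulus reception times recovered from the TTL frame marker."""

    stimulus_times_ms: list[float]
    stimulus_frames: list[int]
    isi_s: float | None = None


# ---------------------------------------------------------------------------
# encoders (used by the synthetic rig; inverses of the decoders below)
# ---------------------------------------------------------------------------


def encode_counter_row(frame: np.ndarray, counter: int, spec: TimestampSpec = TimestampSpec()) -> None:
    """Write the binary frame counter into the reserved row of ``frame`` in place."""
    if counter < 0 or counter >= 2**spec.n_bits:
        raise ParameterError(f"counter {counter} does not fit in {spec.n_bits} bits")
    bits = (counter >> np.arange(spec.n_bits)) & 1
    frame[spec.row, : spec.n_bits] = bits * spec.on_value
    frame[spec.row, spec.n_bits :] = 0


def set_stimulus_marker(
    frame: np.ndarray, on: bool, spec: StimulusMarkerSpec = StimulusMarkerSpec()
) -> None:
    """Set or clear the TTL marker block of ``frame`` in place."""
    r0, r1 = spec.rows
    frame[r0:r1, -spec.cols_from_right :] = spec.on_value if on else 0


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def read_frames(path: str | Path, fps: float) -> FrameStack:
    """Read a multi-page TIFF or a directory of lexically ordered PNG frames.

    Frames are returned in acquisition order with bit depth preserved; the
    stack is undecoded (no time base) until :func:`decode_timestamps` runs.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.png"))
        if not files:
            raise FrameIOError(f"no PNG frames found in directory {path}")
        frames = []
        for f in files:
            try:
                img = iio.imread(f)
            except Exception as exc:  # noqa: BLE001 - report the offending file
                raise FrameIOError(f"could not read frame {f}: {exc}") from exc
            frames.append(_as_grayscale(img, f))
        shapes = {fr.shape for fr in frames}
        if len(shapes) > 1:
            offender = next(f for f, fr in zip(files, frames) if fr.shape != frames[0].shape)
            raise FrameIOError(f"mixed frame shapes; first offending frame: {offender}")
        arr = np.stack(frames)
    else:
        try:
            arr = tifffile.imread(path)
        except Exception as exc:  # noqa: BLE001
            raise FrameIOError(f"could not read TIFF stack {path}: {exc}") from exc
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise FrameIOError(f"{path}: expected grayscale pages, got shape {arr.shape}")
    if arr.shape[0] == 0:
        raise FrameIOError(f"empty frame stack: {path}")
    return FrameStack(frames=arr, fps=fps)


def write_frames(path: str | Path, stack: FrameStack) -> None:
    """Write a stack as an 8/16-bit grayscale multi-page TIFF."""
    tifffile.imwrite(Path(path), stack.frames, photometric="minisblack")


def _as_grayscale(img: np.ndarray, name: object) -> np.ndarray:
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[2] in (3, 4):
        rgb = img[..., :3]
        if not (rgb[..., 0] == rgb[..., 1]).all() or not (rgb[..., 1] == rgb[..., 2]).all():
            raise FrameIOError(f"frame {name} is not grayscale")
        return rgb[..., 0]
    raise FrameIOError(f"frame {name} has unsupported shape {img.shape}")


# ---------------------------------------------------------------------------
# decoders
# ---------------------------------------------------------------------------


def decode_counters(stack: FrameStack, spec: TimestampSpec = TimestampSpec()) -> np.ndarray:
    """Decode the raw per-frame counter values without converting to time."""
    row = stack.frames[:, spec.row, : spec.n_bits]
    bits = (row.astype(np.int64) > spec.on_value // 2).astype(np.int64)
    weights = 1 << np.arange(spec.n_bits, dtype=np.int64)
    return bits @ weights


def decode_timestamps(stack: FrameStack, spec: TimestampSpec = TimestampSpec()) -> np.ndarray:
    """Decode per-frame times (ms from the first frame) from the counter row.

    Dropped frames show up as counter gaps; they are reported via logging and
    recorded in ``stack.dropped_frame_gaps`` (index of the frame *after* each
    gap) but the time base is kept honest — times jump by the true gap.
    Non-monotone counters raise :class:`CorruptStreamError`.  A stack with no
    counter row at all (all-zero codes) falls back to ``index / fps`` with a
    logged warning.
    """
    counters = decode_counters(stack, spec)
    if stack.n_frames > 1 and (counters == 0).all():
        logger.warning("no timestamp code row found; falling back to frame index / fps")
        times = np.arange(stack.n_frames, dtype=float) / stack.fps * 1000.0
        stack.times_ms = times
        return times
    diffs = np.diff(counters)
    if (diffs <= 0).any():
        bad = int(np.argmax(diffs <= 0)) + 1
        raise CorruptStreamError(f"non-monotone frame counter at frame {bad}")
    gaps = np.flatnonzero(diffs > 1) + 1
    if gaps.size:
        stack.dropped_frame_gaps = [int(g) for g in gaps]
        logger.warning(
            "dropped frames detected before frame indices %s (counter gaps %s)",
            stack.dropped_frame_gaps,
            [int(diffs[g - 1] - 1) for g in gaps],
        )
    times = (counters - counters[0]) / stack.fps * 1000.0
    stack.times_ms = times
    return times


def extract_stimuli(
    stack: FrameStack, spec: StimulusMarkerSpec = StimulusMarkerSpec()
) -> StimulusLog:
    """Log one stimulus at the first frame of each maximal run of marker-on frames.

    Times are taken from the decoded timestamps (decoding is performed on
    demand).  An all-off marker channel yields an empty log, which is valid;
    downstream exclusion is the caller's choice.
    """
    if stack.times_ms is None:
        decode_timestamps(stack)
    r0, r1 = spec.rows
    block = stack.frames[:, r0:r1, -spec.cols_from_right :]
    on = block.mean(axis=(1, 2)) > spec.on_value / 2
    onsets = np.flatnonzero(on & ~np.concatenate(([False], on[:-1])))
    if onsets.size == 0:
        logger.info("no stimulus marker found in stack; trial will be excluded downstream")
    stack.stimulus_frames = onsets
    times = [float(stack.times_ms[i]) for i in onsets]
    return StimulusLog(stimulus_times_ms=times, stimulus_frames=[int(i) for i in onsets])


def stimulus_log_to_csv(log: StimulusLog, path: str | Path) -> None:
    """Write a stimulus log as CSV (stimulus_index, frame, time_ms)."""
    import pandas as pd

    pd.DataFrame(
        {
            "stimulus_index": np.arange(len(log.stimulus_times_ms)),
            "frame": log.stimulus_frames,
            "time_ms": log.stimulus_times_ms,
        }
    ).to_csv(path, index=False)
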