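"""Escape-event detection, latency metrics and SLC/LLC classification.

From a rest-relative tail-angle trace and the stimulus times, each tap yields
one event record:

* latency to first movement — time from the stimulus to the first frame whose
  absolute angle change from rest exceeds 5 degrees;
* escape / C-bend max — the event is an escape when the angle crosses 60
  degrees from rest; the C-bend max is the largest absolute excursion and
  t_peak the first frame attaining it;
* latency to C-bend max — time to the peak minus the latency to first
  movement;
* latency class — short-latency C-bend (SLC, latency < 13 ms; Mauthner-cell
  mediated), long-latency C-bend (LLC, 13-26 ms inclusive), or OTHER beyond
  26 ms.  Non-responding events are class NONE.

All latencies are quantized to the frame grid (multiples of 1000/fps ms when
the camera drops no frames).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from startletrack.errors import ParameterError
from startletrack.tail_tracking import TailAngleTrace

logger = logging.getLogger(__name__)

CLASS_SLC = "SLC"
CLASS_LLC = "LLC"
CLASS_OTHER = "OTHER"
CLASS_NONE = "NONE"


@dataclass(frozen=True)
class EventConfig:
    """Thresholds and windows of the event detector (all angles rest-relative).

    Defaults are the assay's standard values: 5 degrees marks first movement,
    60 degrees qualifies an escape, SLC means latency < 13 ms and LLC covers
    13-26 ms.  ``rebaseline_window_ms`` re-estimates the local rest angle from
    the frames immediately before each tap (robust to slow drift across the
    six taps); 0 disables it.
    """

    first_move_threshold_deg: float = 5.0
    escape_threshold_deg: float = 60.0
    slc_max_ms: float = 13.0
    llc_max_ms: float = 26.0
    response_window_ms: float = 1000.0
    rebaseline_window_ms: float = 50.0

    def __post_init__(self) -> None:
        if not (0 < self.first_move_threshold_deg < self.escape_threshold_deg):
            raise ParameterError("need 0 < first_move_threshold_deg < escape_threshold_deg")
        if not (self.slc_max_ms < self.llc_max_ms <= self.response_window_ms):
            raise ParameterError("need slc_max_ms < llc_max_ms <= response_window_ms")


@dataclass
class EscapeEvent:
    """Per-stimulus behavioral record."""

    stimulus_time_ms: float
    responded: bool
    latency_first_move_ms: float | None = None
    is_escape: bool = False
    c_bend_max_deg: float | None = None
    latency_c_bend_max_ms: float | None = None  # time-to-peak minus latency to first movement
    latency_class: str = CLASS_NONE


def _window(trace: TailAngleTrace, t_stim: float, cfg: EventConfig) -> tuple[np.ndarray, np.ndarray]:
    """Rest-corrected angles and times in (t_stim, t_stim + response window]."""
    t = trace.times_ms
    if t[-1] < t_stim + cfg.response_window_ms:
        warnings.warn(
            "response window extends past the end of the trace; searching available frames",
            stacklevel=3,
        )
    sel = (t > t_stim) & (t <= t_stim + cfg.response_window_ms)
    ang = trace.angles_deg[sel]
    if cfg.rebaseline_window_ms > 0:
        pre = (t >= t_stim - cfg.rebaseline_window_ms) & (t <= t_stim)
        pre_vals = trace.angles_deg[pre]
        pre_vals = pre_vals[~np.isnan(pre_vals)]
        if pre_vals.size >= 3:
            ang = ang - np.median(pre_vals)
    return ang, t[sel]


def detect_first_movement(
    trace: TailAngleTrace, t_stim_ms: float, cfg: EventConfig = EventConfig()
) -> float | None:
    """Latency (ms) to the first supra-threshold angle change, or None.

    The latency is the time of the first frame after the stimulus at which
    the absolute rest-relative angle exceeds ``first_move_threshold_deg``,
    minus the stimulus time.
    """
    ang, t = _window(trace, t_stim_ms, cfg)
    with np.errstate(invalid="ignore"):
        crossing = np.abs(ang) > cfg.first_move_threshold_deg
    idx = np.flatnonzero(crossing)
    if idx.size == 0:
        return None
    return float(t[idx[0]] - t_stim_ms)


def detect_escape(
    trace: TailAngleTrace, t_stim_ms: float, cfg: EventConfig = EventConfig()
) -> tuple[bool, float | None, float | None]:
    """Escape decision, C-bend max (deg, unsigned) and peak time (ms post-stimulus).

    The event is an escape when the maximum absolute rest-relative angle in
    the response window exceeds ``escape_threshold_deg``.  With two equal
    maxima the earlier frame is reported.
    """
    ang, t = _window(trace, t_stim_ms, cfg)
    finite = ~np.isnan(ang)
    if not finite.any():
        return False, None, None
    mags = np.abs(ang)
    mags[~finite] = -np.inf
    i_peak = int(np.argmax(mags))  # argmax returns the first of equal maxima
    c_max = float(mags[i_peak])
    t_peak = float(t[i_peak] - t_stim_ms)
    return c_max > cfg.escape_threshold_deg, c_max, t_peak


def classify_latency(latency_ms: float, cfg: EventConfig = EventConfig()) -> str:
    """SLC (< 13 ms), LLC (13-26 ms, boundaries included) or OTHER (> 26 ms)."""
    if latency_ms < 0:
        raise ParameterError("latency_ms must be >= 0")
    if latency_ms < cfg.slc_max_ms:
        return CLASS_SLC
    if latency_ms <= cfg.llc_max_ms:
        return CLASS_LLC
    return CLASS_OTHER


def build_event(
    trace: TailAngleTrace, t_stim_ms: float, cfg: EventConfig = EventConfig()
) -> EscapeEvent:
    """Assemble the full per-stimulus event record.

    ``latency_c_bend_max`` is the total time to the maximum angle minus the
    latency to first movement.  Non-responding events carry no kinematics.
    """
    latency = detect_first_movement(trace, t_stim_ms, cfg)
    if latency is None:
        return EscapeEvent(stimulus_time_ms=t_stim_ms, responded=False)
    is_escape, c_max, t_peak = detect_escape(trace, t_stim_ms, cfg)
    # an escape without a first-movement crossing is impossible (60 > 5)
    assert not (is_escape and latency is None)
    return EscapeEvent(
        stimulus_time_ms=t_stim_ms,
        responded=True,
        latency_first_move_ms=latency,
        is_escape=is_escape,
        c_bend_max_deg=c_max,
        latency_c_bend_max_ms=None if t_peak is None else t_peak - latency,
        latency_class=classify_latency(latency, cfg),
    )


def events_for_trial(
    trace: TailAngleTrace, stimulus_times_ms: list[float] | None = None, cfg: EventConfig = EventConfig()
) -> list[EscapeEvent]:
    """One event per stimulus of a tracked trial.

    Each stimulus's search window is clipped at the next stimulus so one tap's
    response is never attributed to the preceding tap.
    """
    stims = stimulus_times_ms if stimulus_times_ms is not None else trace.stimulus_times_ms
    events = []
    for k, t in enumerate(stims):
        window = cfg.response_window_ms
        if k + 1 < len(stims):
            window = min(window, stims[k + 1] - t)
        local = cfg if window == cfg.response_window_ms else _clipped(cfg, window)
        events.append(build_event(trace, t, local))
    return events


def _clipped(cfg: EventConfig, window_ms: float) -> EventConfig:
    from dataclasses import replace

    return replace(cfg, response_window_ms=window_ms, llc_max_ms=min(cfg.llc_max_ms, window_ms))


def events_table(records: list[tuple[str, str, int, EscapeEvent]]) -> pd.DataFrame:
    """Flatten (fish_id, group, stimulus_index, event) records into a table."""
    rows = []
    for fish_id, group, stim_idx, ev in records:
        rows.append(
            {
                "fish_id": fish_id,
                "group": group,
                "stimulus_index": stim_idx,
                "stimulus_time_ms": ev.stimulus_time_ms,
                "responded": ev.responded,
                "latency_first_move_ms": ev.latency_first_move_ms,
                "is_escape": ev.is_escape,
                "c_bend_max_deg": ev.c_bend_max_deg,
                "latency_c_bend_max_ms": ev.latency_c_bend_max_ms,
                "latency_class": ev.latency_class,
            }
        )
    return pd.DataFrame(rows)


def summarize_group(events: pd.DataFrame, group: str) -> dict:
    """Group-level behavior summary.

    Responsiveness is the fraction of delivered stimuli that elicited a
    response (pooled over events); SLC/LLC/OTHER fractions are computed over
    responded events; medians are over responded events with the respective
    measurement.  A per-larva responsiveness roll-up (a larva responds when at
    least one of its taps does) is included as ``responsiveness_per_larva``.
    """
    sub = events[events["group"] == group]
    n_stimuli = len(sub)
    if n_stimuli == 0:
        raise ParameterError(f"no stimuli delivered for group {group!r}")
    responded = sub[sub["responded"]]
    n_resp = len(responded)
    frac = lambda cls: (responded["latency_class"] == cls).sum() / n_resp if n_resp else float("nan")
    per_larva = sub.groupby("fish_id")["responded"].any()
    return {
        "group": group,
        "n_stimuli": int(n_stimuli),
        "n_responded": int(n_resp),
        "responsiveness": n_resp / n_stimuli,
        "responsiveness_per_larva": float(per_larva.mean()),
        "slc_fraction": float(frac(CLASS_SLC)),
        "llc_fraction": float(frac(CLASS_LLC)),
        "other_fraction": float(frac(CLASS_OTHER)),
        "median_latency_ms": (
            float(responded["latency_first_move_ms"].median()) if n_resp else float("nan")
        ),
        "median_c_bend_max_deg": (
            float(responded["c_bend_max_deg"].median()) if n_resp else float("nan")
        ),
        "median_latency_c_bend_max_ms": (
            float(responded["latency_c_bend_max_ms"].median()) if n_resp else float("nan")
        ),
    }
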