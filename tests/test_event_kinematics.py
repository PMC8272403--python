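"""Event detection on angle traces: thresholds, latencies, classes, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from startletrack import event_kinematics as ek
from startletrack.errors import ParameterError
from startletrack.tail_tracking import TailAngleTrace

FPS = 640.0
PERIOD = 1000.0 / FPS


def make_trace(angles, fps=FPS, stim_times=None):
    angles = np.asarray(angles, dtype=float)
    return TailAngleTrace(
        times_ms=np.arange(len(angles)) * 1000.0 / fps,
        angles_deg=angles,
        rest_angle_deg=0.0,
        quality=["tracked"] * len(angles),
        fps=fps,
        stimulus_times_ms=list(stim_times or []),
    )


# a config whose window fits comfortably inside the short synthetic traces
CFG = ek.EventConfig(response_window_ms=100.0, rebaseline_window_ms=0.0)


class TestFirstMovement:
    def test_flat_trace_gives_none(self):
        trace = make_trace(np.zeros(128))
        assert ek.detect_first_movement(trace, 10 * PERIOD, CFG) is None

    def test_step_seven_frames_after_stimulus(self):
        angles = np.zeros(128)
        angles[10 + 7 :] = 10.0
        trace = make_trace(angles)
        lat = ek.detect_first_movement(trace, 10 * PERIOD, CFG)
        assert lat == pytest.approx(7 * PERIOD)
        assert lat == pytest.approx(10.9375)

    def test_subthreshold_excursion_ignored(self):
        angles = np.zeros(128)
        angles[20:30] = 4.0  # below the 5-degree first-movement threshold
        trace = make_trace(angles)
        assert ek.detect_first_movement(trace, 10 * PERIOD, CFG) is None

    def test_negative_bends_count(self):
        angles = np.zeros(128)
        angles[25:] = -12.0
        trace = make_trace(angles)
        assert ek.detect_first_movement(trace, 10 * PERIOD, CFG) == pytest.approx(15 * PERIOD)


class TestEscape:
    def test_fifty_nine_degrees_is_not_an_escape(self):
        angles = np.zeros(128)
        angles[20:40] = 59.0
        trace = make_trace(angles)
        is_escape, c_max, _ = ek.detect_escape(trace, 10 * PERIOD, CFG)
        assert not is_escape
        assert c_max == pytest.approx(59.0)

    def test_sixty_one_degrees_is_an_escape(self):
        angles = np.zeros(128)
        peak_frame = 10 + round(20 / PERIOD)
        angles[peak_frame] = 61.0
        trace = make_trace(angles)
        is_escape, c_max, t_peak = ek.detect_escape(trace, 10 * PERIOD, CFG)
        assert is_escape
        assert c_max == pytest.approx(61.0)
        assert t_peak == pytest.approx((peak_frame - 10) * PERIOD)

    def test_equal_maxima_earlier_frame_wins(self):
        angles = np.zeros(128)
        angles[30] = 80.0
        angles[50] = 80.0
        trace = make_trace(angles)
        _, _, t_peak = ek.detect_escape(trace, 10 * PERIOD, CFG)
        assert t_peak == pytest.approx(20 * PERIOD)


class TestClassification:
    @pytest.mark.parametrize(
        "latency,expected",
        [(12.0, "SLC"), (12.9999, "SLC"), (13.0, "LLC"), (20.0, "LLC"), (26.0, "LLC"), (26.001, "OTHER"), (30.0, "OTHER")],
    )
    def test_boundaries(self, latency, expected):
        assert ek.classify_latency(latency) == expected

    def test_negative_latency_rejected(self):
        with pytest.raises(ParameterError):
            ek.classify_latency(-1.0)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=500.0, allow_nan=False))
    def test_every_latency_maps_to_exactly_one_class(self, latency):
        cls = ek.classify_latency(latency)
        assert cls in ("SLC", "LLC", "OTHER")


class TestBuildEvent:
    def test_latency_to_peak_is_difference(self):
        # onset crossing at 12.5 ms post-stimulus, peak at 25 ms -> 12.5 ms
        angles = np.zeros(256)
        t_stim_frame = 16
        onset = t_stim_frame + 8  # 12.5 ms on the 640 fps grid
        peak = t_stim_frame + 16  # 25 ms
        angles[onset:peak] = 20.0
        angles[peak] = 90.0
        angles[peak + 1 :] = 10.0
        trace = make_trace(angles)
        ev = ek.build_event(trace, t_stim_frame * PERIOD, CFG)
        assert ev.responded and ev.is_escape
        assert ev.latency_first_move_ms == pytest.approx(12.5)
        assert ev.latency_c_bend_max_ms == pytest.approx(25.0 - 12.5, abs=1e-9)

    def test_no_crossing_gives_none_class(self):
        ev = ek.build_event(make_trace(np.zeros(128)), 10 * PERIOD, CFG)
        assert not ev.responded
        assert ev.latency_class == "NONE"
        assert ev.latency_first_move_ms is None
        assert ev.c_bend_max_deg is None

    def test_latency_quantized_to_frame_grid(self):
        rng = np.random.default_rng(0)
        angles = np.zeros(256)
        angles[40:] = 90.0
        trace = make_trace(angles)
        for stim_frame in (10, 17, 23):
            ev = ek.build_event(trace, stim_frame * PERIOD, CFG)
            assert (ev.latency_first_move_ms / PERIOD) == pytest.approx(
                round(ev.latency_first_move_ms / PERIOD)
            )

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=6, max_value=20), st.integers(min_value=0, max_value=1000))
    def test_raising_threshold_never_shortens_latency(self, thresh, seed):
        rng = np.random.default_rng(seed)
        angles = np.cumsum(rng.normal(0, 4.0, size=128))
        trace = make_trace(angles - angles[:10].mean())
        lo = ek.EventConfig(
            first_move_threshold_deg=5.0, response_window_ms=100.0, rebaseline_window_ms=0.0
        )
        hi = ek.EventConfig(
            first_move_threshold_deg=float(thresh), response_window_ms=100.0, rebaseline_window_ms=0.0
        )
        l_lo = ek.detect_first_movement(trace, 5 * PERIOD, lo)
        l_hi = ek.detect_first_movement(trace, 5 * PERIOD, hi)
        if l_hi is not None:
            assert l_lo is not None and l_hi >= l_lo

    def test_window_clipped_at_next_stimulus(self):
        # a response to tap 2 must not be attributed to a silent tap 1
        angles = np.zeros(512)
        stim1, stim2 = 64, 256
        angles[stim2 + 8 :] = 90.0
        trace = make_trace(angles, stim_times=[stim1 * PERIOD, stim2 * PERIOD])
        evs = ek.events_for_trial(trace, cfg=ek.EventConfig(rebaseline_window_ms=0.0))
        assert not evs[0].responded
        assert evs[1].responded


class TestGroupSummary:
    def _events(self):
        rows = []
        for i in range(100):
            responded = i < 94
            rows.append(
                (
                    f"fish_{i % 10}",
                    "g",
                    i,
                    ek.EscapeEvent(
                        stimulus_time_ms=0.0,
                        responded=responded,
                        latency_first_move_ms=8.0 if responded else None,
                        is_escape=responded,
                        c_bend_max_deg=100.0 if responded else None,
                        latency_c_bend_max_ms=5.0 if responded else None,
                        latency_class="SLC" if responded else "NONE",
                    ),
                )
            )
        return ek.events_table(rows)

    def test_responsiveness_ratio(self):
        summ = ek.summarize_group(self._events(), "g")
        assert summ["responsiveness"] == pytest.approx(0.94)

    def test_all_slc(self):
        summ = ek.summarize_group(self._events(), "g")
        assert summ["slc_fraction"] == pytest.approx(1.0)
        assert summ["llc_fraction"] == pytest.approx(0.0)

    def test_fractions_partition_responded_events(self):
        summ = ek.summarize_group(self._events(), "g")
        total = summ["slc_fraction"] + summ["llc_fraction"] + summ["other_fraction"]
        assert total == pytest.approx(1.0)

    def test_unknown_group_rejected(self):
        with pytest.raises(ParameterError):
            ek.summarize_group(self._events(), "nope")
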