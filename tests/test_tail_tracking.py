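"""Centerline extraction and the tail angle must recover the scripted geometry."""

import numpy as np
import pytest

from startletrack import synthetic_rig as sr
from startletrack import tail_tracking as tt
from startletrack.errors import DegeneratePathError


class TestSegmentation:
    def test_speck_ignored(self, fast_rig, tracking_config):
        frame = sr.render_fish_frame(30.0, fast_rig).copy()
        frame[100:102, 118:120] = 255  # 4-px noise speck away from the fish
        mask = tt.segment_fish(frame, tracking_config)
        assert mask is not None
        assert not mask[100:102, 118:120].any()

    def test_blank_frame_fails(self, tracking_config):
        assert tt.segment_fish(np.zeros((128, 128), dtype=np.uint8), tracking_config) is None

    def test_mask_area_matches_rendered_silhouette(self, fast_rig, tracking_config):
        frame = sr.render_fish_frame(0.0, fast_rig)
        level = (fast_rig.background_level + fast_rig.fish_level) / 2
        rendered_area = int((frame > level).sum())
        mask = tt.segment_fish(frame, tracking_config)
        assert abs(int(mask.sum()) - rendered_area) <= 0.1 * rendered_area


class TestCenterline:
    def test_straight_bar_midline(self):
        mask = np.zeros((40, 120), dtype=bool)
        mask[17:23, 10:110] = True  # 100 x 6 bar
        path = tt.extract_centerline(mask, (10.0, 20.0))
        assert path is not None
        seg = np.linalg.norm(np.diff(path, axis=0), axis=1).sum()
        assert seg == pytest.approx(100, abs=8)
        assert np.abs(path[:, 1] - 19.5).max() <= 1.0

    def test_tail_tip_reaches_rendered_tip(self, fast_rig, tracking_config):
        bend = 110.0
        frame = sr.render_fish_frame(bend, fast_rig)
        mask = tt.segment_fish(frame, tracking_config)
        path = tt.extract_centerline(mask, tracking_config.head_anchor)
        true_tip = sr.centerline_polyline(bend, fast_rig.body_length_px)[-1] + np.array(
            fast_rig.head_anchor_xy
        )
        assert np.linalg.norm(path[-1] - true_tip) <= 3.0

    def test_single_pixel_mask_fails(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[10, 10] = True
        assert tt.extract_centerline(mask, (0.0, 0.0)) is None

    def test_ring_mask_fails(self):
        mask = np.zeros((40, 40), dtype=bool)
        yy, xx = np.mgrid[:40, :40]
        r = np.hypot(yy - 20, xx - 20)
        mask[(r > 10) & (r < 14)] = True
        assert tt.extract_centerline(mask, (0.0, 0.0)) is None


class TestResampling:
    def test_straight_path_uniform_spacing(self):
        path = np.column_stack([np.arange(20.0), np.zeros(20)])  # length 19 px
        cl = tt.resample_centerline(path, 20)
        spacing = np.diff(cl.arc_length)
        assert np.allclose(spacing, 1.0, atol=0.01)

    def test_semicircle_equal_chords(self):
        theta = np.linspace(0, np.pi, 200)
        r = 30.0
        path = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        cl = tt.resample_centerline(path, 20)
        chords = np.linalg.norm(np.diff(cl.points, axis=0), axis=1)
        assert chords.max() / chords.min() - 1 < 0.01

    def test_two_points_are_endpoints(self):
        path = np.column_stack([np.arange(10.0), np.arange(10.0) * 0.5])
        cl = tt.resample_centerline(path, 2)
        assert np.allclose(cl.points[0], path[0], atol=0.5)
        assert np.allclose(cl.points[-1], path[-1], atol=0.5)

    def test_short_path_rejected(self):
        with pytest.raises(DegeneratePathError):
            tt.resample_centerline(np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]]), 20)


class TestTailAngle:
    def test_collinear_centerline_is_zero(self, tracking_config):
        pts = np.column_stack([np.linspace(0, 19, 20), np.zeros(20)])
        cl = tt.Centerline(points=pts, arc_length=np.linspace(0, 19, 20))
        assert tt.compute_tail_angle(cl, tracking_config) == pytest.approx(0.0, abs=1e-9)

    def test_constructed_sixty_degree_tail(self, tracking_config):
        pts = np.column_stack([np.linspace(0, 14, 15), np.zeros(15)])
        direction = np.array([np.cos(np.radians(60)), np.sin(np.radians(60))])
        tail = pts[-1] + np.outer(np.arange(1, 6), direction)
        cl_pts = np.vstack([pts, tail])
        cl = tt.Centerline(points=cl_pts, arc_length=np.arange(20.0))
        assert tt.compute_tail_angle(cl, tracking_config) == pytest.approx(60.0, abs=0.1)

    def test_coincident_tail_points_fail(self, tracking_config):
        pts = np.zeros((20, 2))
        pts[:15, 0] = np.arange(15)
        pts[15:] = pts[14]
        cl = tt.Centerline(points=pts, arc_length=np.arange(20.0))
        assert tt.compute_tail_angle(cl, tracking_config) is None

    @pytest.mark.parametrize("bend", [-150, -100, -45, 0, 45, 60, 100, 150])
    def test_scripted_bend_recovered_within_3_degrees(self, bend, fast_rig, tracking_config):
        frame = sr.render_fish_frame(float(bend), fast_rig)
        a = tt._angle_for_frame(frame, tracking_config, tracking_config.head_anchor)
        assert a == pytest.approx(bend, abs=3.0)

    def test_rendered_45_degree_bend(self, fast_rig, tracking_config):
        frame = sr.render_fish_frame(45.0, fast_rig)
        a = tt._angle_for_frame(frame, tracking_config, tracking_config.head_anchor)
        assert a == pytest.approx(45.0, abs=2.0)

    def test_rotation_equivariance_quarter_turn(self, fast_rig):
        # rotate frame and head axis together by 90 degrees: angle unchanged
        frame = sr.render_fish_frame(40.0, fast_rig)
        anchor = tt.HeadAnchor(xy=fast_rig.head_anchor_xy, axis=(1.0, 0.0))
        cfg = tt.TrackingConfig(head_anchor=anchor)
        a0 = tt._angle_for_frame(frame, cfg, anchor)
        h, w = frame.shape
        rot = np.rot90(frame, k=-1).copy()  # (x, y) -> (h-1-y, x)
        x, y = anchor.xy
        anchor_r = tt.HeadAnchor(xy=(h - 1 - y, x), axis=(0.0, 1.0))
        cfg_r = tt.TrackingConfig(head_anchor=anchor_r, reserved_rows=0)
        a1 = tt._angle_for_frame(rot, cfg_r, anchor_r)
        assert a1 == pytest.approx(a0, abs=1.0)


class TestTrialTracking:
    def test_noise_free_trial_rmse(self, tracked_trial):
        _, truth, trace = tracked_trial
        ok = ~np.isnan(trace.angles_deg)
        rmse = np.sqrt(np.mean((trace.angles_deg[ok] - truth.frame_angles_deg[ok]) ** 2))
        assert rmse <= 2.0

    def test_all_blank_stack_flagged(self):
        from startletrack.acquisition_io import FrameStack

        frames = np.zeros((30, 64, 64), dtype=np.uint8)
        stack = FrameStack(frames=frames, fps=640.0)
        trace = tt.track_trial(stack, tt.TrackingConfig(head_anchor=tt.HeadAnchor((5.0, 32.0))))
        assert trace.low_quality
        assert all(q == tt.QUALITY_FAILED for q in trace.quality)

    def test_constant_angle_fish_trace_is_flat(self, fast_rig):
        from startletrack.acquisition_io import FrameStack, encode_counter_row

        frame = sr.render_fish_frame(20.0, fast_rig)
        frames = np.repeat(frame[None], 40, axis=0).copy()
        for i in range(40):
            encode_counter_row(frames[i], i)
        stack = FrameStack(frames=frames, fps=640.0)
        trace = tt.track_trial(stack, tt.TrackingConfig())
        assert np.nanstd(trace.angles_deg) < 1.0

    def test_short_gap_interpolated(self, fast_rig):
        script = sr.KinematicScript(
            latency_ms=10.0, peak_angle_deg=90.0, time_to_peak_ms=5.0, relaxation_ms=20.0
        )
        cfg = sr.RigConfig(**{**fast_rig.__dict__, "n_stimuli": 1})
        stack, _ = sr.generate_trial(script, cfg, seed=0)
        stack.frames[20:22, cfg.reserved_rows :, :] = 0  # blank two frames mid-baseline
        trace = tt.track_trial(stack, tt.TrackingConfig())
        assert trace.quality[20] == tt.QUALITY_FALLBACK
        assert trace.quality[21] == tt.QUALITY_FALLBACK
        assert not np.isnan(trace.angles_deg[20:22]).any()

    def test_estimated_anchor_close_to_true(self, fast_rig):
        frame = sr.render_fish_frame(0.0, fast_rig)
        anchor = tt.estimate_head_anchor(frame, tt.TrackingConfig())
        assert anchor.xy[0] == pytest.approx(fast_rig.head_anchor_xy[0], abs=6)
        assert anchor.xy[1] == pytest.approx(fast_rig.head_anchor_xy[1], abs=3)
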