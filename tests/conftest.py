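import numpy as np
import pytest

from startletrack import synthetic_rig as sr
from startletrack import tail_tracking as tt

FPS = 640.0
PERIOD_MS = 1000.0 / FPS


@pytest.fixture(scope="session")
def fast_rig() -> sr.RigConfig:
    """Desk-scale rig: compressed inter-stimulus interval, no sensor noise."""
    return sr.RigConfig(
        isi_s=0.25,
        pre_stimulus_ms=80.0,
        post_window_ms=150.0,
        n_stimuli=2,
        sensor_noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def true_anchor(fast_rig) -> tt.HeadAnchor:
    return tt.HeadAnchor(xy=fast_rig.head_anchor_xy, axis=(1.0, 0.0))


@pytest.fixture(scope="session")
def tracking_config(true_anchor) -> tt.TrackingConfig:
    return tt.TrackingConfig(head_anchor=true_anchor)


@pytest.fixture(scope="session")
def tracked_trial(fast_rig):
    """One noise-free trial (two taps, 10 ms latency, 90-degree C-bend), tracked."""
    script = sr.KinematicScript(
        latency_ms=10.0, peak_angle_deg=90.0, time_to_peak_ms=5.0, relaxation_ms=20.0
    )
    stack, truth = sr.generate_trial(script, fast_rig, seed=42)
    trace = tt.track_trial(stack, tt.TrackingConfig())
    return stack, truth, trace
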