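from types import SimpleNamespace

import pytest
from hypothesis import HealthCheck, settings

from trialvr.proanti import TaskConfig, build_proanti_scene
from trialvr.recorder import FrameClock, SampleRecorder
from trialvr.simulate import ParticipantProfile, simulate_participant

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def noiseless_profile():
    """Fully deterministic participant: no gaze bias/noise, no jitter."""
    return ParticipantProfile(gaze_noise_sd_deg=0.0, gaze_bias_deg=0.0)


@pytest.fixture
def rig():
    """Factory assembling a complete simulated task rig.

    Returns config, clock, scene, device bundle, and a recorder with
    head + controller + eye tracker registered, so tests can run trials
    directly and still reach the simulator's ground-truth draws.
    """

    def make(profile=None, config=None, seed=0):
        config = config or TaskConfig()
        profile = profile or ParticipantProfile()
        clock = FrameClock(rate=config.frame_rate)
        scene = build_proanti_scene(config)
        devices = simulate_participant(profile, seed, config=config)
        recorder = SampleRecorder(scene, head_node="head")
        recorder.register_node("head", devices.head)
        recorder.register_node("controller", devices.controller)
        recorder.register_eye_tracker(devices.gaze)
        return SimpleNamespace(
            config=config,
            profile=profile,
            clock=clock,
            scene=scene,
            devices=devices,
            recorder=recorder,
        )

    return make
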