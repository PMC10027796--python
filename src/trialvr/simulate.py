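"""Seeded device simulators: HMD, reach controller, and eye tracker.

These stand-ins make every other module testable without hardware.  The
head is (optionally jittered) static at eye height facing +Z; the eye
tracker emits a cyclopean gaze ray toward its current fixation point,
perturbed by a constant angular bias and per-frame isotropic Gaussian
angular noise; the controller executes point-to-point reaches with a
minimum-jerk speed profile, triggered relative to the go cue with a
per-trial latency (which may be negative to emulate participants who
start before the cue).

All randomness flows from numpy Generators seeded at construction, so
the same seed yields byte-identical sample streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .geometry import Pose, normalize, vec3

__all__ = [
    "SimulationError",
    "minimum_jerk_fraction",
    "minimum_jerk_position",
    "MIN_JERK_PEAK_SPEED_FACTOR",
    "perturb_direction",
    "SimulatedHead",
    "SimulatedGaze",
    "SimulatedReach",
    "ParticipantProfile",
    "SimulatedParticipant",
    "simulate_participant",
]


class SimulationError(ValueError):
    """Invalid simulator configuration."""


#: peak path speed of a minimum-jerk reach is 1.875 * distance / duration
MIN_JERK_PEAK_SPEED_FACTOR = 1.875


def minimum_jerk_fraction(tau: float) -> float:
    """Displacement fraction 10*tau^3 - 15*tau^4 + 6*tau^5, tau clamped to [0, 1]."""
    t = min(max(tau, 0.0), 1.0)
    return t * t * t * (10.0 + t * (-15.0 + 6.0 * t))


def minimum_jerk_position(start, goal, t_since_onset: float, duration: float):
    """Point on a straight minimum-jerk path from start to goal.

    The quintic profile is the standard smooth-reach model: zero
    velocity and acceleration at both endpoints, bell-shaped speed with
    peak ``1.875 * |goal - start| / duration`` at the midpoint.
    """
    if duration <= 0:
        raise SimulationError("movement duration must be positive")
    start = vec3(start)
    goal = vec3(goal)
    return start + minimum_jerk_fraction(t_since_onset / duration) * (goal - start)


def perturb_direction(direction, h_deg: float, v_deg: float) -> np.ndarray:
    """Rotate a direction by yaw ``h_deg`` (right positive) and pitch
    ``v_deg`` (up positive).

    For directions near +Z the resulting angular offset from the
    original is ``sqrt(h^2 + v^2)`` to second order, which is the regime
    all simulated gaze operates in.
    """
    d = vec3(direction)
    if h_deg:
        h = math.radians(h_deg)
        ch, sh = math.cos(h), math.sin(h)
        d = np.array([ch * d[0] + sh * d[2], d[1], -sh * d[0] + ch * d[2]])
    if v_deg:
        v = math.radians(v_deg)
        cv, sv = math.cos(v), math.sin(v)
        # pitch up: +Z rotates toward +Y
        d = np.array([d[0], cv * d[1] + sv * d[2], -sv * d[1] + cv * d[2]])
    return d


class SimulatedHead:
    """Static HMD pose with optional per-frame positional jitter (m/axis)."""

    def __init__(self, base_pose: Pose, jitter_sd: float = 0.0, rng=None):
        self.base_pose = base_pose
        self.jitter_sd = float(jitter_sd)
        self.rng = rng if rng is not None else np.random.default_rng()

    def poll(self, clock) -> Pose:
        if self.jitter_sd <= 0.0:
            return self.base_pose
        offset = self.rng.normal(0.0, self.jitter_sd, size=3)
        return Pose(self.base_pose.position + offset, self.base_pose.quat)


class SimulatedGaze:
    """Eye tracker emitting a biased, noisy ray toward a fixation point.

    The emitted local gaze is the head-inverse-transformed ray from the
    cyclopean origin toward the current fixation point, rotated by the
    constant bias (deg) and then by per-frame Gaussian noise (deg/axis).
    Scripted ``(time, point)`` events re-target the fixation when due,
    emulating e.g. a participant glancing at the reach target.
    """

    def __init__(
        self,
        bias_h_deg: float = 0.0,
        bias_v_deg: float = 0.0,
        noise_sd_deg: float = 0.0,
        rng=None,
        fixation_point=None,
        scripted_events=None,
    ):
        self.bias_h_deg = float(bias_h_deg)
        self.bias_v_deg = float(bias_v_deg)
        self.noise_sd_deg = float(noise_sd_deg)
        self.rng = rng if rng is not None else np.random.default_rng()
        self.fixation_point = None if fixation_point is None else vec3(fixation_point)
        self.scripted_events = sorted(scripted_events or [], key=lambda e: e[0])

    def set_fixation(self, point) -> None:
        self.fixation_point = vec3(point)

    def schedule(self, time: float, point) -> None:
        self.scripted_events.append((float(time), vec3(point)))
        self.scripted_events.sort(key=lambda e: e[0])

    def poll_gaze(self, clock, head_pose: Pose):
        while self.scripted_events and self.scripted_events[0][0] <= clock.time:
            _, point = self.scripted_events.pop(0)
            self.fixation_point = vec3(point)
        if self.fixation_point is None:
            raise SimulationError("no fixation point set")
        world_dir = normalize(self.fixation_point - head_pose.position)
        local_dir = head_pose.inverse_transform_direction(world_dir)
        h, v = self.bias_h_deg, self.bias_v_deg
        if self.noise_sd_deg > 0.0:
            nh, nv = self.rng.normal(0.0, self.noise_sd_deg, size=2)
            h += nh
            v += nv
        if h or v:
            local_dir = perturb_direction(local_dir, h, v)
        return np.zeros(3), local_dir


class SimulatedReach:
    """Hand controller holding at a start position, then reaching a goal.

    The depth of the reach follows a minimum-jerk profile over the full
    movement duration, while the lateral (x, y) displacement completes
    over the first ``lateral_complete_fraction`` of it — reaches aimed
    at lateral goals finish their sideways motion before crossing the
    trial-ending depth threshold, so the recorded crossing position
    matches the movement goal.  Hold-phase positional jitter (m/axis) is
    applied only while stationary.
    """

    def __init__(
        self,
        start_position,
        hold_jitter_sd: float = 0.0,
        lateral_complete_fraction: float = 0.7,
        rng=None,
    ):
        if not (0.0 < lateral_complete_fraction <= 1.0):
            raise SimulationError("lateral_complete_fraction must be in (0, 1]")
        self.start_position = vec3(start_position)
        self.hold_jitter_sd = float(hold_jitter_sd)
        self.lateral_complete_fraction = float(lateral_complete_fraction)
        self.rng = rng if rng is not None else np.random.default_rng()
        self._reach: tuple[float, float, np.ndarray] | None = None

    def reset(self, start_position=None) -> None:
        if start_position is not None:
            self.start_position = vec3(start_position)
        self._reach = None

    def schedule_reach(self, onset_time: float, duration: float, goal) -> None:
        if duration <= 0:
            raise SimulationError("movement duration must be positive")
        self._reach = (float(onset_time), float(duration), vec3(goal))

    def position(self, t: float) -> np.ndarray:
        if self._reach is None or t < self._reach[0]:
            return self._jittered(self.start_position)
        onset, duration, goal = self._reach
        dt = t - onset
        if dt >= duration:
            return self._jittered(goal)
        delta = goal - self.start_position
        frac_z = minimum_jerk_fraction(dt / duration)
        frac_lat = minimum_jerk_fraction(
            dt / (duration * self.lateral_complete_fraction)
        )
        return self.start_position + np.array(
            [frac_lat * delta[0], frac_lat * delta[1], frac_z * delta[2]]
        )

    def _jittered(self, p: np.ndarray) -> np.ndarray:
        if self.hold_jitter_sd <= 0.0:
            return p
        return p + self.rng.normal(0.0, self.hold_jitter_sd, size=3)

    def poll(self, clock) -> Pose:
        return Pose(self.position(clock.time))


# ---------------------------------------------------------------------------
# Participant profiles and bundles
# ---------------------------------------------------------------------------


@dataclass
class ParticipantProfile:
    """Behavioral profile driving a simulated participant.

    ``mode`` selects the scripted behavior:

    * ``"compliant"`` — fixates as instructed, reaches after the go cue;
    * ``"early_start"`` — begins the reach before the go cue (negative
      onset latency), a typical participant mistake;
    * ``"gaze_to_target"`` — glances at the target at its onset instead
      of holding central fixation.

    Latencies and durations are drawn per trial from normal
    distributions (seconds); compliant latencies and all durations are
    truncated at zero (durations at a small positive floor).  Gaze bias
    magnitude defaults to a per-participant draw in [0.2, 0.7] degrees,
    matching accuracies typical of consumer VR eye trackers, with a
    random bias direction.
    """

    mode: str = "compliant"
    latency_mean_s: float = 0.45
    latency_sd_s: float = 0.08
    early_latency_mean_s: float = -0.2
    early_latency_sd_s: float = 0.05
    duration_mean_s: float = 0.5
    duration_sd_s: float = 0.1
    min_duration_s: float = 0.15
    gaze_noise_sd_deg: float = 0.3
    gaze_bias_deg: float | None = None  # None -> drawn uniformly in [0.2, 0.7]
    head_jitter_sd_m: float = 0.0
    hold_jitter_sd_m: float = 0.0
    lateral_complete_fraction: float = 0.7

    _MODES = ("compliant", "early_start", "gaze_to_target")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise SimulationError(
                f"unknown profile mode {self.mode!r}; expected one of {self._MODES}"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ParticipantProfile":
        return cls(**d)


@dataclass
class TrialDraw:
    """Per-trial ground-truth parameters drawn from the profile."""

    latency_s: float
    duration_s: float


class SimulatedParticipant:
    """Bundle of head/gaze/controller sources plus scripted behavior.

    The task drives the bundle through :meth:`begin_trial` and
    :meth:`notify` (stimulus events); the recorder polls the ``head``,
    ``controller``, and ``gaze`` attributes each frame.  Ground-truth
    per-trial draws are kept in ``draws`` for parameter-recovery tests.
    """

    def __init__(
        self,
        profile: ParticipantProfile,
        seed,
        eye_height: float = 1.60,
        controller_start=(0.0, 1.30, 0.05),
    ):
        self.profile = profile
        rng = np.random.default_rng(seed)
        bias = profile.gaze_bias_deg
        if bias is None:
            bias = rng.uniform(0.2, 0.7)
        theta = rng.uniform(0.0, 2.0 * math.pi)
        self.bias_deg = float(bias)
        self.head = SimulatedHead(
            Pose(vec3(0.0, eye_height, 0.0)),
            jitter_sd=profile.head_jitter_sd_m,
            rng=rng,
        )
        self.gaze = SimulatedGaze(
            bias_h_deg=bias * math.cos(theta),
            bias_v_deg=bias * math.sin(theta),
            noise_sd_deg=profile.gaze_noise_sd_deg,
            rng=rng,
        )
        self.controller = SimulatedReach(
            vec3(controller_start),
            hold_jitter_sd=profile.hold_jitter_sd_m,
            lateral_complete_fraction=profile.lateral_complete_fraction,
            rng=rng,
        )
        self._rng = rng
        self.draws: list[TrialDraw] = []

    def _draw_trial(self) -> TrialDraw:
        p = self.profile
        if p.mode == "early_start":
            latency = self._rng.normal(p.early_latency_mean_s, p.early_latency_sd_s)
        else:
            latency = max(
                0.0, self._rng.normal(p.latency_mean_s, p.latency_sd_s)
            )
        duration = max(
            p.min_duration_s, self._rng.normal(p.duration_mean_s, p.duration_sd_s)
        )
        return TrialDraw(latency_s=float(latency), duration_s=float(duration))

    def begin_trial(self, trial) -> None:
        self.draws.append(self._draw_trial())
        self.controller.reset()

    @property
    def current_draw(self) -> TrialDraw:
        if not self.draws:
            raise SimulationError("begin_trial has not been called")
        return self.draws[-1]

    def notify(self, label: str, time: float, payload: dict | None = None) -> None:
        """React to a task event (stimulus onsets, cue)."""
        payload = payload or {}
        if label == "fixation_on":
            self.gaze.set_fixation(payload["position"])
        elif label == "target_on":
            if self.profile.mode == "gaze_to_target":
                self.gaze.set_fixation(payload["position"])
        elif label == "cue_on":
            draw = self.current_draw
            self.controller.schedule_reach(
                onset_time=payload["go_time"] + draw.latency_s,
                duration=draw.duration_s,
                goal=payload["goal"],
            )


def simulate_participant(
    profile: ParticipantProfile,
    seed,
    config=None,
    eye_height: float = 1.60,
    controller_start=(0.0, 1.30, 0.05),
) -> SimulatedParticipant:
    """Build a device bundle; geometry defaults can come from a task config."""
    if config is not None:
        eye_height = getattr(config, "eye_height", eye_height)
        controller_start = getattr(config, "controller_start", controller_start)
    return SimulatedParticipant(
        profile, seed, eye_height=eye_height, controller_start=controller_start
    )
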