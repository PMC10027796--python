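"""Headless pro-/anti-reach example task.

In the pro-/anti-reach paradigm a participant reaches either toward a
visual target (pro) or to the mirrored location in the opposite
hemifield (anti), dissociating visual-target from motor-goal coding.
The trial sequence implemented here:

1. A white fixation sphere (5 cm diameter) appears straight ahead at
   50 cm depth, at the participant's eye height.  The participant must
   keep gaze on the sphere continuously for the fixation-hold duration
   (gaze checked per frame via the recorder's raycast; any miss resets
   the hold window).
2. The sphere recolors to cue the reach direction (blue = pro, red =
   anti) and a target cube of the same size appears for 1 s at +-30 cm
   lateral offset from the body midline, same depth and height.
3. Both stimuli disappear — this offset is the go cue.  Controller
   visibility during the reach is set by the trial's feedback factor
   (recorded per sample from trial start).
4. The trial ends at the first frame where the controller's depth (Z)
   coordinate reaches the 45 cm proximity threshold.

Every stimulus onset/offset and the threshold crossing is logged as an
event; an invisible fronto-parallel plane at target depth is the only
raycast-enabled object during the reach, so recorded gaze intersections
always lie in the target plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .design import (
    DesignSpec,
    ExperimentSession,
    ParamSet,
    TrialRecord,
    make_factorial_design,
    randomize_trials,
    run_experiment,
)
from .geometry import Box, RectPlane, Sphere, vec3
from .recorder import FrameClock, SampleRecorder, Scene
from .simulate import ParticipantProfile, simulate_participant
from .validation import make_cross_layout, run_validation

__all__ = [
    "TaskError",
    "TaskConfig",
    "TRIAL_PHASES",
    "FIXATION_ID",
    "TARGET_ID",
    "PLANE_ID",
    "build_proanti_design",
    "build_proanti_scene",
    "run_proanti_trial",
    "run_proanti_session",
]


class TaskError(RuntimeError):
    """A trial could not complete (fixation or response timeout)."""


FIXATION_ID = "fixation"
TARGET_ID = "target"
PLANE_ID = "gaze_plane"

#: phase order traversed exactly once per trial
TRIAL_PHASES = ("await_start", "fixation", "cue_and_target", "response", "done")


@dataclass
class TaskConfig:
    """Stimulus geometry and timing of the example task (meters/seconds)."""

    fixation_diameter: float = 0.05
    stimulus_depth: float = 0.5
    target_lateral_offset: float = 0.30
    proximity_threshold_z: float = 0.45
    fixation_hold: float = 1.0
    target_duration: float = 1.0
    repetitions: int = 10
    eye_height: float = 1.60
    controller_start: tuple = (0.0, 1.30, 0.05)
    fixation_timeout: float = 10.0
    response_timeout: float = 5.0
    frame_rate: float = 90.0
    gaze_plane_size: float = 1.2
    validation_eccentricity_deg: float = 5.0
    continue_on_error: bool = False
    cue_colors: dict = field(
        default_factory=lambda: {"pro": "blue", "anti": "red", "neutral": "white"}
    )

    def __post_init__(self) -> None:
        for name in (
            "fixation_diameter",
            "stimulus_depth",
            "target_lateral_offset",
            "proximity_threshold_z",
            "fixation_hold",
            "target_duration",
            "fixation_timeout",
            "response_timeout",
            "frame_rate",
            "gaze_plane_size",
        ):
            if getattr(self, name) <= 0:
                raise TaskError(f"TaskConfig.{name} must be positive")
        if self.repetitions < 1:
            raise TaskError("repetitions must be >= 1")

    def to_paramset(self) -> ParamSet:
        ps = ParamSet()
        for key, value in self.__dict__.items():
            if key == "controller_start":
                ps["controller_start_x"] = float(value[0])
                ps["controller_start_y"] = float(value[1])
                ps["controller_start_z"] = float(value[2])
            elif key == "cue_colors":
                ps["cue_colors"] = dict(value)
            else:
                ps[key] = value
        return ps

    @classmethod
    def from_dict(cls, overrides: dict) -> "TaskConfig":
        """Build a config from a (possibly partial) plain-dict override."""
        d = dict(overrides)
        kwargs = {}
        if {"controller_start_x", "controller_start_y", "controller_start_z"} <= d.keys():
            kwargs["controller_start"] = (
                d.pop("controller_start_x"),
                d.pop("controller_start_y"),
                d.pop("controller_start_z"),
            )
        elif "controller_start" in d:
            kwargs["controller_start"] = tuple(d.pop("controller_start"))
        valid = {f for f in cls.__dataclass_fields__}
        for key, value in d.items():
            if key not in valid:
                raise TaskError(f"unknown TaskConfig field {key!r}")
            kwargs[key] = value
        return cls(**kwargs)


def build_proanti_design(config: TaskConfig | None = None, seed=0) -> list[TrialRecord]:
    """Randomized 2 (side) x 2 (cue) x 2 (feedback) design.

    Derived per-trial params: ``target_x`` is the signed lateral target
    position and ``goal_x`` the correct reach endpoint — equal to
    ``target_x`` for pro cues and mirrored for anti cues.
    """
    config = config or TaskConfig()
    spec = DesignSpec(
        factors={
            "target_side": ["left", "right"],
            "cue": ["pro", "anti"],
            "feedback": ["visible", "hidden"],
        },
        repetitions=config.repetitions,
    )
    trials = make_factorial_design(spec)
    for t in trials:
        sign = -1.0 if t.params["target_side"] == "left" else 1.0
        target_x = sign * config.target_lateral_offset
        t.params["target_x"] = target_x
        t.params["goal_x"] = target_x if t.params["cue"] == "pro" else -target_x
    return randomize_trials(trials, seed)


def build_proanti_scene(config: TaskConfig | None = None) -> Scene:
    """Fixation sphere, target cube, and the invisible gaze-recording plane.

    Only the plane is raycast-enabled by default; the fixation sphere is
    made pickable during the fixation-acquisition phase of each trial.
    """
    config = config or TaskConfig()
    eh = config.eye_height
    depth = config.stimulus_depth
    half = config.fixation_diameter / 2.0
    scene = Scene()
    scene.add(
        RectPlane(
            PLANE_ID,
            center=vec3(0.0, eh, depth),
            normal=vec3(0.0, 0.0, -1.0),
            width=config.gaze_plane_size,
            height=config.gaze_plane_size,
            visible=False,
            pickable=True,
        )
    )
    scene.add(
        Sphere(
            FIXATION_ID,
            center=vec3(0.0, eh, depth),
            radius=half,
            visible=False,
            pickable=False,
            color="white",
        )
    )
    scene.add(
        Box(
            TARGET_ID,
            center=vec3(0.0, eh, depth),
            half_extents=vec3(half, half, half),
            visible=False,
            pickable=False,
            color="white",
        )
    )
    return scene


def run_proanti_trial(
    trial: TrialRecord,
    devices,
    recorder: SampleRecorder,
    scene: Scene,
    clock: FrameClock,
    config: TaskConfig | None = None,
) -> TrialRecord:
    """Run one trial through the phase machine, recording every frame.

    ``devices`` must provide ``begin_trial(trial)`` and
    ``notify(label, time, payload)`` plus pollable sources already
    registered with the recorder (a :class:`SimulatedParticipant`
    satisfies this).  Results (end time/position, condition echo) are
    stored in ``trial.results``; raises :class:`TaskError` if fixation
    is never attained or the threshold is never crossed within the
    configured timeouts.
    """
    config = config or TaskConfig()
    p = trial.params
    eh = config.eye_height
    depth = config.stimulus_depth
    fixation_pos = vec3(0.0, eh, depth)
    target_pos = vec3(p["target_x"], eh, depth)
    goal_pos = vec3(p["goal_x"], eh, depth)
    controller_visible = p["feedback"] == "visible"

    if trial.status == "pending":  # direct use outside run_experiment
        trial.start()
    devices.begin_trial(trial)
    recorder.start_trial(trial)
    recorder.state["controller_visible"] = controller_visible
    phase_times = {}
    try:
        # -- await_start: simulated inter-trial confirmation ------------------
        phase_times["await_start"] = clock.time
        recorder.log_event(
            "trial_start_confirmed", clock, {"controller_visible": controller_visible}
        )

        # -- fixation ---------------------------------------------------------
        phase_times["fixation"] = clock.time
        scene.set_group_state([TARGET_ID], visible=False, pickable=False)
        scene.set_group_state(
            [FIXATION_ID],
            visible=True,
            pickable=True,
            position=fixation_pos,
            color=config.cue_colors["neutral"],
        )
        recorder.log_event("fixation_on", clock)
        devices.notify("fixation_on", clock.time, {"position": fixation_pos})
        window_start = None
        acquired = None
        fixation_t0 = clock.time
        while clock.time - fixation_t0 <= config.fixation_timeout:
            sample = recorder.record_frame(clock)
            _, hit_id, _ = recorder.current_gaze()
            if hit_id == FIXATION_ID:
                if window_start is None:
                    window_start = sample.time
                if sample.time - window_start >= config.fixation_hold - 1e-9:
                    acquired = sample.time
                    recorder.log_event("fixation_acquired", clock)
                    clock.tick()
                    break
            else:
                window_start = None
            clock.tick()
        if acquired is None:
            raise TaskError(
                f"fixation not attained within {config.fixation_timeout} s"
            )

        # -- cue + target -----------------------------------------------------
        phase_times["cue_and_target"] = clock.time
        cue_color = config.cue_colors[p["cue"]]
        # gaze recording is restricted to the plane from here on
        scene.set_group_state([FIXATION_ID], pickable=False, color=cue_color)
        scene.set_group_state([TARGET_ID], visible=True, position=target_pos)
        cue_time = clock.time
        go_time = cue_time + config.target_duration
        recorder.log_event("cue_on", clock, {"cue": p["cue"], "color": cue_color})
        recorder.log_event("target_on", clock, {"x": float(target_pos[0])})
        devices.notify("target_on", cue_time, {"position": target_pos})
        devices.notify("cue_on", cue_time, {"go_time": go_time, "goal": goal_pos})
        for _ in range(clock.frames(config.target_duration)):
            recorder.record_frame(clock)
            clock.tick()

        # -- go cue -----------------------------------------------------------
        scene.set_group_state([FIXATION_ID, TARGET_ID], visible=False)
        recorder.log_event("go_cue", clock, {"controller_visible": controller_visible})
        devices.notify("go_cue", clock.time, {})

        # -- response: wait for the depth-threshold crossing -------------------
        phase_times["response"] = clock.time
        response_t0 = clock.time
        crossing = None
        while clock.time - response_t0 <= config.response_timeout:
            sample = recorder.record_frame(clock)
            pose = sample.nodes.get("controller")
            if (
                pose is not None
                and float(pose.position[2]) >= config.proximity_threshold_z
            ):
                crossing = sample
                recorder.log_event(
                    "threshold_crossed",
                    clock,
                    {
                        "x": float(pose.position[0]),
                        "y": float(pose.position[1]),
                        "z": float(pose.position[2]),
                    },
                )
                break
            clock.tick()
        if crossing is None:
            raise TaskError(
                f"controller never crossed z={config.proximity_threshold_z} m"
            )
        phase_times["done"] = clock.time

        end_pose = crossing.nodes["controller"]
        trial.results.update(
            {
                "end_time": crossing.time,
                "end_x": float(end_pose.position[0]),
                "end_y": float(end_pose.position[1]),
                "end_z": float(end_pose.position[2]),
                "cue_time": cue_time,
                "go_time": go_time,
                "fixation_acquired_time": acquired,
                "cue": p["cue"],
                "target_side": p["target_side"],
                "feedback": p["feedback"],
                "target_x": p["target_x"],
                "goal_x": p["goal_x"],
            }
        )
        clock.tick()
        return trial
    finally:
        recorder.stop_trial()
        recorder.state.pop("controller_visible", None)


def run_proanti_session(
    config: TaskConfig | None = None,
    profile: ParticipantProfile | None = None,
    seed: int = 0,
    participant: str = "P01",
    validate: bool = True,
    clock: FrameClock | None = None,
) -> ExperimentSession:
    """Full simulated session: validation (optional) plus all trials.

    All randomness — design order, per-trial latencies/durations, gaze
    noise, per-participant bias — derives from ``seed``.  Session
    timestamps come from the simulated clock, so identical seeds yield
    identical sessions.
    """
    config = config or TaskConfig()
    profile = profile or ParticipantProfile()
    clock = clock or FrameClock(rate=config.frame_rate)

    import numpy as np

    design_seed, device_seed = np.random.SeedSequence(seed).spawn(2)
    trials = build_proanti_design(config, seed=design_seed)
    scene = build_proanti_scene(config)
    devices = simulate_participant(profile, device_seed, config=config)

    session = ExperimentSession(
        metadata=ParamSet(
            participant=participant,
            seed=int(seed),
            profile_mode=profile.mode,
            gaze_bias_deg=devices.bias_deg,
        ),
        config=config.to_paramset(),
    )
    session.add_trials(trials)

    recorder = SampleRecorder(scene, head_node="head")
    recorder.register_node("head", devices.head)
    recorder.register_node("controller", devices.controller)
    recorder.register_eye_tracker(devices.gaze)

    if validate:
        targets = make_cross_layout(
            config.validation_eccentricity_deg,
            config.stimulus_depth,
            origin=devices.head.base_pose,
        )
        run_validation(
            recorder,
            targets,
            clock,
            session=session,
            present=lambda t: devices.gaze.set_fixation(t.world_position),
        )

    run_experiment(
        session,
        main_task=lambda trial: run_proanti_trial(
            trial, devices, recorder, scene, clock, config
        ),
        clock=clock,
        continue_on_error=config.continue_on_error,
    )
    return session
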