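"""Frame-locked recording of tracked-node poses, gaze, and events.

One :class:`Sample` is taken per simulated display refresh (default
90 Hz).  If an eye tracker is registered, the tracker-frame gaze ray is
converted to world space using the head pose, raycast against all
pickable scene objects, and the closest hit (object id and 3D point) is
stored with the sample.  Recording is strictly frame-locked: each source
is polled exactly once per clock tick, accepting the fidelity limits of
display-synced sampling.

Missing or failing sources never abort a recording: the affected fields
are simply stored as invalid (``None`` in memory, empty cells in CSV,
nulls in JSON).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ParamSet
from .geometry import (
    Pose,
    Ray,
    ScenePrimitive,
    closest_intersection,
    vec3,
)

__all__ = [
    "RecorderError",
    "SceneError",
    "FrameClock",
    "EventRecord",
    "GazeData",
    "Sample",
    "Scene",
    "SampleRecorder",
    "export_samples_csv",
    "read_samples_csv",
]


class RecorderError(RuntimeError):
    """Recorder misuse: duplicate node ids, queries before any frame."""


class SceneError(KeyError):
    """Unknown scene object id."""


@dataclass
class FrameClock:
    """Simulated display clock: ``time = frame / rate`` seconds."""

    rate: float = 90.0
    frame: int = 0

    @property
    def time(self) -> float:
        return self.frame / self.rate

    def tick(self, n: int = 1) -> None:
        if n < 0:
            raise ValueError("the clock is monotone; cannot tick backwards")
        self.frame += n

    def frames(self, duration_s: float) -> int:
        """Number of whole frames covering ``duration_s`` seconds."""
        return int(round(duration_s * self.rate))


@dataclass
class EventRecord:
    """Timestamped marker (stimulus onsets/offsets, threshold crossings)."""

    time: float
    frame: int
    label: str
    payload: ParamSet | None = None

    def to_dict(self) -> dict:
        return {
            "time": self.time,
            "frame": self.frame,
            "label": self.label,
            "payload": self.payload.to_dict() if self.payload is not None else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EventRecord":
        payload = d.get("payload")
        return cls(
            time=d["time"],
            frame=d["frame"],
            label=d["label"],
            payload=ParamSet(payload) if payload is not None else None,
        )


@dataclass(eq=False)
class GazeData:
    """Gaze ray in tracker and world frames, plus the raycast result.

    A single combined ("cyclopean") ray from the midpoint between the
    eyes is used; ``hit_object``/``hit_point`` are present iff a pickable
    object was hit.
    """

    local_origin: np.ndarray
    local_dir: np.ndarray
    world_origin: np.ndarray
    world_dir: np.ndarray
    hit_object: str | None = None
    hit_point: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "local_origin": self.local_origin.tolist(),
            "local_dir": self.local_dir.tolist(),
            "world_origin": self.world_origin.tolist(),
            "world_dir": self.world_dir.tolist(),
            "hit_object": self.hit_object,
            "hit_point": None if self.hit_point is None else self.hit_point.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GazeData":
        hp = d.get("hit_point")
        return cls(
            local_origin=vec3(d["local_origin"]),
            local_dir=vec3(d["local_dir"]),
            world_origin=vec3(d["world_origin"]),
            world_dir=vec3(d["world_dir"]),
            hit_object=d.get("hit_object"),
            hit_point=None if hp is None else vec3(hp),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, GazeData):
            return NotImplemented
        return self.to_dict() == other.to_dict()


@dataclass(eq=False)
class Sample:
    """One frame of continuous data.

    ``nodes`` maps node id to its :class:`~trialvr.geometry.Pose`, or
    ``None`` if the source failed that frame; ``gaze`` is ``None`` when
    no eye tracker is registered or the tracker failed.  ``state``
    carries per-frame bookkeeping flags (e.g. controller visibility).
    """

    time: float
    frame: int
    nodes: dict = field(default_factory=dict)
    gaze: GazeData | None = None
    state: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "time": self.time,
            "frame": self.frame,
            "nodes": {
                k: (None if p is None else p.to_dict()) for k, p in self.nodes.items()
            },
            "gaze": None if self.gaze is None else self.gaze.to_dict(),
            "state": dict(self.state),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Sample":
        return cls(
            time=d["time"],
            frame=d["frame"],
            nodes={
                k: (None if p is None else Pose.from_dict(p))
                for k, p in d["nodes"].items()
            },
            gaze=None if d.get("gaze") is None else GazeData.from_dict(d["gaze"]),
            state=dict(d.get("state", {})),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, Sample):
            return NotImplemented
        return self.to_dict() == other.to_dict()


class Scene:
    """Registry of scene primitives with grouped state changes.

    Analogous to an object-collection/tag system: show, hide, move, or
    rescale several objects with one call.  Visibility and pickability
    are independent; hiding an object does not remove it from raycasts
    unless ``pickable=False`` is also set.
    """

    def __init__(self, prims=()):
        self._prims: dict[str, ScenePrimitive] = {}
        for p in prims:
            self.add(p)

    def add(self, prim: ScenePrimitive) -> ScenePrimitive:
        if prim.id in self._prims:
            raise SceneError(f"duplicate scene object id {prim.id!r}")
        self._prims[prim.id] = prim
        return prim

    def __getitem__(self, prim_id: str) -> ScenePrimitive:
        try:
            return self._prims[prim_id]
        except KeyError:
            raise SceneError(f"unknown scene object id {prim_id!r}") from None

    def __contains__(self, prim_id: str) -> bool:
        return prim_id in self._prims

    @property
    def prims(self) -> list[ScenePrimitive]:
        """All primitives in registration order."""
        return list(self._prims.values())

    def pickable(self) -> list[ScenePrimitive]:
        return [p for p in self._prims.values() if p.pickable]

    def set_group_state(
        self,
        ids,
        visible: bool | None = None,
        pickable: bool | None = None,
        position=None,
        scale: float | None = None,
        color: str | None = None,
    ) -> None:
        prims = [self[i] for i in ids]  # resolve all first: unknown id -> error
        for p in prims:
            if visible is not None:
                p.visible = visible
            if pickable is not None:
                p.pickable = pickable
            if position is not None:
                p.center = vec3(position)
            if scale is not None:
                p.rescale(scale)
            if color is not None:
                p.color = color


class SampleRecorder:
    """Polls registered sources once per frame and buffers Samples.

    Samples go to the current trial's buffer when a trial is attached
    via :meth:`start_trial`, otherwise to the recorder's own ``samples``
    list (used e.g. during eye-tracker validation).  The most recent
    gaze state is exposed through :meth:`current_gaze` for immediate
    fixation checks without re-polling.
    """

    def __init__(self, scene: Scene | None = None, head_node: str = "head"):
        self.scene = scene
        self.head_node = head_node
        self._sources: dict[str, object] = {}
        self._eye = None
        self.state: dict = {}
        self.samples: list[Sample] = []
        self.events: list[EventRecord] = []
        self._trial = None
        self._last: Sample | None = None

    # -- registration ---------------------------------------------------------
    def register_node(self, node_id: str, source) -> None:
        if node_id in self._sources:
            raise RecorderError(f"node id {node_id!r} already registered")
        self._sources[node_id] = source
        return None

    def register_eye_tracker(self, source) -> None:
        if self._eye is not None:
            raise RecorderError("an eye tracker is already registered")
        self._eye = source

    @property
    def has_eye_tracker(self) -> bool:
        return self._eye is not None

    @property
    def node_ids(self) -> list[str]:
        return list(self._sources)

    # -- trial attachment -----------------------------------------------------
    def start_trial(self, trial) -> None:
        self._trial = trial

    def stop_trial(self) -> None:
        self._trial = None

    def _buffer(self) -> list:
        return self._trial.samples if self._trial is not None else self.samples

    # -- recording ------------------------------------------------------------
    @staticmethod
    def _poll(source, *args):
        poll = getattr(source, "poll", None)
        if poll is not None:
            return poll(*args)
        return source(*args)

    def record_frame(self, clock: FrameClock) -> Sample:
        """Poll every source once and append a Sample for this frame.

        A failing source marks its fields invalid for this frame;
        recording never aborts mid-trial.
        """
        nodes: dict[str, Pose | None] = {}
        for nid, src in self._sources.items():
            try:
                nodes[nid] = self._poll(src, clock)
            except Exception:
                nodes[nid] = None
        gaze = None
        head = nodes.get(self.head_node)
        if self._eye is not None and head is not None:
            try:
                poll = getattr(self._eye, "poll_gaze", self._eye)
                local_origin, local_dir = poll(clock, head)
                local_origin = vec3(local_origin)
                world_origin = head.transform_point(local_origin)
                world_dir = head.transform_direction(local_dir)
                hit_id, hit_point = None, None
                if self.scene is not None:
                    hit = closest_intersection(
                        Ray(world_origin, world_dir), self.scene.prims
                    )
                    if hit is not None:
                        hit_id, _, hit_point = hit
                gaze = GazeData(
                    local_origin=local_origin,
                    local_dir=vec3(local_dir),
                    world_origin=world_origin,
                    world_dir=world_dir,
                    hit_object=hit_id,
                    hit_point=hit_point,
                )
            except Exception:
                gaze = None
        sample = Sample(
            time=clock.time,
            frame=clock.frame,
            nodes=nodes,
            gaze=gaze,
            state=dict(self.state),
        )
        self._buffer().append(sample)
        self._last = sample
        return sample

    def current_gaze(self) -> tuple[Ray | None, str | None, np.ndarray | None]:
        """Most recent world gaze ray, hit object id, and hit point.

        Returns the last computed values without re-polling; stable
        within a frame.  Raises if no frame has been recorded yet.
        """
        if self._last is None:
            raise RecorderError("no frames recorded yet")
        g = self._last.gaze
        if g is None:
            return None, None, None
        return Ray(g.world_origin, g.world_dir), g.hit_object, g.hit_point

    def log_event(self, label: str, clock: FrameClock, payload=None) -> EventRecord:
        ev = EventRecord(
            time=clock.time,
            frame=clock.frame,
            label=label,
            payload=ParamSet(payload) if payload is not None else None,
        )
        (self._trial.events if self._trial is not None else self.events).append(ev)
        return ev


# ---------------------------------------------------------------------------
# Sample CSV export
# ---------------------------------------------------------------------------

_GAZE_COLUMNS = (
    ["gaze_local_origin_" + a for a in "xyz"]
    + ["gaze_local_dir_" + a for a in "xyz"]
    + ["gaze_world_origin_" + a for a in "xyz"]
    + ["gaze_world_dir_" + a for a in "xyz"]
    + ["gaze_hit_object"]
    + ["gaze_hit_" + a for a in "xyz"]
)


def _gather(session_or_trial) -> list[tuple]:
    """Yield (trial_number, sample) pairs from a session, trial, or list."""
    trials = getattr(session_or_trial, "trials", None)
    if trials is not None:
        return [(t.number, s) for t in trials for s in t.samples]
    samples = getattr(session_or_trial, "samples", session_or_trial)
    number = getattr(session_or_trial, "number", None)
    return [(number, s) for s in samples]


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def export_samples_csv(session_or_trial, path) -> None:
    """One row per sample, in a fixed documented column order.

    Columns: time, frame, trial_number; then per registered node
    (first-seen order) position x/y/z and yaw/pitch/roll degrees; then
    the gaze block (local and world origin/direction, hit object, hit
    point); then any per-frame state flags.  Invalid fields are written
    as empty cells.  Columns for nodes that never appear are omitted.
    """
    import csv

    pairs = _gather(session_or_trial)
    node_order: list[str] = []
    state_keys: list[str] = []
    any_gaze = False
    for _, s in pairs:
        for nid in s.nodes:
            if nid not in node_order:
                node_order.append(nid)
        for k in s.state:
            if k not in state_keys:
                state_keys.append(k)
        any_gaze = any_gaze or s.gaze is not None
    header = ["time", "frame", "trial_number"]
    for nid in node_order:
        header += [f"{nid}_pos_{a}" for a in "xyz"]
        header += [f"{nid}_{a}" for a in ("yaw", "pitch", "roll")]
    if any_gaze:
        header += _GAZE_COLUMNS
    header += state_keys
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for number, s in pairs:
            row = [_fmt(s.time), _fmt(s.frame), _fmt(number)]
            for nid in node_order:
                pose = s.nodes.get(nid)
                if pose is None:
                    row += [""] * 6
                else:
                    row += [_fmt(float(v)) for v in pose.position]
                    row += [_fmt(v) for v in pose.euler_ypr()]
            if any_gaze:
                g = s.gaze
                if g is None:
                    row += [""] * len(_GAZE_COLUMNS)
                else:
                    for vecs in (g.local_origin, g.local_dir, g.world_origin, g.world_dir):
                        row += [_fmt(float(v)) for v in vecs]
                    row.append(_fmt(g.hit_object))
                    if g.hit_point is None:
                        row += [""] * 3
                    else:
                        row += [_fmt(float(v)) for v in g.hit_point]
            row += [_fmt(s.state.get(k)) for k in state_keys]
            writer.writerow(row)


def read_samples_csv(path) -> pd.DataFrame:
    """Load an exported sample CSV into a DataFrame (empty cells -> NaN)."""
    return pd.read_csv(path)
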