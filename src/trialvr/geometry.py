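"""3D math shared by the recorder, validation, and task modules.

Coordinate frame
----------------
X points right, Y points up, and Z points forward, *away* from the
participant; units are meters throughout and the frame is right-handed.
Lateral target offsets are therefore signed X values and "depth" is Z.
Orientations are stored as unit quaternions (scalar-last, ``[x, y, z, w]``)
and can be exported as yaw(Y)-pitch(X)-roll(Z) Euler angles in degrees,
the order typically shown by tracked-device debug displays.

The module provides poses (rigid transforms), rays, analytic ray
intersections with the scene primitives used by the gaze raycaster
(spheres, oriented boxes, bounded rectangular planes), and angular
distance between direction vectors, the basic measure behind all
eye-tracking accuracy metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "GeometryError",
    "Vec3Like",
    "vec3",
    "normalize",
    "Pose",
    "Ray",
    "ScenePrimitive",
    "Sphere",
    "Box",
    "RectPlane",
    "intersect",
    "closest_intersection",
    "angular_distance",
]

#: tolerance used for unit-length checks and surface residuals (meters)
TOL = 1e-9

Vec3Like = "np.ndarray | tuple[float, float, float] | list[float]"


class GeometryError(ValueError):
    """Degenerate geometric input: zero vectors, non-unit quaternions, etc."""


def vec3(x, y: float | None = None, z: float | None = None) -> np.ndarray:
    """Coerce input to a finite float vector of shape (3,).

    Accepts either three scalars or a single length-3 sequence/array.
    """
    if y is None:
        a = np.asarray(x, dtype=float).reshape(3).copy()
    else:
        a = np.array([x, y, z], dtype=float)
    if not np.all(np.isfinite(a)):
        raise GeometryError(f"non-finite vector components: {a!r}")
    return a


def normalize(v) -> np.ndarray:
    """Return ``v / |v|``; raise :class:`GeometryError` for zero vectors."""
    v = np.asarray(v, dtype=float)
    n = float(np.linalg.norm(v))
    if n == 0.0 or not np.isfinite(n):
        raise GeometryError("cannot normalize a zero-length vector")
    return v / n


@dataclass(frozen=True, eq=False)
class Pose:
    """Rigid transform: a 3D position (m) plus an orientation quaternion.

    ``quat`` is scalar-last ``[x, y, z, w]`` and must be unit length to
    within 1e-6 (checked; stored as given so that serialization round
    trips are bit-exact).
    """

    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    quat: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", vec3(self.position))
        q = np.asarray(self.quat, dtype=float).reshape(4).copy()
        n = float(np.linalg.norm(q))
        if abs(n - 1.0) > 1e-6:
            raise GeometryError(f"quaternion norm {n} is not 1")
        object.__setattr__(self, "quat", q)

    # -- construction helpers -------------------------------------------------
    @classmethod
    def identity(cls) -> "Pose":
        return cls()

    @classmethod
    def from_euler(
        cls,
        position: Vec3Like = (0.0, 0.0, 0.0),
        yaw: float = 0.0,
        pitch: float = 0.0,
        roll: float = 0.0,
    ) -> "Pose":
        """Build a pose from yaw(Y)/pitch(X)/roll(Z) angles in degrees."""
        rot = Rotation.from_euler("YXZ", [yaw, pitch, roll], degrees=True)
        return cls(vec3(position), rot.as_quat())

    # -- cached rotation objects ----------------------------------------------
    @property
    def rotation(self) -> Rotation:
        rot = self.__dict__.get("_rot")
        if rot is None:
            rot = Rotation.from_quat(self.quat)
            object.__setattr__(self, "_rot", rot)
        return rot

    @property
    def rotation_inv(self) -> Rotation:
        inv = self.__dict__.get("_rot_inv")
        if inv is None:
            inv = self.rotation.inv()
            object.__setattr__(self, "_rot_inv", inv)
        return inv

    def euler_ypr(self) -> tuple[float, float, float]:
        """Orientation as (yaw, pitch, roll) degrees, YXZ order."""
        y, p, r = self.rotation.as_euler("YXZ", degrees=True)
        return float(y), float(p), float(r)

    # -- transforms -----------------------------------------------------------
    def transform_point(self, local: Vec3Like) -> np.ndarray:
        """Local point to world: rotate, then translate."""
        return self.rotation.apply(vec3(local)) + self.position

    def transform_direction(self, local: Vec3Like) -> np.ndarray:
        """Local direction to world: rotate only, renormalized."""
        return normalize(self.rotation.apply(vec3(local)))

    def inverse_transform_point(self, world: Vec3Like) -> np.ndarray:
        return self.rotation_inv.apply(vec3(world) - self.position)

    def inverse_transform_direction(self, world: Vec3Like) -> np.ndarray:
        return normalize(self.rotation_inv.apply(vec3(world)))

    # -- serialization / equality ---------------------------------------------
    def to_dict(self) -> dict:
        return {"pos": self.position.tolist(), "quat": self.quat.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Pose":
        return cls(vec3(d["pos"]), np.asarray(d["quat"], dtype=float))

    def __eq__(self, other) -> bool:
        if not isinstance(other, Pose):
            return NotImplemented
        return np.array_equal(self.position, other.position) and np.array_equal(
            self.quat, other.quat
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        y, p, r = self.euler_ypr()
        return (
            f"Pose(position={self.position.round(6).tolist()}, "
            f"ypr_deg=({y:.3f}, {p:.3f}, {r:.3f}))"
        )


@dataclass(frozen=True, eq=False)
class Ray:
    """Half-line from ``origin`` along unit ``direction``."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", vec3(self.origin))
        object.__setattr__(self, "direction", normalize(self.direction))

    def point_at(self, t: float) -> np.ndarray:
        return self.origin + t * self.direction


# ---------------------------------------------------------------------------
# Scene primitives
# ---------------------------------------------------------------------------


@dataclass
class ScenePrimitive:
    """Base scene object.

    ``visible`` and ``pickable`` are independent flags: an invisible
    object can still participate in gaze raycasts (the task uses exactly
    this for its invisible gaze-recording plane) and vice versa.
    """

    id: str
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    visible: bool = True
    pickable: bool = True
    color: str | None = None

    def __post_init__(self) -> None:
        self.center = vec3(self.center)

    def rescale(self, factor: float) -> None:
        raise NotImplementedError


@dataclass
class Sphere(ScenePrimitive):
    radius: float = 0.025

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.radius <= 0:
            raise GeometryError("sphere radius must be positive")

    def rescale(self, factor: float) -> None:
        self.radius *= factor


@dataclass
class Box(ScenePrimitive):
    """Oriented box given by center, half extents and a rotation."""

    half_extents: np.ndarray = field(default_factory=lambda: np.full(3, 0.025))
    quat: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        super().__post_init__()
        self.half_extents = vec3(self.half_extents)
        if np.any(self.half_extents <= 0):
            raise GeometryError("box half extents must be positive")
        self.quat = np.asarray(self.quat, dtype=float).reshape(4)

    @property
    def pose(self) -> Pose:
        return Pose(self.center, self.quat)

    def rescale(self, factor: float) -> None:
        self.half_extents = self.half_extents * factor


@dataclass
class RectPlane(ScenePrimitive):
    """Bounded rectangle: center, outward normal, width (m) and height (m).

    The in-plane width axis is chosen perpendicular to the world up
    vector (or to +Z when the normal is near-vertical), so a plane with
    normal -Z has its width along X and height along Y, matching the
    fronto-parallel gaze-recording plane of the reaching task.
    """

    normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, -1.0]))
    width: float = 1.0
    height: float = 1.0

    def __post_init__(self) -> None:
        super().__post_init__()
        self.normal = normalize(self.normal)
        if self.width <= 0 or self.height <= 0:
            raise GeometryError("plane extents must be positive")

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        """Unit in-plane (width, height) axes."""
        ref = np.array([0.0, 1.0, 0.0])
        if abs(float(np.dot(ref, self.normal))) > 0.9:
            ref = np.array([0.0, 0.0, 1.0])
        u = normalize(np.cross(ref, self.normal))
        v = np.cross(self.normal, u)
        return u, v

    def rescale(self, factor: float) -> None:
        self.width *= factor
        self.height *= factor


# ---------------------------------------------------------------------------
# Intersections
# ---------------------------------------------------------------------------


def _intersect_sphere(ray: Ray, s: Sphere) -> float | None:
    oc = ray.origin - s.center
    b = float(np.dot(oc, ray.direction))
    c = float(np.dot(oc, oc)) - s.radius * s.radius
    disc = b * b - c
    if disc < 0.0:
        if disc > -1e-12:  # grazing hit: treat a vanishing discriminant as 0
            disc = 0.0
        else:
            return None
    sq = math.sqrt(disc)
    t = -b - sq
    if t < -TOL:
        t = -b + sq
    if t < -TOL:
        return None
    return max(t, 0.0)


def _intersect_plane(ray: Ray, p: RectPlane) -> float | None:
    denom = float(np.dot(ray.direction, p.normal))
    if abs(denom) < 1e-12:
        return None
    t = float(np.dot(p.center - ray.origin, p.normal)) / denom
    if t < -TOL:
        return None
    t = max(t, 0.0)
    local = ray.point_at(t) - p.center
    u_ax, v_ax = p.axes()
    if abs(float(np.dot(local, u_ax))) > p.width / 2 + TOL:
        return None
    if abs(float(np.dot(local, v_ax))) > p.height / 2 + TOL:
        return None
    return t


def _intersect_box(ray: Ray, b: Box) -> float | None:
    # slab test in the box's local frame
    pose = b.pose
    o = pose.inverse_transform_point(ray.origin)
    d = pose.rotation_inv.apply(ray.direction)
    t_near, t_far = -math.inf, math.inf
    for i in range(3):
        e = b.half_extents[i]
        if abs(d[i]) < 1e-12:
            if abs(o[i]) > e + TOL:
                return None
            continue
        t1 = (-e - o[i]) / d[i]
        t2 = (e - o[i]) / d[i]
        if t1 > t2:
            t1, t2 = t2, t1
        t_near = max(t_near, t1)
        t_far = min(t_far, t2)
    if t_near > t_far + TOL or t_far < -TOL:
        return None
    t = t_near if t_near >= -TOL else t_far
    return max(t, 0.0)


def intersect(ray: Ray, prim: ScenePrimitive) -> tuple[float, np.ndarray] | None:
    """Closest non-negative ray/primitive intersection.

    Returns ``(t, point)`` with ``point = origin + t * direction``, or
    ``None`` on a miss (a miss is a valid result, not an error).
    """
    if isinstance(prim, Sphere):
        t = _intersect_sphere(ray, prim)
    elif isinstance(prim, RectPlane):
        t = _intersect_plane(ray, prim)
    elif isinstance(prim, Box):
        t = _intersect_box(ray, prim)
    else:  # pragma: no cover - guarded by the type system in practice
        raise GeometryError(f"unsupported primitive type {type(prim).__name__}")
    if t is None:
        return None
    return t, ray.point_at(t)


def closest_intersection(
    ray: Ray, prims
) -> tuple[str, float, np.ndarray] | None:
    """Hit with minimal ``t`` among pickable primitives.

    Ties are broken by registration (iteration) order. Returns
    ``(id, t, point)`` or ``None``.
    """
    best: tuple[str, float, np.ndarray] | None = None
    for prim in prims:
        if not prim.pickable:
            continue
        hit = intersect(ray, prim)
        if hit is None:
            continue
        t, point = hit
        if best is None or t < best[1]:
            best = (prim.id, t, point)
    return best


def angular_distance(a: Vec3Like, b: Vec3Like) -> float:
    """Angle between two nonzero vectors, in degrees, range [0, 180]."""
    ua = normalize(a)
    ub = normalize(b)
    dot = float(np.clip(np.dot(ua, ub), -1.0, 1.0))
    return math.degrees(math.acos(dot))
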