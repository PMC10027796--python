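"""Gaze-calibration quality assessment.

After an eye tracker's own calibration, its *real* data quality for the
current participant is measured by presenting fixation targets at known
angular positions and recording gaze.  Three standard metrics are
computed per target from the scalar angular error between each gaze
direction and the true origin-to-target direction:

* **accuracy**: mean angular error (degrees) — systematic offset,
* **precision SD**: sample standard deviation (ddof=1) of the errors,
* **RMSE**: root mean square of the errors (vs-target, population n).

With these conventions the identity
``rmse**2 == accuracy**2 + (n-1)/n * sd**2`` holds exactly on every
result, which the test suite exploits.

The default layout is the five-target cross: one central target plus
four at +-e degrees horizontally and vertically, all placed on a sphere
of the requested depth around the cyclopean origin, so each peripheral
target's eccentricity is exactly ``e``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .design import ParamSet
from .geometry import Pose, angular_distance, vec3
from .recorder import FrameClock, SampleRecorder

__all__ = [
    "ValidationError",
    "ValidationTarget",
    "TargetMetrics",
    "ValidationResult",
    "target_direction",
    "make_cross_layout",
    "run_validation",
    "summarize_validation",
]


class ValidationError(RuntimeError):
    """Validation could not run or produced no usable data."""


def target_direction(h_deg: float, v_deg: float) -> np.ndarray:
    """Unit direction for horizontal/vertical offsets from straight ahead.

    Straight ahead is +Z; positive ``h_deg`` turns right (+X), positive
    ``v_deg`` turns up (+Y).  For single-axis offsets the angle to +Z
    equals the offset exactly.
    """
    h = math.radians(h_deg)
    v = math.radians(v_deg)
    return np.array(
        [math.cos(v) * math.sin(h), math.sin(v), math.cos(v) * math.cos(h)]
    )


@dataclass(frozen=True, eq=False)
class ValidationTarget:
    """One fixation target: angular offsets (deg), depth (m), world position."""

    h_deg: float
    v_deg: float
    depth: float
    world_position: np.ndarray

    @property
    def eccentricity_deg(self) -> float:
        return math.hypot(self.h_deg, self.v_deg)


def make_cross_layout(
    eccentricity_deg: float = 5.0,
    depth_m: float = 0.5,
    origin: Pose | None = None,
) -> list[ValidationTarget]:
    """Central target plus four at (+-e, 0) and (0, +-e) degrees.

    World positions lie on a sphere of radius ``depth_m`` around the
    cyclopean origin given by ``origin`` (default: world origin facing
    +Z).  Changing the depth rescales positions but not eccentricities.
    """
    if not (0.0 < eccentricity_deg <= 45.0):
        raise ValidationError("eccentricity must be in (0, 45] degrees")
    if depth_m <= 0:
        raise ValidationError("target depth must be positive")
    if origin is None:
        origin = Pose()
    e = eccentricity_deg
    offsets = [(0.0, 0.0), (e, 0.0), (-e, 0.0), (0.0, e), (0.0, -e)]
    targets = []
    for h, v in offsets:
        local = depth_m * target_direction(h, v)
        targets.append(
            ValidationTarget(
                h_deg=h,
                v_deg=v,
                depth=depth_m,
                world_position=origin.transform_point(local),
            )
        )
    return targets


@dataclass
class TargetMetrics:
    """Per-target angular-error metrics; flagged targets had no valid data."""

    h_deg: float
    v_deg: float
    depth: float
    accuracy_deg: float | None
    sd_deg: float | None
    rmse_deg: float | None
    n_samples: int
    flagged: bool = False

    def to_dict(self) -> dict:
        return {
            "h_deg": self.h_deg,
            "v_deg": self.v_deg,
            "depth": self.depth,
            "accuracy_deg": self.accuracy_deg,
            "sd_deg": self.sd_deg,
            "rmse_deg": self.rmse_deg,
            "n_samples": self.n_samples,
            "flagged": self.flagged,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TargetMetrics":
        return cls(**d)


@dataclass
class ValidationResult:
    """Metrics for one validation run (one entry per target)."""

    targets: list = field(default_factory=list)
    timestamp: float = 0.0

    def unflagged(self) -> list[TargetMetrics]:
        return [t for t in self.targets if not t.flagged]

    def to_dict(self) -> dict:
        return {
            "timestamp": self.timestamp,
            "targets": [t.to_dict() for t in self.targets],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ValidationResult":
        return cls(
            targets=[TargetMetrics.from_dict(t) for t in d["targets"]],
            timestamp=d["timestamp"],
        )


def metrics_from_angles(angles, h_deg=0.0, v_deg=0.0, depth=0.0) -> TargetMetrics:
    """Accuracy / precision SD / RMSE from a sequence of angular errors."""
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        return TargetMetrics(h_deg, v_deg, depth, None, None, None, 0, flagged=True)
    accuracy = float(np.mean(a))
    sd = float(np.std(a, ddof=1)) if a.size > 1 else 0.0
    rmse = float(np.sqrt(np.mean(a**2)))
    return TargetMetrics(h_deg, v_deg, depth, accuracy, sd, rmse, int(a.size))


def angular_errors(samples, target_position) -> list[float]:
    """Angle between each valid gaze direction and the true target direction."""
    target_position = vec3(target_position)
    errors = []
    for s in samples:
        g = s.gaze
        if g is None:
            continue
        errors.append(
            angular_distance(g.world_dir, target_position - g.world_origin)
        )
    return errors


def run_validation(
    recorder: SampleRecorder,
    targets,
    clock: FrameClock,
    fixation_window_s: float = 1.0,
    settle_s: float = 0.2,
    session=None,
    present=None,
) -> ValidationResult:
    """Collect gaze for each target in order and compute its metrics.

    ``present(target)`` is called at each target's onset (show the
    stimulus; in simulation, point the synthetic gaze at it).  Samples
    from the first ``settle_s`` of each window are discarded as saccade
    settling.  A target with zero valid samples is flagged and excluded
    from averages.  The result is appended to ``session.validations``
    when a session is given.
    """
    if not recorder.has_eye_tracker:
        raise ValidationError("no eye tracker registered")
    result = ValidationResult(timestamp=clock.time)
    n_total = clock.frames(fixation_window_s)
    n_settle = clock.frames(settle_s)
    for target in targets:
        if present is not None:
            present(target)
        window = []
        for k in range(n_total):
            sample = recorder.record_frame(clock)
            if k >= n_settle:
                window.append(sample)
            clock.tick()
        metrics = metrics_from_angles(
            angular_errors(window, target.world_position),
            h_deg=target.h_deg,
            v_deg=target.v_deg,
            depth=target.depth,
        )
        result.targets.append(metrics)
    if session is not None:
        session.validations.append(result)
    return result


def summarize_validation(result: ValidationResult) -> ParamSet:
    """Unweighted averages (and worst values) across unflagged targets."""
    good = result.unflagged()
    if not good:
        raise ValidationError("all validation targets are flagged")
    acc = [t.accuracy_deg for t in good]
    sd = [t.sd_deg for t in good]
    rmse = [t.rmse_deg for t in good]
    return ParamSet(
        n_targets=len(good),
        n_flagged=len(result.targets) - len(good),
        mean_accuracy_deg=float(np.mean(acc)),
        mean_sd_deg=float(np.mean(sd)),
        mean_rmse_deg=float(np.mean(rmse)),
        worst_accuracy_deg=float(np.max(acc)),
        worst_sd_deg=float(np.max(sd)),
        worst_rmse_deg=float(np.max(rmse)),
    )
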