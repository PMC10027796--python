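"""Kinematic analysis pipeline for recorded reach sessions.

Given saved sessions (JSON) the pipeline extracts per-trial dependent
variables and condition aggregates:

* controller velocity by backward differences of the recorded positions
  (no smoothing by default; the recordings are frame-locked at 90 Hz);
* movement onset as the first sample whose +Z (away from the
  participant) velocity exceeds a threshold, searched over the whole
  trial so that movements started *before* the go cue are found;
* movement latency = onset - go cue (negative for early starts),
  movement duration = threshold crossing - onset;
* horizontal endpoint error = |X at the depth-threshold crossing minus
  the reference X|, computed both against the visual target position
  (``error_vs_target``, the default) and against the mirrored reach
  goal (``error_vs_goal``), which differ on anti-reach trials;
* correct-hemifield response = the crossing X falls in the goal's
  hemifield;
* per-participant outlier removal at mean +- k*SD (single pass, pooled
  across conditions) on latency and duration;
* per-condition aggregation across participants (mean of participant
  means, standard error), plus gaze-on-plane trace extraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .design import ExperimentSession, TrialRecord
from .simulate import minimum_jerk_fraction

__all__ = [
    "AnalysisError",
    "TrialMeasures",
    "controller_velocity",
    "detect_movement_onset",
    "min_jerk_onset_lag",
    "min_jerk_crossing_offset",
    "compute_trial_measures",
    "session_measures",
    "filter_outliers",
    "aggregate_by_condition",
    "gaze_on_plane",
    "plot_condition_means",
    "plot_trajectories",
    "plot_gaze_traces",
]

DEFAULT_ONSET_THRESHOLD = 0.05  # m/s; the velocity criterion for movement onset


class AnalysisError(ValueError):
    """Unusable input for the analysis pipeline."""


@dataclass
class TrialMeasures:
    """Dependent variables for one trial (None where undefined)."""

    trial_number: int | None
    target_side: str | None
    cue: str | None
    feedback: str | None
    target_x: float | None
    goal_x: float | None
    onset_time: float | None
    latency: float | None
    duration: float | None
    error_vs_target: float | None
    error_vs_goal: float | None
    correct_hemifield: bool | None
    defined: bool
    undefined_reason: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _node_positions(samples, node: str):
    """(times, positions) arrays for frames where the node pose is valid."""
    times, positions = [], []
    for s in samples:
        pose = s.nodes.get(node)
        if pose is None:
            continue
        times.append(s.time)
        positions.append(pose.position)
    return np.asarray(times, dtype=float), np.asarray(positions, dtype=float)


def controller_velocity(samples, node: str = "controller"):
    """Backward-difference velocity (m/s) per sample.

    ``v[i] = (p[i] - p[i-1]) / (t[i] - t[i-1])`` assigned to the later
    sample; the first sample's velocity is undefined (NaN row).
    Returns ``(times, velocities)`` with velocities of shape (n, 3).
    """
    times, pos = _node_positions(samples, node)
    if times.size < 2:
        raise AnalysisError("need at least two samples with a valid pose")
    dt = np.diff(times)
    if np.any(dt <= 0):
        raise AnalysisError("timestamps must be strictly increasing")
    vel = np.full_like(pos, np.nan)
    vel[1:] = np.diff(pos, axis=0) / dt[:, None]
    return times, vel


def detect_movement_onset(times, v_z, threshold_mps: float) -> float | None:
    """Time of the first sample whose +Z velocity exceeds the threshold.

    The whole trial is searched (not just after the go cue), so early
    movement starts are detected.  Returns ``None`` if the threshold is
    never exceeded.
    """
    v_z = np.asarray(v_z, dtype=float)
    above = np.flatnonzero(v_z > threshold_mps)
    if above.size == 0:
        return None
    return float(np.asarray(times, dtype=float)[above[0]])


def min_jerk_onset_lag(
    distance_m: float, duration_s: float, threshold_mps: float
) -> float:
    """Closed-form lag between true onset and the velocity criterion.

    For a minimum-jerk movement of the given total distance and
    duration, path speed is ``(distance/duration) * 30 tau^2 (1-tau)^2``;
    this solves for the earliest tau where it exceeds the threshold.
    Used by parameter-recovery checks as the analytic oracle.
    """
    peak = 1.875 * distance_m / duration_s
    if threshold_mps >= peak:
        raise AnalysisError("threshold exceeds the peak minimum-jerk speed")
    if threshold_mps <= 0:
        return 0.0
    f = lambda tau: 30.0 * tau**2 * (1.0 - tau) ** 2 * (
        distance_m / duration_s
    ) - threshold_mps
    return duration_s * brentq(f, 0.0, 0.5, xtol=1e-12)


def min_jerk_crossing_offset(
    start_z: float, goal_z: float, threshold_z: float, duration_s: float
) -> float:
    """Time after onset at which a minimum-jerk depth profile reaches a
    threshold depth (analytic oracle for movement-duration recovery)."""
    frac = (threshold_z - start_z) / (goal_z - start_z)
    if not (0.0 < frac <= 1.0):
        raise AnalysisError("threshold depth outside the movement range")
    g = lambda tau: minimum_jerk_fraction(tau) - frac
    return duration_s * brentq(g, 0.0, 1.0, xtol=1e-12)


def _event_time(trial: TrialRecord, label: str) -> float | None:
    for ev in trial.events:
        if ev.label == label:
            return ev.time
    return None


def _undefined(trial, reason: str) -> TrialMeasures:
    p = trial.params
    return TrialMeasures(
        trial_number=trial.number,
        target_side=p.get("target_side"),
        cue=p.get("cue"),
        feedback=p.get("feedback"),
        target_x=p.get("target_x"),
        goal_x=p.get("goal_x"),
        onset_time=None,
        latency=None,
        duration=None,
        error_vs_target=None,
        error_vs_goal=None,
        correct_hemifield=None,
        defined=False,
        undefined_reason=reason,
    )


def compute_trial_measures(
    trial: TrialRecord,
    threshold_mps: float = DEFAULT_ONSET_THRESHOLD,
    node: str = "controller",
) -> TrialMeasures:
    """Latency, duration, endpoint errors, and hemifield correctness.

    Requires the trial's ``go_cue`` and ``threshold_crossed`` events;
    missing events or an undetectable onset yield an undefined result
    (flagged, with a reason) rather than an exception.
    """
    go_time = _event_time(trial, "go_cue")
    cross_time = _event_time(trial, "threshold_crossed")
    if go_time is None or cross_time is None:
        return _undefined(trial, "missing go_cue/threshold_crossed events")
    try:
        times, vel = controller_velocity(trial.samples, node)
    except AnalysisError as exc:
        return _undefined(trial, str(exc))
    onset = detect_movement_onset(times, vel[:, 2], threshold_mps)
    if onset is None:
        return _undefined(trial, "velocity never exceeded the onset threshold")

    cross_event = next(e for e in trial.events if e.label == "threshold_crossed")
    if cross_event.payload is not None and "x" in cross_event.payload:
        x_cross = float(cross_event.payload["x"])
    else:
        # fall back to the sample recorded at the crossing frame
        match = [
            s
            for s in trial.samples
            if s.frame == cross_event.frame and s.nodes.get(node) is not None
        ]
        if not match:
            return _undefined(trial, "no sample at the threshold crossing")
        x_cross = float(match[0].nodes[node].position[0])

    p = trial.params
    target_x = p.get("target_x")
    goal_x = p.get("goal_x")
    correct = None
    if goal_x is not None:
        correct = bool(math.copysign(1.0, x_cross) == math.copysign(1.0, goal_x))
    return TrialMeasures(
        trial_number=trial.number,
        target_side=p.get("target_side"),
        cue=p.get("cue"),
        feedback=p.get("feedback"),
        target_x=target_x,
        goal_x=goal_x,
        onset_time=onset,
        latency=onset - go_time,
        duration=cross_time - onset,
        error_vs_target=None if target_x is None else abs(x_cross - target_x),
        error_vs_goal=None if goal_x is None else abs(x_cross - goal_x),
        correct_hemifield=correct,
        defined=True,
    )


def session_measures(
    session: ExperimentSession,
    threshold_mps: float = DEFAULT_ONSET_THRESHOLD,
    participant: str | None = None,
) -> pd.DataFrame:
    """Tidy table of trial measures, one row per non-error trial."""
    if participant is None:
        participant = session.metadata.get("participant", "P??")
    rows = []
    for trial in session.trials:
        if trial.status != "done":
            continue
        m = compute_trial_measures(trial, threshold_mps)
        row = m.to_dict()
        row["participant"] = participant
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        front = ["participant", "trial_number", "target_side", "cue", "feedback"]
        df = df[front + [c for c in df.columns if c not in front]]
    return df


def filter_outliers(measures: pd.DataFrame, k: float = 3.0) -> pd.DataFrame:
    """Flag trials with latency or duration outside mean +- k*SD.

    Statistics are computed per participant over defined values only,
    pooled across conditions, in a single pass (the filter is therefore
    idempotent on its own output by convention).  Returns a copy with
    ``outlier`` and ``outlier_reason`` columns; a trial flagged on
    either measure is excluded from aggregates.
    """
    df = measures.copy()
    df["outlier"] = False
    df["outlier_reason"] = None
    if df.empty:
        return df
    for _, idx in df.groupby("participant").groups.items():
        for measure in ("latency", "duration"):
            values = df.loc[idx, measure].astype(float)
            valid = values.dropna()
            if len(valid) < 2:
                continue
            mean, sd = valid.mean(), valid.std(ddof=1)
            if sd == 0 or not np.isfinite(sd):
                continue
            flagged = (values - mean).abs() > k * sd
            flagged = flagged.fillna(False)
            for i in values.index[flagged]:
                df.loc[i, "outlier"] = True
                reason = df.loc[i, "outlier_reason"]
                df.loc[i, "outlier_reason"] = (
                    measure if reason is None else f"{reason},{measure}"
                )
    return df


_DVS = ("latency", "duration", "error_vs_target", "error_vs_goal")


def aggregate_by_condition(
    measures: pd.DataFrame, by=("target_side", "cue")
) -> pd.DataFrame:
    """Across-participant condition table.

    For each condition cell: the mean over participants of
    per-participant DV means, its standard error (SD of participant
    means / sqrt(N)), and the correct-response rate over all non-outlier
    trials.  Empty cells are reported as missing (NaN), never as zero.
    """
    by = list(by)
    df = measures.copy()
    if "outlier" not in df.columns:
        df["outlier"] = False
    df = df[df["defined"].astype(bool) & ~df["outlier"].astype(bool)]
    cells = []
    if df.empty:
        return pd.DataFrame(cells)
    for keys, cell in df.groupby(by, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        row = dict(zip(by, keys))
        per_participant = cell.groupby("participant")
        row["n_trials"] = int(len(cell))
        row["n_participants"] = int(per_participant.ngroups)
        for dv in _DVS:
            means = per_participant[dv].mean().dropna()
            if means.empty:
                row[f"{dv}_mean"], row[f"{dv}_se"] = np.nan, np.nan
                continue
            row[f"{dv}_mean"] = float(means.mean())
            row[f"{dv}_se"] = (
                float(means.std(ddof=1) / np.sqrt(len(means)))
                if len(means) > 1
                else np.nan
            )
        correct = cell["correct_hemifield"].dropna()
        row["correct_rate"] = float(correct.mean()) if len(correct) else np.nan
        cells.append(row)
    return pd.DataFrame(cells)


def gaze_on_plane(
    trial: TrialRecord,
    plane_id: str = "gaze_plane",
    center_xy=(0.0, 0.0),
    align_to_go: bool = True,
) -> pd.DataFrame:
    """Time series of gaze intersections with the recording plane.

    Returns columns ``time`` (relative to the go cue when available),
    ``x`` and ``y`` (meters relative to ``center_xy``); frames where
    gaze missed the plane are simply absent, leaving gaps.
    """
    go_time = _event_time(trial, "go_cue") if align_to_go else None
    cx, cy = center_xy
    rows = []
    for s in trial.samples:
        g = s.gaze
        if g is None or g.hit_object != plane_id or g.hit_point is None:
            continue
        t = s.time - go_time if go_time is not None else s.time
        rows.append(
            {"time": t, "x": float(g.hit_point[0]) - cx, "y": float(g.hit_point[1]) - cy}
        )
    return pd.DataFrame(rows, columns=["time", "x", "y"])


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------


def _use_agg():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_condition_means(aggregates: pd.DataFrame, path) -> None:
    """Bar chart of per-condition DV means with standard-error bars."""
    plt = _use_agg()
    dvs = [("latency", "s"), ("duration", "s"), ("error_vs_target", "m")]
    fig, axes = plt.subplots(1, len(dvs), figsize=(4 * len(dvs), 3.2))
    labels = [
        " ".join(str(v) for v in row)
        for row in aggregates[["target_side", "cue"]].itertuples(index=False)
    ]
    for ax, (dv, unit) in zip(axes, dvs):
        ax.bar(
            range(len(aggregates)),
            aggregates[f"{dv}_mean"],
            yerr=aggregates[f"{dv}_se"].fillna(0.0),
            capsize=3,
        )
        ax.set_xticks(range(len(aggregates)))
        ax.set_xticklabels(labels, rotation=45, ha="right", fontsize=8)
        ax.set_ylabel(f"{dv.replace('_', ' ')} ({unit})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_trajectories(session: ExperimentSession, path, node: str = "controller") -> None:
    """Controller position over time per condition, aligned to the go cue."""
    plt = _use_agg()
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.2), sharex=True)
    axis_names = ["X (lateral)", "Y (vertical)", "Z (depth)"]
    for trial in session.trials:
        if trial.status != "done":
            continue
        go = _event_time(trial, "go_cue")
        if go is None:
            continue
        times, pos = _node_positions(trial.samples, node)
        color = "tab:blue" if trial.params.get("cue") == "pro" else "tab:red"
        for i, ax in enumerate(axes):
            ax.plot(times - go, pos[:, i], color=color, alpha=0.25, lw=0.8)
    for i, ax in enumerate(axes):
        ax.axvline(0.0, ls=":", color="k", lw=0.8)
        ax.set_xlabel("time from go cue (s)")
        ax.set_ylabel(f"{axis_names[i]} (m)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_gaze_traces(
    session: ExperimentSession, path, plane_id: str = "gaze_plane", center_xy=(0.0, 0.0)
) -> None:
    """Horizontal and vertical gaze-on-plane position per trial."""
    plt = _use_agg()
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.2), sharex=True)
    for trial in session.trials:
        if trial.status != "done":
            continue
        trace = gaze_on_plane(trial, plane_id=plane_id, center_xy=center_xy)
        if trace.empty:
            continue
        axes[0].plot(trace["time"], trace["x"], alpha=0.3, lw=0.8)
        axes[1].plot(trace["time"], trace["y"], alpha=0.3, lw=0.8)
    for ax, label in zip(axes, ("horizontal (X)", "vertical (Y)")):
        ax.axvline(0.0, ls=":", color="k", lw=0.8)
        ax.set_xlabel("time from go cue (s)")
        ax.set_ylabel(f"gaze on plane, {label} (m)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
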