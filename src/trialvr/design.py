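"""Data model and life cycle of a trial-based experimental session.

The central objects mirror how behavioral experiments are normally
organized: an :class:`ExperimentSession` owns ordered
:class:`TrialRecord` objects, each of which carries a ``params``
:class:`ParamSet` (the independent variables for that trial) and an
initially read-only ``results`` :class:`ParamSet` that becomes writable
once the trial is running.  Designs can be generated as full factorials,
imported from CSV, and randomized globally or within ordered blocks.
"""

from __future__ import annotations

import csv
import itertools
import time as _time
from collections.abc import Mapping, MutableMapping
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ParamError",
    "DesignError",
    "FormatError",
    "RunError",
    "SerializationError",
    "TrialStateError",
    "ParamSet",
    "TrialRecord",
    "ExperimentSession",
    "DesignSpec",
    "make_factorial_design",
    "load_trials_csv",
    "save_trials_csv",
    "IncrementalTrialWriter",
    "randomize_trials",
    "run_experiment",
    "parse_scalar",
    "format_scalar",
]


class ParamError(ValueError):
    """Invalid key/value for a ParamSet, or write to a frozen ParamSet."""


class DesignError(ValueError):
    """Invalid experimental design specification."""


class FormatError(ValueError):
    """Malformed tabular input (CSV trial files)."""


class RunError(RuntimeError):
    """Experiment run could not start or was aborted."""


class SerializationError(ValueError):
    """A session value cannot be represented in JSON (named by key path)."""


class TrialStateError(RuntimeError):
    """Illegal trial status transition."""


_SCALARS = (bool, int, float, str, type(None))


def parse_scalar(text: str):
    """CSV cell -> value: empty -> None, then int, float, true/false, text."""
    if text == "":
        return None
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        pass
    low = text.strip().lower()
    if low == "true":
        return True
    if low == "false":
        return False
    return text


def format_scalar(value) -> str:
    """Value -> CSV cell, inverse of :func:`parse_scalar` for round trips."""
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


class ParamSet(MutableMapping):
    """Ordered key->scalar mapping with attribute access and file I/O.

    Behaves like a dict (insertion order preserved, keys unique) but also
    supports ``ps.key`` access and round trips through JSON and through a
    single CSV row.  Values are scalars (number, text, boolean, None);
    one level of nested mappings is allowed, which flattens to
    ``"parent.child"`` keys in CSV.
    """

    __slots__ = ("_data", "_frozen")

    def __init__(self, data: Mapping | None = None, **kwargs):
        object.__setattr__(self, "_data", {})
        object.__setattr__(self, "_frozen", False)
        if data is not None:
            for k, v in dict(data).items():
                self[k] = v
        for k, v in kwargs.items():
            self[k] = v

    # -- mapping protocol -----------------------------------------------------
    def __getitem__(self, key):
        return self._data[key]

    def __setitem__(self, key, value):
        if self._frozen:
            raise ParamError(
                "results are read-only until the trial is running"
            )
        if not isinstance(key, str) or not key:
            raise ParamError(f"ParamSet keys must be non-empty strings, got {key!r}")
        if isinstance(value, Mapping):
            nested = ParamSet()
            for nk, nv in dict(value).items():
                if isinstance(nv, Mapping):
                    raise ParamError(
                        f"nested mappings allowed only one level deep (key {key!r}.{nk!r})"
                    )
                nested[nk] = nv
            value = nested
        elif isinstance(value, (np.integer,)):
            value = int(value)
        elif isinstance(value, (np.floating,)):
            value = float(value)
        elif isinstance(value, np.bool_):
            value = bool(value)
        elif not isinstance(value, _SCALARS):
            raise ParamError(
                f"value for {key!r} must be a scalar or one-level mapping, "
                f"got {type(value).__name__}"
            )
        self._data[key] = value

    def __delitem__(self, key):
        if self._frozen:
            raise ParamError("cannot delete from a frozen ParamSet")
        del self._data[key]

    def __iter__(self):
        return iter(self._data)

    def __len__(self):
        return len(self._data)

    # -- attribute access -----------------------------------------------------
    def __getattr__(self, name):
        if name.startswith("_"):
            raise AttributeError(name)
        try:
            return self._data[name]
        except KeyError:
            raise AttributeError(name) from None

    def __setattr__(self, name, value):
        if name in type(self).__slots__:
            object.__setattr__(self, name, value)
        else:
            self[name] = value

    # -- freezing (trial results before the trial runs) -----------------------
    def _set_frozen(self, frozen: bool) -> None:
        object.__setattr__(self, "_frozen", frozen)

    # -- conversion -----------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            k: (v.to_dict() if isinstance(v, ParamSet) else v)
            for k, v in self._data.items()
        }

    def copy(self) -> "ParamSet":
        return ParamSet(self.to_dict())

    def flatten(self) -> dict:
        """One-level flattening: nested keys become ``parent.child``."""
        flat: dict = {}
        for k, v in self._data.items():
            if isinstance(v, ParamSet):
                for nk, nv in v.items():
                    flat[f"{k}.{nk}"] = nv
            else:
                flat[k] = v
        return flat

    @classmethod
    def from_flat(cls, flat: Mapping) -> "ParamSet":
        ps = cls()
        for k, v in dict(flat).items():
            if "." in k:
                parent, child = k.split(".", 1)
                if parent not in ps or not isinstance(ps[parent], ParamSet):
                    ps[parent] = ParamSet()
                ps[parent][child] = v
            else:
                ps[k] = v
        return ps

    # -- file I/O -------------------------------------------------------------
    def to_csv(self, path) -> None:
        flat = self.flatten()
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(flat.keys())
            writer.writerow([format_scalar(v) for v in flat.values()])

    @classmethod
    def from_csv(cls, path) -> "ParamSet":
        with open(path, newline="", encoding="utf-8") as fh:
            rows = list(csv.reader(fh))
        if len(rows) < 2:
            raise FormatError(f"{path}: expected a header row and one data row")
        header, values = rows[0], rows[1]
        if len(header) != len(values):
            raise FormatError(f"{path}: header/data length mismatch")
        return cls.from_flat(
            {k: parse_scalar(v) for k, v in zip(header, values)}
        )

    def __eq__(self, other) -> bool:
        if isinstance(other, ParamSet):
            return self.to_dict() == other.to_dict()
        if isinstance(other, Mapping):
            return self.to_dict() == dict(other)
        return NotImplemented

    def __repr__(self) -> str:
        return f"ParamSet({self.to_dict()!r})"


# ---------------------------------------------------------------------------
# Trials and sessions
# ---------------------------------------------------------------------------

PENDING, RUNNING, DONE, ERROR = "pending", "running", "done", "error"
_TRANSITIONS = {PENDING: {RUNNING}, RUNNING: {DONE, ERROR}, DONE: set(), ERROR: set()}


def _frozen_paramset() -> ParamSet:
    ps = ParamSet()
    ps._set_frozen(True)
    return ps


@dataclass
class TrialRecord:
    """One experimental trial.

    ``index`` is the 0-based creation order (stable across
    randomization); ``number`` is the 1-based presentation order and is
    assigned when the trial is run.  ``results`` starts read-only and is
    unlocked when the trial enters the ``running`` state.
    """

    index: int
    params: ParamSet = field(default_factory=ParamSet)
    number: int | None = None
    block: int = 0
    status: str = PENDING
    results: ParamSet = field(default_factory=_frozen_paramset)
    samples: list = field(default_factory=list)
    events: list = field(default_factory=list)

    def _transition(self, new_status: str) -> None:
        if new_status not in _TRANSITIONS[self.status]:
            raise TrialStateError(
                f"trial {self.index}: illegal transition {self.status} -> {new_status}"
            )
        self.status = new_status

    def start(self) -> None:
        self._transition(RUNNING)
        self.results._set_frozen(False)

    def finish(self) -> None:
        self._transition(DONE)

    def fail(self) -> None:
        self._transition(ERROR)

    @property
    def condition(self) -> tuple:
        """Factor levels of this trial, excluding the repetition counter."""
        return tuple(
            v for k, v in self.params.items() if k != "repetition"
        )


@dataclass
class ExperimentSession:
    """All information specific to one experimental session."""

    metadata: ParamSet = field(default_factory=ParamSet)
    config: ParamSet = field(default_factory=ParamSet)
    trials: list = field(default_factory=list)
    validations: list = field(default_factory=list)
    start_time: float | None = None
    end_time: float | None = None

    def add_trials(self, trials) -> None:
        existing = {t.index for t in self.trials}
        for t in trials:
            if t.index in existing:
                raise DesignError(f"duplicate trial index {t.index}")
            existing.add(t.index)
            self.trials.append(t)


# ---------------------------------------------------------------------------
# Design generation
# ---------------------------------------------------------------------------


@dataclass
class DesignSpec:
    """Full-factorial design: ordered factors -> levels, plus repetitions."""

    factors: dict
    repetitions: int = 1
    block_factor: str | None = None

    def __post_init__(self) -> None:
        if not self.factors:
            raise DesignError("design needs at least one factor")
        for name, levels in self.factors.items():
            if not isinstance(levels, (list, tuple)) or len(levels) == 0:
                raise DesignError(f"factor {name!r} needs at least one level")
        if self.repetitions < 1:
            raise DesignError("repetitions must be >= 1")
        if self.block_factor is not None and self.block_factor not in self.factors:
            raise DesignError(f"unknown block factor {self.block_factor!r}")

    @property
    def n_trials(self) -> int:
        n = self.repetitions
        for levels in self.factors.values():
            n *= len(levels)
        return n


def make_factorial_design(spec: DesignSpec) -> list[TrialRecord]:
    """Cross all factor levels, repeated ``spec.repetitions`` times.

    Enumeration order: the last factor varies fastest and repetitions are
    outermost; each trial's params holds one factor-level combination
    plus a 1-based ``repetition`` key.
    """
    names = list(spec.factors)
    trials: list[TrialRecord] = []
    index = 0
    for rep in range(1, spec.repetitions + 1):
        for combo in itertools.product(*(spec.factors[n] for n in names)):
            params = ParamSet()
            for name, level in zip(names, combo):
                params[name] = level
            params["repetition"] = rep
            block = 0
            if spec.block_factor is not None:
                try:
                    block = int(params[spec.block_factor])
                except (TypeError, ValueError) as exc:
                    raise DesignError(
                        f"block factor {spec.block_factor!r} level "
                        f"{params[spec.block_factor]!r} is not an integer"
                    ) from exc
            trials.append(TrialRecord(index=index, params=params, block=block))
            index += 1
    return trials


# ---------------------------------------------------------------------------
# Trial CSV I/O
# ---------------------------------------------------------------------------

#: identifier columns written by save_trials_csv; skipped on import so that
#: a save -> load round trip reproduces the original params.
_RESERVED_COLUMNS = ("number", "status")


def load_trials_csv(path, block_column: str | None = None) -> list[TrialRecord]:
    """One TrialRecord per data row, params keyed by header names.

    Cell types are inferred (int, then float, then true/false, else
    text).  ``block_column`` names the column holding integer block
    numbers.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise FormatError(f"{path}: empty file")
    header = rows[0]
    dupes = {h for h in header if header.count(h) > 1}
    if dupes:
        raise FormatError(f"{path}: duplicate header names {sorted(dupes)}")
    if block_column is not None and block_column not in header:
        raise FormatError(f"{path}: block column {block_column!r} not in header")
    trials: list[TrialRecord] = []
    for i, row in enumerate(rows[1:]):
        if len(row) != len(header):
            raise FormatError(
                f"{path}: row {i + 2} has {len(row)} cells, expected {len(header)}"
            )
        record = dict(zip(header, row))
        block = 0
        if block_column is not None:
            value = parse_scalar(record[block_column])
            if not isinstance(value, int) or isinstance(value, bool):
                raise FormatError(
                    f"{path}: row {i + 2}, column {block_column!r}: "
                    f"block value {record[block_column]!r} is not an integer"
                )
            block = value
        params = ParamSet.from_flat(
            {
                k: parse_scalar(v)
                for k, v in record.items()
                if k not in _RESERVED_COLUMNS and k != block_column
            }
        )
        trials.append(TrialRecord(index=i, params=params, block=block))
    return trials


def _trial_columns(trials) -> tuple[list[str], list[str]]:
    param_keys: list[str] = []
    result_keys: list[str] = []
    for t in trials:
        for k in t.params.flatten():
            if k not in param_keys:
                param_keys.append(k)
        for k in t.results.flatten():
            if k not in result_keys:
                result_keys.append(k)
    return param_keys, result_keys


def _trial_row(trial: TrialRecord, param_keys, result_keys) -> list[str]:
    flat_p = trial.params.flatten()
    flat_r = trial.results.flatten()
    row = [
        format_scalar(trial.number),
        format_scalar(trial.block),
        trial.status,
    ]
    row += [format_scalar(flat_p.get(k)) for k in param_keys]
    row += [format_scalar(flat_r.get(k)) for k in result_keys]
    return row


def save_trials_csv(session_or_trials, path) -> None:
    """One row per trial: number, block, status, params, then results.

    Param and result columns appear in first-seen order; a key missing in
    some trial yields an empty cell.
    """
    trials = getattr(session_or_trials, "trials", session_or_trials)
    param_keys, result_keys = _trial_columns(trials)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["number", "block", "status", *param_keys, *result_keys])
        for t in trials:
            writer.writerow(_trial_row(t, param_keys, result_keys))


class IncrementalTrialWriter:
    """Append one CSV row per trial immediately after it finishes.

    Writing after every trial limits data loss if the session script
    crashes.  Column layout is fixed at construction, so the expected
    result keys must be declared up front.
    """

    def __init__(self, path, param_keys, result_keys=()):
        self.path = path
        self.param_keys = list(param_keys)
        self.result_keys = list(result_keys)
        with open(path, "w", newline="", encoding="utf-8") as fh:
            csv.writer(fh).writerow(
                ["number", "block", "status", *self.param_keys, *self.result_keys]
            )

    def append(self, trial: TrialRecord) -> None:
        with open(self.path, "a", newline="", encoding="utf-8") as fh:
            csv.writer(fh).writerow(
                _trial_row(trial, self.param_keys, self.result_keys)
            )


# ---------------------------------------------------------------------------
# Randomization and run flow
# ---------------------------------------------------------------------------


def randomize_trials(trials, seed, within_blocks: bool = False) -> list[TrialRecord]:
    """Deterministically shuffle trials.

    With ``within_blocks`` the blocks are emitted in ascending block
    order and each block's members are permuted only among themselves;
    otherwise all trials are shuffled globally.  The returned list is a
    permutation of the input (same TrialRecord objects).
    """
    rng = np.random.default_rng(seed)
    trials = list(trials)
    if not within_blocks:
        return [trials[i] for i in rng.permutation(len(trials))]
    out: list[TrialRecord] = []
    for block in sorted({t.block for t in trials}):
        members = [t for t in trials if t.block == block]
        out.extend(members[i] for i in rng.permutation(len(members)))
    return out


def run_experiment(
    session: ExperimentSession,
    main_task,
    pre_task=None,
    post_task=None,
    clock=None,
    continue_on_error: bool | None = None,
) -> ExperimentSession:
    """Run every trial in list order through pre/main/post task functions.

    Tasks are callables receiving the current :class:`TrialRecord`; any
    frame clock they need is captured in their closures.  Presentation
    numbers 1..N are assigned in run order.  An uncaught task exception
    marks the trial ``error`` and, depending on ``continue_on_error``
    (default: the session config flag, else abort), either continues
    with the next trial or aborts the run by raising :class:`RunError`.
    """
    if not session.trials:
        raise RunError("cannot run an experiment with no trials")
    if continue_on_error is None:
        continue_on_error = bool(session.config.get("continue_on_error", False))
    now = (lambda: clock.time) if clock is not None else _time.time
    session.start_time = now()
    number = 0
    try:
        for trial in session.trials:
            number += 1
            trial.number = number
            trial.start()
            try:
                if pre_task is not None:
                    pre_task(trial)
                main_task(trial)
                if post_task is not None:
                    post_task(trial)
            except Exception as exc:
                trial.fail()
                trial.results["error"] = f"{type(exc).__name__}: {exc}"
                if not continue_on_error:
                    raise RunError(
                        f"trial {trial.number} failed; aborting run"
                    ) from exc
            else:
                trial.finish()
    finally:
        session.end_time = now()
    return session
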