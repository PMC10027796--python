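"""Design generation, randomization, run flow, and serialization."""

import itertools
import json

import numpy as np
import pytest

from trialvr.design import (
    DesignError,
    DesignSpec,
    ExperimentSession,
    FormatError,
    IncrementalTrialWriter,
    ParamError,
    ParamSet,
    RunError,
    SerializationError,
    TrialRecord,
    TrialStateError,
    load_trials_csv,
    make_factorial_design,
    parse_scalar,
    randomize_trials,
    run_experiment,
    save_trials_csv,
)
from trialvr.recorder import FrameClock
from trialvr.session_io import (
    load_session_json,
    save_session_json,
    session_to_dict,
)


class TestParamSet:
    def test_insertion_order_and_attribute_access(self):
        ps = ParamSet(b=2, a=1)
        ps["c"] = "x"
        assert list(ps) == ["b", "a", "c"]
        assert ps.a == 1 and ps["c"] == "x"

    def test_rejects_non_scalar_values(self):
        with pytest.raises(ParamError):
            ParamSet(bad=object())

    def test_rejects_two_level_nesting(self):
        with pytest.raises(ParamError):
            ParamSet(a={"b": {"c": 1}})

    def test_csv_round_trip_with_nested_keys(self, tmp_path):
        ps = ParamSet(name="s01", depth=0.5, n=80, ok=True, note=None,
                      timing={"hold": 1.0, "cue": 1.0})
        path = tmp_path / "params.csv"
        ps.to_csv(path)
        again = ParamSet.from_csv(path)
        assert again == ps
        # nested mapping flattens to parent.child in the CSV header
        header = path.read_text().splitlines()[0]
        assert "timing.hold" in header

    def test_json_round_trip(self):
        ps = ParamSet(x=1.5, label="left", nested={"a": 1})
        assert ParamSet(json.loads(json.dumps(ps.to_dict()))) == ps

    @pytest.mark.parametrize(
        "text,expected",
        [("3", 3), ("3.5", 3.5), ("true", True), ("False", False),
         ("", None), ("left", "left"), ("1e-3", 1e-3)],
    )
    def test_csv_type_inference(self, text, expected):
        assert parse_scalar(text) == expected


class TestFactorialDesign:
    def test_example_two_by_two_by_two_times_ten(self):
        spec = DesignSpec(
            factors={"pos": ["L", "R"], "cue": ["pro", "anti"], "fb": ["on", "off"]},
            repetitions=10,
        )
        trials = make_factorial_design(spec)
        assert len(trials) == 80
        combos = {(t.params["pos"], t.params["cue"], t.params["fb"]) for t in trials}
        assert len(combos) == 8

    def test_degenerate_single_cell(self):
        trials = make_factorial_design(DesignSpec(factors={"a": [1]}, repetitions=1))
        assert len(trials) == 1
        assert trials[0].params == {"a": 1, "repetition": 1}

    def test_each_level_appears_repetitions_times(self):
        trials = make_factorial_design(
            DesignSpec(factors={"a": [1, 2, 3]}, repetitions=2)
        )
        assert len(trials) == 6
        for level in (1, 2, 3):
            assert sum(t.params["a"] == level for t in trials) == 2

    def test_every_combination_appears_exactly_repetitions_times(self):
        factors = {"a": [1, 2], "b": ["x", "y", "z"]}
        reps = 3
        trials = make_factorial_design(DesignSpec(factors=factors, repetitions=reps))
        expected = list(itertools.product(factors["a"], factors["b"]))
        counts = {
            combo: sum(
                (t.params["a"], t.params["b"]) == combo for t in trials
            )
            for combo in expected
        }
        assert all(c == reps for c in counts.values())

    def test_last_factor_varies_fastest(self):
        trials = make_factorial_design(
            DesignSpec(factors={"a": [1, 2], "b": ["x", "y"]}, repetitions=1)
        )
        order = [(t.params["a"], t.params["b"]) for t in trials]
        assert order == [(1, "x"), (1, "y"), (2, "x"), (2, "y")]

    def test_empty_factor_rejected(self):
        with pytest.raises(DesignError):
            DesignSpec(factors={"a": []})
        with pytest.raises(DesignError):
            DesignSpec(factors={})


class TestTrialsCsv:
    def test_load_with_type_inference(self, tmp_path):
        path = tmp_path / "trials.csv"
        path.write_text("target_x,cue\n0.3,pro\n-0.3,anti\n")
        trials = load_trials_csv(path)
        assert len(trials) == 2
        assert trials[0].params == {"target_x": 0.3, "cue": "pro"}

    def test_block_column(self, tmp_path):
        path = tmp_path / "trials.csv"
        path.write_text("block,cue\n1,a\n1,b\n2,c\n2,d\n")
        trials = load_trials_csv(path, block_column="block")
        assert [t.block for t in trials] == [1, 1, 2, 2]

    def test_missing_block_column_named_in_error(self, tmp_path):
        path = tmp_path / "trials.csv"
        path.write_text("cue\na\n")
        with pytest.raises(FormatError, match="blk"):
            load_trials_csv(path, block_column="blk")

    def test_ragged_row_named_in_error(self, tmp_path):
        path = tmp_path / "trials.csv"
        path.write_text("a,b\n1,2\n3\n")
        with pytest.raises(FormatError, match="row 3"):
            load_trials_csv(path)

    def test_duplicate_header_rejected(self, tmp_path):
        path = tmp_path / "trials.csv"
        path.write_text("a,a\n1,2\n")
        with pytest.raises(FormatError, match="duplicate"):
            load_trials_csv(path)

    def test_save_load_round_trip_reproduces_params(self, tmp_path):
        trials = make_factorial_design(
            DesignSpec(factors={"x": [0.5, -0.5], "cue": ["pro", "anti"]})
        )
        path = tmp_path / "out.csv"
        save_trials_csv(trials, path)
        reloaded = load_trials_csv(path, block_column="block")
        assert [t.params.to_dict() for t in reloaded] == [
            t.params.to_dict() for t in trials
        ]

    def test_result_key_union_with_empty_cells(self, tmp_path):
        trials = make_factorial_design(DesignSpec(factors={"a": [1, 2]}))
        for t, results in zip(trials, [{"rt": 0.5}, {"rt": 0.6, "err": 1}]):
            t.start()
            t.results.update(results)
            t.finish()
        path = tmp_path / "out.csv"
        save_trials_csv(trials, path)
        lines = path.read_text().splitlines()
        assert lines[0].endswith("rt,err")
        assert lines[1].endswith("0.5,")  # "err" empty in row 1
        assert lines[2].endswith("0.6,1")

    def test_incremental_writer_grows_one_row_per_trial(self, tmp_path):
        trials = make_factorial_design(DesignSpec(factors={"a": [1, 2, 3]}))
        path = tmp_path / "inc.csv"
        writer = IncrementalTrialWriter(path, ["a", "repetition"], ["rt"])
        for i, t in enumerate(trials):
            t.start()
            t.results["rt"] = 0.1 * i
            t.finish()
            writer.append(t)
            assert len(path.read_text().splitlines()) == i + 2


class TestRandomization:
    def _design(self, n=8):
        return make_factorial_design(DesignSpec(factors={"a": list(range(n))}))

    def test_same_seed_gives_identical_permutation(self):
        trials = self._design()
        a = randomize_trials(trials, seed=42)
        b = randomize_trials(trials, seed=42)
        assert [t.index for t in a] == [t.index for t in b]

    def test_global_shuffle_is_a_bijection(self):
        trials = self._design(50)
        shuffled = randomize_trials(trials, seed=1)
        assert sorted(t.index for t in shuffled) == list(range(50))

    def test_within_blocks_preserves_block_sequence(self):
        trials = self._design(4)
        for t, block in zip(trials, [1, 1, 2, 2]):
            t.block = block
        shuffled = randomize_trials(trials, seed=3, within_blocks=True)
        assert [t.block for t in shuffled] == [1, 1, 2, 2]

    def test_within_blocks_never_crosses_blocks(self):
        trials = self._design(30)
        for i, t in enumerate(trials):
            t.block = i % 3
        shuffled = randomize_trials(trials, seed=5, within_blocks=True)
        by_block = {
            b: [t.index for t in shuffled if t.block == b] for b in (0, 1, 2)
        }
        for b, members in by_block.items():
            assert sorted(members) == [i for i in range(30) if i % 3 == b]

    def test_shuffle_preserves_condition_multiset(self):
        spec = DesignSpec(
            factors={"pos": ["L", "R"], "cue": ["pro", "anti"], "fb": ["on", "off"]},
            repetitions=10,
        )
        trials = make_factorial_design(spec)
        shuffled = randomize_trials(trials, seed=9)
        combos = [
            (t.params["pos"], t.params["cue"], t.params["fb"]) for t in shuffled
        ]
        for combo in set(combos):
            assert combos.count(combo) == 10


class TestRunExperiment:
    def _session(self, n=3):
        session = ExperimentSession()
        session.add_trials(
            make_factorial_design(DesignSpec(factors={"a": list(range(n))}))
        )
        return session

    def test_task_call_order_pre_main_post_per_trial(self):
        session = self._session(3)
        calls = []
        run_experiment(
            session,
            main_task=lambda t: calls.append(f"main{t.number}"),
            pre_task=lambda t: calls.append(f"pre{t.number}"),
            post_task=lambda t: calls.append(f"post{t.number}"),
        )
        assert calls == [
            "pre1", "main1", "post1", "pre2", "main2", "post2", "pre3", "main3", "post3"
        ]
        assert [t.status for t in session.trials] == ["done"] * 3
        assert [t.number for t in session.trials] == [1, 2, 3]

    def test_continue_on_error_marks_failed_trial_only(self):
        session = self._session(3)

        def main(trial):
            if trial.number == 2:
                raise ValueError("boom")

        run_experiment(session, main, continue_on_error=True)
        assert [t.status for t in session.trials] == ["done", "error", "done"]
        assert "boom" in session.trials[1].results["error"]

    def test_default_policy_aborts_on_error(self):
        session = self._session(3)

        def main(trial):
            if trial.number == 2:
                raise ValueError("boom")

        with pytest.raises(RunError):
            run_experiment(session, main)
        assert [t.status for t in session.trials] == ["done", "error", "pending"]

    def test_empty_trial_list_rejected(self):
        with pytest.raises(RunError):
            run_experiment(ExperimentSession(), lambda t: None)

    def test_clock_timestamps_used_when_given(self):
        session = self._session(1)
        clock = FrameClock()
        clock.tick(90)
        run_experiment(session, lambda t: clock.tick(10), clock=clock)
        assert session.start_time == pytest.approx(1.0)
        assert session.end_time == pytest.approx(100 / 90)

    def test_results_read_only_until_running(self):
        trial = TrialRecord(index=0)
        with pytest.raises(ParamError):
            trial.results["rt"] = 1.0
        trial.start()
        trial.results["rt"] = 1.0
        trial.finish()
        with pytest.raises(TrialStateError):
            trial.start()


class TestSessionJson:
    def test_empty_session_round_trip(self, tmp_path):
        session = ExperimentSession(metadata=ParamSet(participant="P01"))
        path = tmp_path / "s.json"
        save_session_json(session, path)
        again = load_session_json(path)
        assert session_to_dict(again) == session_to_dict(session)

    def test_session_with_trials_and_results_round_trip(self, tmp_path):
        session = ExperimentSession(config=ParamSet(continue_on_error=False))
        session.add_trials(
            make_factorial_design(DesignSpec(factors={"a": [1, 2]}))
        )
        run_experiment(session, lambda t: t.results.update({"rt": 0.5 * t.number}))
        path = tmp_path / "s.json"
        save_session_json(session, path)
        again = load_session_json(path)
        assert session_to_dict(again) == session_to_dict(session)
        assert again.trials[1].results["rt"] == 1.0

    def test_unserializable_value_names_key_path(self):
        session = ExperimentSession()
        session.metadata._data["bad"] = {"deep": object()}  # bypass checks
        with pytest.raises(SerializationError, match="metadata.bad.deep"):
            session_to_dict(session)
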