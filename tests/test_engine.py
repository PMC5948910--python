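"""Stability, day counting, the advancement/restart rules, and ingest."""

import json

import pytest

import nof1zones as nz
from nof1zones.engine import AttemptStatus, Reason, Verdict
from nof1zones.scenarios import fully_adherent_participant
from nof1zones.specs import Zone

from conftest import make_attempt


def likert_attempt(outcomes, stage=2, zone=Zone.O2, behavior=7.5):
    return make_attempt(stage, zone, [(True, behavior, y) for y in outcomes])


class TestStability:
    def test_three_point_likert_range_is_stable(self, sleep_spec):
        assert nz.is_output_stable(sleep_spec, likert_attempt([4, 5, 6, 7]))

    def test_four_point_likert_range_is_unstable(self, sleep_spec):
        assert not nz.is_output_stable(sleep_spec, likert_attempt([2, 6]))

    def test_efficiency_tolerance_is_ten_points(self, steps_spec):
        stable = make_attempt(2, Zone.O2, [(True, 11000, 82.0), (True, 11000, 91.0)])
        unstable = make_attempt(2, Zone.O2, [(True, 11000, 82.0), (True, 11000, 93.0)])
        assert nz.is_output_stable(steps_spec, stable)
        assert not nz.is_output_stable(steps_spec, unstable)

    def test_requires_at_least_one_outcome(self, sleep_spec):
        attempt = make_attempt(2, Zone.O2, [(False, None, None)])
        with pytest.raises(ValueError):
            nz.is_output_stable(sleep_spec, attempt)


class TestCountStageDays:
    def test_all_in_range(self, sleep_spec):
        attempt = likert_attempt([4] * 5)
        assert nz.count_stage_days(sleep_spec, attempt) == (5, 5, 0)

    def test_two_out_of_range_days(self, sleep_spec):
        days = [(True, 7.5 if i not in (1, 4) else 5.0, 4) for i in range(7)]
        attempt = make_attempt(2, Zone.O2, days)
        assert nz.count_stage_days(sleep_spec, attempt) == (7, 5, 0)

    def test_longest_missed_run(self, sleep_spec):
        days = [(True, 7.5, 4), (False, None, None), (False, None, None), (True, 7.5, 4)]
        attempt = make_attempt(2, Zone.O2, days)
        assert nz.count_stage_days(sleep_spec, attempt) == (4, 2, 2)

    def test_baseline_counts_any_recorded_behavior(self, sleep_spec):
        days = [(True, 5.0, 4), (True, 9.9, 4), (True, None, 4)]
        attempt = make_attempt(1, None, days)
        assert nz.count_stage_days(sleep_spec, attempt) == (3, 2, 0)


class TestEvaluateStage:
    def test_five_stable_in_range_days_advance(self, sleep_spec):
        decision = nz.evaluate_stage(sleep_spec, likert_attempt([4] * 5))
        assert decision.verdict is Verdict.ADVANCE
        assert decision.reason is Reason.IN_RANGE_AND_STABLE

    def test_day7_with_four_in_range_advances_even_if_unstable(self, sleep_spec):
        days = [(True, 7.5, 1 if i % 2 else 7) for i in range(4)]
        days += [(True, 5.0, 4)] * 3
        decision = nz.evaluate_stage(sleep_spec, make_attempt(2, Zone.O2, days))
        assert decision.verdict is Verdict.ADVANCE
        assert decision.reason is Reason.DAY7_ENOUGH_IN_RANGE

    def test_day7_with_three_in_range_restarts(self, sleep_spec):
        days = [(True, 7.5, 4)] * 3 + [(True, 5.0, 4)] * 4
        decision = nz.evaluate_stage(sleep_spec, make_attempt(2, Zone.O2, days))
        assert decision.verdict is Verdict.RESTART
        assert decision.reason is Reason.DAY7_TOO_FEW_IN_RANGE

    def test_six_days_five_in_range_stable_advances(self, sleep_spec):
        days = [(True, 5.0, 4)] + [(True, 7.5, 4)] * 5
        decision = nz.evaluate_stage(sleep_spec, make_attempt(2, Zone.O2, days))
        assert decision.verdict is Verdict.ADVANCE
        assert decision.reason is Reason.IN_RANGE_AND_STABLE

    def test_unstable_in_range_stage_waits_for_day7(self, sleep_spec):
        attempt = likert_attempt([1, 7, 1, 7, 1, 7])
        assert nz.evaluate_stage(sleep_spec, attempt).verdict is Verdict.CONTINUE
        attempt = likert_attempt([1, 7, 1, 7, 1, 7, 1])
        decision = nz.evaluate_stage(sleep_spec, attempt)
        assert decision.verdict is Verdict.ADVANCE
        assert decision.reason is Reason.DAY7_UNSTABLE

    def test_two_consecutive_missed_days_restart(self, sleep_spec):
        days = [(True, 7.5, 4), (False, None, None), (False, None, None)]
        decision = nz.evaluate_stage(sleep_spec, make_attempt(2, Zone.O2, days))
        assert decision.verdict is Verdict.RESTART
        assert decision.reason is Reason.MISSED_CHECKINS

    def test_separated_missed_days_do_not_restart_by_default(self, sleep_spec):
        days = [(False, None, None), (True, 7.5, 4), (False, None, None)]
        decision = nz.evaluate_stage(sleep_spec, make_attempt(2, Zone.O2, days))
        assert decision.verdict is Verdict.CONTINUE

    def test_cumulative_missed_policy_counts_all_misses(self, sleep_spec):
        spec = sleep_spec.model_copy(update={"missed_policy": "cumulative"})
        days = [(False, None, None), (True, 7.5, 4), (False, None, None)]
        decision = nz.evaluate_stage(spec, make_attempt(2, Zone.O2, days))
        assert decision.verdict is Verdict.RESTART
        assert decision.reason is Reason.MISSED_CHECKINS

    def test_stage4_advance_completes_experiment(self, sleep_spec):
        decision = nz.evaluate_stage(sleep_spec, likert_attempt([4] * 5, stage=4))
        assert decision.verdict is Verdict.EXPERIMENT_COMPLETE

    def test_terminal_attempt_rejected(self, sleep_spec):
        attempt = likert_attempt([4] * 5)
        attempt.status = AttemptStatus.COMPLETED
        with pytest.raises(ValueError):
            nz.evaluate_stage(sleep_spec, attempt)


class TestIngestDay:
    def test_fully_adherent_completes_in_twenty_days(self, sleep_spec):
        run = nz.run_experiment(sleep_spec, fully_adherent_participant(sleep_spec))
        assert run.completed and run.duration_days == 20

    def test_missed_pair_restarts_and_resets_day_counter(self, sleep_spec):
        state = nz.ExperimentState.new(sleep_spec)
        for day in (1, 2):
            nz.ingest_day(state, nz.CheckInRecord(day, True, 7.5, 4))
        for day in (3, 4):
            _, decision = nz.ingest_day(state, nz.CheckInRecord(day, False))
        assert decision.verdict is Verdict.RESTART
        assert state.attempts[0].status is AttemptStatus.RESTARTED
        fresh = state.current_attempt
        assert (fresh.stage_number, fresh.attempt_index, len(fresh.records)) == (1, 2, 0)

    def test_baseline_advance_fixes_plan(self, sleep_spec):
        state = nz.ExperimentState.new(sleep_spec)
        for day in range(1, 6):
            nz.ingest_day(state, nz.CheckInRecord(day, True, 6.75, 4))
        assert state.baseline_mean == pytest.approx(6.75)
        assert state.plan.targets == (Zone.O3, Zone.O1, Zone.O2)
        assert state.current_attempt.target_zone is Zone.O3

    def test_out_of_order_day_rejected(self, sleep_spec):
        state = nz.ExperimentState.new(sleep_spec)
        nz.ingest_day(state, nz.CheckInRecord(1, True, 7.5, 4))
        with pytest.raises(ValueError):
            nz.ingest_day(state, nz.CheckInRecord(3, True, 7.5, 4))

    def test_ingest_after_completion_rejected(self, sleep_spec):
        run = nz.run_experiment(sleep_spec, fully_adherent_participant(sleep_spec))
        with pytest.raises(ValueError):
            nz.ingest_day(run.state, nz.CheckInRecord(21, True, 7.5, 4))

    def test_outcome_scale_bounds_enforced(self, sleep_spec, steps_spec):
        state = nz.ExperimentState.new(sleep_spec)
        with pytest.raises(ValueError):
            nz.ingest_day(state, nz.CheckInRecord(1, True, 7.5, 9))
        with pytest.raises(ValueError):
            nz.ingest_day(state, nz.CheckInRecord(1, True, 7.5, 4.5))
        state = nz.ExperimentState.new(steps_spec)
        nz.ingest_day(state, nz.CheckInRecord(1, True, 11000, 91.5))  # percents may be fractional

    def test_record_invariant_no_outcome_without_checkin(self):
        with pytest.raises(ValueError):
            nz.CheckInRecord(1, False, None, 4)

    def test_completed_attempt_shape_invariants(self, sleep_spec):
        """No completed attempt has under 4 in-range days or over 7 days."""
        import numpy as np

        from conftest import random_participant

        rng = np.random.default_rng(11)
        for _ in range(50):
            run = nz.run_experiment(
                sleep_spec, random_participant(sleep_spec, rng), max_days=84,
                seed=int(rng.integers(2**31)),
            )
            for attempt in run.state.completed_attempts():
                days, in_range, _ = nz.count_stage_days(sleep_spec, attempt)
                assert 4 <= in_range <= days <= 7
            if run.completed:
                stages = [a.stage_number for a in run.state.completed_attempts()]
                assert stages == [1, 2, 3, 4]


class TestPersistenceAndReplay:
    def test_state_round_trips_through_json(self, sleep_spec, tmp_path):
        run = nz.run_experiment(sleep_spec, fully_adherent_participant(sleep_spec))
        path = tmp_path / "state.json"
        nz.save_state(run.state, path)
        assert nz.load_state(path).to_dict() == run.state.to_dict()

    def test_replay_determinism(self, sleep_spec):
        """Ingesting the same record sequence twice yields identical states."""
        records = [r for r in nz.scenarios.multi_restart_sleep_days()]
        state_a, decisions_a = nz.replay(sleep_spec, records)
        state_b, decisions_b = nz.replay(sleep_spec, records)
        assert json.dumps(state_a.to_dict(), sort_keys=True) == json.dumps(
            state_b.to_dict(), sort_keys=True
        )
        assert decisions_a == decisions_b

    def test_unsupported_state_version_rejected(self, sleep_spec, tmp_path):
        run = nz.run_experiment(sleep_spec, fully_adherent_participant(sleep_spec))
        data = run.state.to_dict()
        data["version"] = 99
        with pytest.raises(ValueError):
            nz.ExperimentState.from_dict(data)
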