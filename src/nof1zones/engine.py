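"""The daily check-in state machine.

Each calendar day produces one :class:`CheckInRecord`; ingesting it
appends the record to the current stage attempt and immediately
evaluates the stage rules:

1. at least five days in the target range and a stable outcome
   (within-stage outcome range at most the stability tolerance)
   advances the stage;
2. at the seven-day cap, four or more in-range days advance the stage
   (whether the shortfall was one in-range day or an unstable outcome),
   while three or fewer restart it;
3. two consecutive missed check-ins restart the stage at once.

The baseline stage has no target, so every checked-in day with a
recorded behavior value counts as in range there.  When the baseline
completes, the mean baseline behavior is classified and the
intervention ordering is fixed (see :mod:`nof1zones.scheduler`); an
advance out of stage 4 completes the experiment.  Restarted attempts
keep their records for audit but are excluded from analysis.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from statistics import fmean
from typing import List, Optional, Tuple

from .scheduler import StagePlan, classify_baseline, stage_targets
from .specs import ExperimentSpec, Zone, in_target_range

__all__ = [
    "CheckInRecord",
    "StageAttempt",
    "ExperimentState",
    "Verdict",
    "Reason",
    "StageDecision",
    "is_output_stable",
    "count_stage_days",
    "evaluate_stage",
    "ingest_day",
    "save_state",
    "load_state",
    "STATE_FORMAT_VERSION",
]

logger = logging.getLogger(__name__)

STATE_FORMAT_VERSION = 1


@dataclass
class CheckInRecord:
    """One calendar day's observation.

    ``behavior_value`` may be present without a check-in (a passively
    sensed quantity), but outcome and self-reported adherence exist
    only on checked-in days.
    """

    day_index: int
    checked_in: bool
    behavior_value: Optional[float] = None
    outcome_value: Optional[float] = None
    self_adherence: Optional[int] = None

    def __post_init__(self) -> None:
        if self.day_index < 1:
            raise ValueError("day_index is 1-based")
        if not self.checked_in and (self.outcome_value is not None or self.self_adherence is not None):
            raise ValueError("a day without a check-in cannot carry an outcome or self-adherence")
        if self.self_adherence is not None and not 1 <= self.self_adherence <= 7:
            raise ValueError("self_adherence is a 1-7 Likert rating")

    def to_dict(self) -> dict:
        return {
            "day_index": self.day_index,
            "checked_in": self.checked_in,
            "behavior_value": self.behavior_value,
            "outcome_value": self.outcome_value,
            "self_adherence": self.self_adherence,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CheckInRecord":
        return cls(
            day_index=d["day_index"],
            checked_in=d["checked_in"],
            behavior_value=d.get("behavior_value"),
            outcome_value=d.get("outcome_value"),
            self_adherence=d.get("self_adherence"),
        )


class AttemptStatus(str, Enum):
    IN_PROGRESS = "in_progress"
    COMPLETED = "completed"
    RESTARTED = "restarted"


@dataclass
class StageAttempt:
    """One attempt at one stage (restarts open fresh attempts)."""

    stage_number: int
    target_zone: Optional[Zone]  # None for the baseline stage
    attempt_index: int = 1
    records: List[CheckInRecord] = field(default_factory=list)
    status: AttemptStatus = AttemptStatus.IN_PROGRESS

    def to_dict(self) -> dict:
        return {
            "stage_number": self.stage_number,
            "target_zone": self.target_zone.value if self.target_zone else None,
            "attempt_index": self.attempt_index,
            "records": [r.to_dict() for r in self.records],
            "status": self.status.value,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StageAttempt":
        return cls(
            stage_number=d["stage_number"],
            target_zone=Zone(d["target_zone"]) if d["target_zone"] else None,
            attempt_index=d["attempt_index"],
            records=[CheckInRecord.from_dict(r) for r in d["records"]],
            status=AttemptStatus(d["status"]),
        )


@dataclass
class ExperimentState:
    """Full trajectory of one self-experiment."""

    spec: ExperimentSpec
    attempts: List[StageAttempt] = field(default_factory=list)
    baseline_mean: Optional[float] = None
    plan: Optional[StagePlan] = None
    completed: bool = False

    @classmethod
    def new(cls, spec: ExperimentSpec) -> "ExperimentState":
        return cls(spec=spec, attempts=[StageAttempt(stage_number=1, target_zone=None)])

    @property
    def current_attempt(self) -> StageAttempt:
        if self.completed:
            raise ValueError("experiment is complete; no attempt in progress")
        return self.attempts[-1]

    @property
    def total_days(self) -> int:
        return sum(len(a.records) for a in self.attempts)

    def completed_attempts(self) -> List[StageAttempt]:
        return [a for a in self.attempts if a.status is AttemptStatus.COMPLETED]

    def to_dict(self) -> dict:
        return {
            "version": STATE_FORMAT_VERSION,
            "spec": self.spec.model_dump(mode="json"),
            "attempts": [a.to_dict() for a in self.attempts],
            "baseline_mean": self.baseline_mean,
            "plan": self.plan.to_dict() if self.plan else None,
            "completed": self.completed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentState":
        version = d.get("version")
        if version != STATE_FORMAT_VERSION:
            raise ValueError(f"unsupported state-file version {version!r}")
        return cls(
            spec=ExperimentSpec.model_validate(d["spec"]),
            attempts=[StageAttempt.from_dict(a) for a in d["attempts"]],
            baseline_mean=d.get("baseline_mean"),
            plan=StagePlan.from_dict(d["plan"]) if d.get("plan") else None,
            completed=d["completed"],
        )


class Verdict(str, Enum):
    CONTINUE = "continue"
    ADVANCE = "advance"
    RESTART = "restart"
    EXPERIMENT_COMPLETE = "experiment_complete"


class Reason(str, Enum):
    IN_RANGE_AND_STABLE = "in_range_and_stable"
    DAY7_ENOUGH_IN_RANGE = "day7_enough_in_range"
    DAY7_UNSTABLE = "day7_unstable"
    DAY7_TOO_FEW_IN_RANGE = "day7_too_few_in_range"
    MISSED_CHECKINS = "missed_checkins"
    NOT_YET = "not_yet"


@dataclass(frozen=True)
class StageDecision:
    verdict: Verdict
    reason: Reason


def _outcomes(attempt: StageAttempt) -> List[float]:
    return [r.outcome_value for r in attempt.records if r.checked_in and r.outcome_value is not None]


def is_output_stable(spec: ExperimentSpec, attempt: StageAttempt) -> bool:
    """Whether the attempt's outcomes so far span at most the tolerance.

    The range runs over every checked-in day of the attempt with an
    outcome value; the tolerance bound is inclusive (a Likert range of
    exactly 3 points still counts as stable).
    """
    outcomes = _outcomes(attempt)
    if not outcomes:
        raise ValueError("no outcome values recorded in this attempt")
    return max(outcomes) - min(outcomes) <= spec.stability_tolerance


def _record_in_range(spec: ExperimentSpec, attempt: StageAttempt, record: CheckInRecord) -> bool:
    if not record.checked_in or record.behavior_value is None:
        return False
    if attempt.stage_number == 1:
        return True  # baseline: any recorded behavior counts
    return in_target_range(spec, attempt.target_zone, record.behavior_value)


def count_stage_days(spec: ExperimentSpec, attempt: StageAttempt) -> Tuple[int, int, int]:
    """(days elapsed, in-range days, longest run of missed check-ins)."""
    days_elapsed = len(attempt.records)
    in_range = sum(_record_in_range(spec, attempt, r) for r in attempt.records)
    longest = current = 0
    for r in attempt.records:
        current = current + 1 if not r.checked_in else 0
        longest = max(longest, current)
    return days_elapsed, in_range, longest


def evaluate_stage(spec: ExperimentSpec, attempt: StageAttempt) -> StageDecision:
    """Apply the advancement/restart rules to the attempt as it stands.

    Rule precedence: the missed-check-in restart preempts everything,
    then early advancement (in-range + stable), then the 7-day-cap
    rules.  An advance out of stage 4 is reported as experiment
    completion.
    """
    if attempt.status is not AttemptStatus.IN_PROGRESS:
        raise ValueError("cannot evaluate a terminal attempt")
    days, in_range, longest_missed = count_stage_days(spec, attempt)
    total_missed = sum(not r.checked_in for r in attempt.records)
    missed_metric = longest_missed if spec.missed_policy == "consecutive" else total_missed
    if missed_metric >= spec.max_missed_consecutive:
        return StageDecision(Verdict.RESTART, Reason.MISSED_CHECKINS)
    outcomes = _outcomes(attempt)
    stable = is_output_stable(spec, attempt) if outcomes else True
    advance = Verdict.EXPERIMENT_COMPLETE if attempt.stage_number == 4 else Verdict.ADVANCE
    if days >= spec.min_stage_days and in_range >= spec.min_stage_days and stable:
        return StageDecision(advance, Reason.IN_RANGE_AND_STABLE)
    if days >= spec.max_stage_days:
        if in_range >= spec.min_stage_days:
            return StageDecision(advance, Reason.DAY7_UNSTABLE)
        if in_range >= spec.min_in_range_days_at_cap:
            return StageDecision(advance, Reason.DAY7_ENOUGH_IN_RANGE)
        return StageDecision(Verdict.RESTART, Reason.DAY7_TOO_FEW_IN_RANGE)
    return StageDecision(Verdict.CONTINUE, Reason.NOT_YET)


def _validate_outcome(spec: ExperimentSpec, record: CheckInRecord) -> None:
    if record.outcome_value is None:
        return
    lo, hi = spec.outcome_bounds
    v = record.outcome_value
    if not lo <= v <= hi:
        raise ValueError(f"outcome {v} outside the {spec.outcome_scale} bounds [{lo}, {hi}]")
    if spec.outcome_scale == "likert7" and v != int(v):
        raise ValueError(f"likert outcomes are integers 1-7, got {v}")


def ingest_day(state: ExperimentState, record: CheckInRecord) -> Tuple[ExperimentState, StageDecision]:
    """Append one calendar day and run the stage rules.

    Mutates ``state`` in place and returns it with the decision.  On a
    baseline advance the baseline mean is computed and the intervention
    plan fixed; on a restart a fresh attempt of the same stage opens
    the next day; an advance out of stage 4 completes the experiment.
    """
    if state.completed:
        raise ValueError("experiment already completed")
    if record.day_index != state.total_days + 1:
        raise ValueError(
            f"out-of-order day_index {record.day_index}; expected {state.total_days + 1}"
        )
    _validate_outcome(state.spec, record)
    attempt = state.current_attempt
    attempt.records.append(record)
    decision = evaluate_stage(state.spec, attempt)
    logger.info(
        "day %d stage %d attempt %d: %s (%s)",
        record.day_index, attempt.stage_number, attempt.attempt_index,
        decision.verdict.value, decision.reason.value,
    )
    if decision.verdict is Verdict.RESTART:
        attempt.status = AttemptStatus.RESTARTED
        state.attempts.append(
            StageAttempt(
                stage_number=attempt.stage_number,
                target_zone=attempt.target_zone,
                attempt_index=attempt.attempt_index + 1,
            )
        )
    elif decision.verdict in (Verdict.ADVANCE, Verdict.EXPERIMENT_COMPLETE):
        attempt.status = AttemptStatus.COMPLETED
        if attempt.stage_number == 1:
            values = [
                r.behavior_value
                for r in attempt.records
                if r.checked_in and r.behavior_value is not None
            ]
            state.baseline_mean = fmean(values)
            state.plan = stage_targets(
                classify_baseline(state.spec, state.baseline_mean), table=state.spec.stage_order
            )
        if attempt.stage_number == 4:
            state.completed = True
        else:
            next_stage = attempt.stage_number + 1
            state.attempts.append(
                StageAttempt(
                    stage_number=next_stage,
                    target_zone=state.plan.target_for_stage(next_stage),
                )
            )
    return state, decision


def save_state(state: ExperimentState, path: str | Path) -> None:
    """Persist the state as JSON, atomically (write-then-rename)."""
    path = Path(path)
    payload = json.dumps(state.to_dict(), indent=2, sort_keys=True) + "\n"
    fd, tmp = tempfile.mkstemp(dir=path.parent or Path("."), prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(payload)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def load_state(path: str | Path) -> ExperimentState:
    """Load a persisted experiment state."""
    with open(path) as fh:
        return ExperimentState.from_dict(json.load(fh))
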