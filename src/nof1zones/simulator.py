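"""Synthetic participants and end-to-end simulated experiments.

A :class:`ParticipantModel` emulates the behavior patterns seen in real
self-experimenters: they check in on a given fraction of days, attempt
the day's target with a given probability (otherwise falling back to
habit), and report an outcome drawn from a peaked (quadratic) response
around a true optimal behavior ``b_star`` plus noise.  The quadratic
response is a testability device — it gives the engine a ground truth
to recover — not a behavioral claim.

A :class:`ScriptedParticipant` instead plays back an explicit per-day
table, which is how the worked boundary cases (fastest possible
completion, 4-of-7 stages, all-unstable stages) are driven.  Random and
scripted participants share the same ingest path through the engine.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .analysis import ExperimentResult, experiment_result
from .engine import CheckInRecord, ExperimentState, StageDecision, ingest_day
from .scheduler import DailyGoal, daily_goal
from .specs import ExperimentSpec, Zone, zone_interval

__all__ = [
    "QuadraticOutcome",
    "ParticipantModel",
    "ScriptedParticipant",
    "SimulationRun",
    "CompletionStats",
    "simulate_day",
    "run_experiment",
    "completion_stats",
    "discretize_outcome",
]


class QuadraticOutcome(BaseModel):
    """Expected outcome as a downward parabola in the behavior value.

    ``expected(b) = level + amplitude * (1 - ((b - b_star) / width)**2)``,
    peaking at ``b_star`` with value ``level + amplitude`` and falling
    back to ``level`` at ``b_star +/- width``.  ``amplitude = 0`` gives
    a flat (null) response.
    """

    model_config = ConfigDict(frozen=True)

    b_star: float
    amplitude: float = 0.0
    level: float = 4.0
    width: float = Field(default=1.0, gt=0)

    def expected(self, behavior: float) -> float:
        z = (behavior - self.b_star) / self.width
        return self.level + self.amplitude * (1.0 - z * z)


class ParticipantModel(BaseModel):
    """Stochastic day-by-day behavior of a synthetic participant."""

    model_config = ConfigDict(frozen=True)

    habitual_mean: float
    habitual_sd: float = Field(ge=0)
    p_checkin: float = Field(ge=0, le=1)
    p_comply: float = Field(ge=0, le=1)
    comply_sd: float = Field(ge=0)
    outcome_model: QuadraticOutcome
    outcome_noise_sd: float = Field(default=0.0, ge=0)
    seed: int = 0


def discretize_outcome(spec: ExperimentSpec, raw: float) -> float:
    """Map a raw outcome draw onto the spec's outcome scale.

    Likert outcomes are rounded half-up to integers and clipped to
    [1, 7]; efficiencies are clipped to [0, 100] and stay continuous.
    """
    if spec.outcome_scale == "likert7":
        return float(min(7, max(1, math.floor(raw + 0.5))))
    return float(min(100.0, max(0.0, raw)))


def simulate_day(
    spec: ExperimentSpec,
    participant: ParticipantModel,
    goal: DailyGoal,
    rng: np.random.Generator,
    day_index: int,
) -> CheckInRecord:
    """Draw one day: check-in, behavior, outcome, self-adherence.

    During the baseline stage behavior always comes from the habitual
    distribution (there is no target to comply with); in intervention
    stages a compliance draw decides between aiming at the target
    center and habit.  Behavior values are truncated at zero.  A missed
    day carries no data at all.
    """
    if rng.random() >= participant.p_checkin:
        return CheckInRecord(day_index=day_index, checked_in=False)
    complied = False
    if goal.target_center is not None and rng.random() < participant.p_comply:
        behavior = rng.normal(goal.target_center, participant.comply_sd)
        complied = True
    else:
        behavior = rng.normal(participant.habitual_mean, participant.habitual_sd)
    behavior = max(0.0, float(behavior))
    raw = participant.outcome_model.expected(behavior) + rng.normal(0.0, participant.outcome_noise_sd)
    self_adherence = 4 if goal.target_center is None else (6 if complied else 2)
    return CheckInRecord(
        day_index=day_index,
        checked_in=True,
        behavior_value=behavior,
        outcome_value=discretize_outcome(spec, raw),
        self_adherence=self_adherence,
    )


@dataclass
class ScriptedParticipant:
    """Plays back an explicit day table instead of sampling.

    ``days`` holds one :class:`CheckInRecord` per calendar day; the
    stored ``day_index`` values are ignored and reassigned sequentially
    so tables can be built stage by stage.
    """

    days: List[CheckInRecord]

    def record_for(self, day_index: int) -> CheckInRecord:
        template = self.days[day_index - 1]
        return CheckInRecord(
            day_index=day_index,
            checked_in=template.checked_in,
            behavior_value=template.behavior_value,
            outcome_value=template.outcome_value,
            self_adherence=template.self_adherence,
        )

    def __len__(self) -> int:
        return len(self.days)


Participant = Union[ParticipantModel, ScriptedParticipant]


@dataclass
class SimulationRun:
    """Outcome of one simulated experiment."""

    state: ExperimentState
    decisions: List[StageDecision] = field(default_factory=list)
    completed: bool = False
    duration_days: int = 0
    result: Optional[ExperimentResult] = None

    def serialize(self) -> str:
        """Canonical JSON of the run (used for determinism checks)."""
        payload = {
            "state": self.state.to_dict(),
            "decisions": [[d.verdict.value, d.reason.value] for d in self.decisions],
            "completed": self.completed,
            "duration_days": self.duration_days,
        }
        return json.dumps(payload, sort_keys=True)


def run_experiment(
    spec: ExperimentSpec,
    participant: Participant,
    max_days: int = 84,
    seed: Optional[int] = None,
) -> SimulationRun:
    """Run one full simulated experiment through the daily engine.

    Days are generated and ingested one at a time until the experiment
    completes, ``max_days`` elapse, or a scripted participant's table
    runs out.  Identical (spec, participant, seed) gives an identical
    run.
    """
    scripted = isinstance(participant, ScriptedParticipant)
    if scripted:
        max_days = min(max_days, len(participant))
    elif max_days < 20:
        raise ValueError("max_days must allow at least the 20-day minimum experiment")
    rng = np.random.default_rng(seed if seed is not None else getattr(participant, "seed", 0))
    state = ExperimentState.new(spec)
    run = SimulationRun(state=state)
    for day in range(1, max_days + 1):
        goal = daily_goal(state)
        if scripted:
            record = participant.record_for(day)
        else:
            record = simulate_day(spec, participant, goal, rng, day)
        _, decision = ingest_day(state, record)
        run.decisions.append(decision)
        run.duration_days = day
        if state.completed:
            break
    run.completed = state.completed
    if run.completed:
        run.result = experiment_result(state)
    return run


@dataclass(frozen=True)
class CompletionStats:
    """Monte-Carlo summary over independent replicate experiments."""

    n_reps: int
    completion_rate: float
    durations: tuple  # durations of completed runs, in days
    zone_recovery_rate: Optional[float]  # fraction of completed runs recovering b_star's zone
    runs: tuple  # one summary dict per replicate

    def duration_summary(self) -> dict:
        if not self.durations:
            return {"n": 0}
        arr = np.asarray(self.durations, dtype=float)
        return {
            "n": len(arr),
            "mean": float(arr.mean()),
            "median": float(np.median(arr)),
            "min": float(arr.min()),
            "max": float(arr.max()),
        }


def completion_stats(
    spec: ExperimentSpec,
    participant: ParticipantModel,
    n_reps: int,
    max_days: int = 42,
    seed: int = 0,
) -> CompletionStats:
    """Replicate ``run_experiment`` over independent seeds and summarize.

    Zone recovery asks whether a completed run's optimal zone contains
    the participant's true optimal behavior ``b_star``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_reps) & 0x7FFFFFFF
    b_star = participant.outcome_model.b_star
    runs = []
    durations = []
    recovered = 0
    completed = 0
    for rep_seed in child_seeds:
        run = run_experiment(spec, participant, max_days=max_days, seed=int(rep_seed))
        row = {
            "seed": int(rep_seed),
            "completed": run.completed,
            "duration_days": run.duration_days,
            "days_used": run.result.days_used if run.result else None,
            "optimal_stage": run.result.optimal_stage if run.result else None,
            "optimal_zone": run.result.optimal_zone.value if run.result else None,
        }
        runs.append(row)
        if run.completed:
            completed += 1
            durations.append(run.duration_days)
            if b_star in zone_interval(spec, run.result.optimal_zone):
                recovered += 1
    return CompletionStats(
        n_reps=n_reps,
        completion_rate=completed / n_reps,
        durations=tuple(durations),
        zone_recovery_rate=(recovered / completed) if completed else None,
        runs=tuple(runs),
    )


def load_participant(path) -> ParticipantModel:
    """Read a participant model from YAML or JSON."""
    import yaml
    from pathlib import Path

    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return ParticipantModel.model_validate(data)
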