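"""Final analysis of a self-experiment.

Only *valid* days enter the result: checked-in days with both a
behavior value inside the stage's zone and a recorded outcome.  For
intervention stages the zone is the assigned target; for the baseline
stage, which has no target, valid days are filtered post hoc to the
zone containing the final baseline mean (the open Under/Over interval
if the mean lands there).  Each completed stage contributes the mean
outcome over its valid days; the stage whose mean is best under the
experiment's optimization direction names the personalized optimal
zone, reported with its zone center (or, for a winning baseline, the
baseline mean itself) as the recommended behavior level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from statistics import fmean, median
from typing import List, Optional, Tuple

from .engine import AttemptStatus, CheckInRecord, ExperimentState, StageAttempt
from .scheduler import classify_baseline
from .specs import ExperimentSpec, Zone, zone_interval

__all__ = [
    "StageResult",
    "ExperimentResult",
    "AdherenceSummary",
    "valid_days",
    "experiment_result",
    "adherence_summary",
    "report_dict",
    "report_text",
]


@dataclass(frozen=True)
class StageResult:
    stage_number: int
    zone: Zone
    valid_day_indices: Tuple[int, ...]
    mean_outcome: Optional[float]  # None when no valid day survives filtering

    @property
    def n_valid(self) -> int:
        return len(self.valid_day_indices)


@dataclass(frozen=True)
class ExperimentResult:
    stage_results: Tuple[StageResult, StageResult, StageResult, StageResult]
    optimal_stage: int
    optimal_zone: Zone
    optimal_target_value: float
    days_used: int
    tie: bool


@dataclass(frozen=True)
class AdherenceSummary:
    check_in_rate: float
    objective_rate: Optional[float]  # None before any intervention day exists
    median_self_adherence: Optional[float]


def valid_days(
    spec: ExperimentSpec, attempt: StageAttempt, baseline_zone: Optional[Zone] = None
) -> List[CheckInRecord]:
    """Records of a completed attempt that enter the analysis.

    Intervention stages filter on the attempt's target zone; the
    baseline stage needs ``baseline_zone`` (the zone of the final
    baseline mean).  A day lacking either the behavior value or the
    outcome can never be valid.
    """
    if attempt.status is not AttemptStatus.COMPLETED:
        raise ValueError("valid days are defined only for completed attempts")
    zone = attempt.target_zone if attempt.stage_number != 1 else baseline_zone
    if zone is None:
        raise ValueError("baseline_zone is required for the baseline stage")
    interval = zone_interval(spec, zone)
    return [
        r
        for r in attempt.records
        if r.checked_in
        and r.behavior_value is not None
        and r.outcome_value is not None
        and r.behavior_value in interval
    ]


def experiment_result(state: ExperimentState) -> ExperimentResult:
    """Per-stage means over valid days and the optimal zone.

    Ties between stage means are broken toward the lower stage number
    and flagged.  A stage left with no valid days after filtering (a
    baseline edge case) is excluded from the optimum.
    """
    if not state.completed:
        raise ValueError("analysis requires a completed experiment")
    spec = state.spec
    baseline_zone = classify_baseline(spec, state.baseline_mean)
    results: List[StageResult] = []
    for stage in (1, 2, 3, 4):
        attempt = next(
            a
            for a in state.completed_attempts()
            if a.stage_number == stage
        )
        days = valid_days(spec, attempt, baseline_zone)
        zone = baseline_zone if stage == 1 else attempt.target_zone
        mean = fmean(r.outcome_value for r in days) if days else None
        results.append(
            StageResult(
                stage_number=stage,
                zone=zone,
                valid_day_indices=tuple(r.day_index for r in days),
                mean_outcome=mean,
            )
        )
    scored = [r for r in results if r.mean_outcome is not None]
    best = max if spec.optimization == "maximize" else min
    best_mean = best(r.mean_outcome for r in scored)
    winners = [r for r in scored if r.mean_outcome == best_mean]
    winner = winners[0]  # lowest stage number wins a tie
    optimal_value = (
        state.baseline_mean if winner.stage_number == 1 else spec.zone_centers[winner.zone]
    )
    return ExperimentResult(
        stage_results=tuple(results),
        optimal_stage=winner.stage_number,
        optimal_zone=winner.zone,
        optimal_target_value=optimal_value,
        days_used=sum(r.n_valid for r in results),
        tie=len(winners) > 1,
    )


def adherence_summary(state: ExperimentState) -> AdherenceSummary:
    """Check-in rate, objective (in-target-range) rate and median self-report.

    The check-in rate runs over every elapsed calendar day; the
    objective rate over intervention-stage days only (the baseline has
    no target to adhere to); the self-adherence median over every
    checked-in day that rated it.
    """
    all_records = [r for a in state.attempts for r in a.records]
    if not all_records:
        raise ValueError("no days ingested yet")
    check_in_rate = sum(r.checked_in for r in all_records) / len(all_records)
    intervention = [
        (a, r) for a in state.attempts if a.stage_number != 1 for r in a.records
    ]
    objective_rate: Optional[float] = None
    if intervention:
        from .specs import in_target_range

        hits = sum(
            r.checked_in
            and r.behavior_value is not None
            and in_target_range(state.spec, a.target_zone, r.behavior_value)
            for a, r in intervention
        )
        objective_rate = hits / len(intervention)
    ratings = [r.self_adherence for r in all_records if r.checked_in and r.self_adherence is not None]
    return AdherenceSummary(
        check_in_rate=check_in_rate,
        objective_rate=objective_rate,
        median_self_adherence=float(median(ratings)) if ratings else None,
    )


def report_dict(state: ExperimentState) -> dict:
    """JSON-ready report: per-stage results, optimum and adherence."""
    result = experiment_result(state)
    adherence = adherence_summary(state)
    spec = state.spec
    return {
        "experiment": spec.id,
        "optimization": spec.optimization,
        "baseline_mean": state.baseline_mean,
        "stages": [
            {
                "stage": r.stage_number,
                "zone": r.zone.value,
                "target_value": (
                    state.baseline_mean if r.stage_number == 1 else spec.zone_centers[r.zone]
                ),
                "valid_days": list(r.valid_day_indices),
                "mean_outcome": r.mean_outcome,
            }
            for r in result.stage_results
        ],
        "optimal_stage": result.optimal_stage,
        "optimal_zone": result.optimal_zone.value,
        "optimal_target_value": result.optimal_target_value,
        "days_used": result.days_used,
        "tie": result.tie,
        "adherence": {
            "check_in_rate": adherence.check_in_rate,
            "objective_rate": adherence.objective_rate,
            "median_self_adherence": adherence.median_self_adherence,
        },
    }


def report_text(state: ExperimentState) -> str:
    """Plain-text rendering of the final report."""
    d = report_dict(state)
    spec = state.spec
    lines = [
        f"Experiment: {spec.id} ({spec.behavior_name} -> {spec.outcome_name}, {spec.optimization})",
        f"Baseline mean {spec.behavior_name}: {d['baseline_mean']:g} {spec.behavior_units}",
        "",
        f"{'stage':>5}  {'zone':<6}{'target':>10}  {'valid days':<24}{'mean ' + spec.outcome_name}",
    ]
    for s in d["stages"]:
        mean = "n/a" if s["mean_outcome"] is None else f"{s['mean_outcome']:.3f}"
        days = ",".join(map(str, s["valid_days"])) or "-"
        lines.append(f"{s['stage']:>5}  {s['zone']:<6}{s['target_value']:>10.4g}  {days:<24}{mean}")
    lines += [
        "",
        f"Optimal: stage {d['optimal_stage']} (zone {d['optimal_zone']}) -> "
        f"{d['optimal_target_value']:g} {spec.behavior_units}"
        + (" [tie, lowest stage reported]" if d["tie"] else ""),
        f"Days used in analysis: {d['days_used']}",
        f"Check-in adherence: {d['adherence']['check_in_rate']:.1%}",
    ]
    if d["adherence"]["objective_rate"] is not None:
        lines.append(f"Objective adherence: {d['adherence']['objective_rate']:.1%}")
    if d["adherence"]["median_self_adherence"] is not None:
        lines.append(f"Median self-reported adherence: {d['adherence']['median_self_adherence']:g}")
    return "\n".join(lines)


def report_json(state: ExperimentState) -> str:
    return json.dumps(report_dict(state), indent=2, sort_keys=True)
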