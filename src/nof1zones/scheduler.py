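"""Stage ordering and daily goals.

After the baseline stage completes, the participant's mean baseline
behavior is classified into one of the five zones and that zone selects
the order in which the three intervention targets are attempted.  Two
conventions shape the built-in order table: the middle zone O2 is
always the final stage, and every ordering includes at least one
increase and one decrease relative to the baseline.  Targets are fixed
once, at baseline completion, and never recomputed after later-stage
restarts; participants only ever see the current stage's goal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

from .specs import TARGET_ZONES, ExperimentSpec, Zone, ZoneInterval, classify_value, zone_interval

__all__ = ["StagePlan", "DailyGoal", "STAGE_ORDER_TABLE", "classify_baseline", "stage_targets", "daily_goal"]

#: Baseline zone -> target zones for stages 2, 3, 4.
STAGE_ORDER_TABLE: Dict[Zone, Tuple[Zone, Zone, Zone]] = {
    Zone.O1: (Zone.O3, Zone.O1, Zone.O2),
    Zone.O2: (Zone.O3, Zone.O1, Zone.O2),
    Zone.O3: (Zone.O1, Zone.O3, Zone.O2),
    Zone.UNDER: (Zone.O1, Zone.O3, Zone.O2),
    Zone.OVER: (Zone.O3, Zone.O1, Zone.O2),
}


@dataclass(frozen=True)
class StagePlan:
    """The intervention ordering fixed at the end of the baseline stage."""

    baseline_zone: Zone
    targets: Tuple[Zone, Zone, Zone]  # stages 2, 3, 4

    def __post_init__(self) -> None:
        if any(t not in TARGET_ZONES for t in self.targets):
            raise ValueError("stage targets must be bounded zones (O1/O2/O3)")
        if self.targets[-1] is not Zone.O2:
            raise ValueError("the final stage must target the middle zone O2")

    def target_for_stage(self, stage_number: int) -> Zone:
        if stage_number not in (2, 3, 4):
            raise ValueError("intervention stages are 2, 3 and 4")
        return self.targets[stage_number - 2]

    def to_dict(self) -> dict:
        return {"baseline_zone": self.baseline_zone.value, "targets": [t.value for t in self.targets]}

    @classmethod
    def from_dict(cls, data: dict) -> "StagePlan":
        return cls(Zone(data["baseline_zone"]), tuple(Zone(t) for t in data["targets"]))


@dataclass(frozen=True)
class DailyGoal:
    """What the participant is asked to do today.

    During the baseline stage there is no numeric target; afterwards
    the goal is the current stage's zone center plus/minus the buffer.
    Future stages' targets are never part of a goal.
    """

    stage_number: int
    target_zone: Optional[Zone]
    target_center: Optional[float]
    acceptable: Optional[ZoneInterval]
    instruction: str


def classify_baseline(spec: ExperimentSpec, baseline_mean: float) -> Zone:
    """Zone containing the (unrounded) mean baseline behavior."""
    return classify_value(spec, baseline_mean)


def stage_targets(
    baseline_zone: Zone,
    table: Optional[Dict[Zone, Tuple[Zone, Zone, Zone]]] = None,
) -> StagePlan:
    """Look up the intervention ordering for a baseline zone.

    ``table`` substitutes a custom ordering (e.g. from an
    :class:`~nof1zones.specs.ExperimentSpec` with ``stage_order`` set);
    by default the built-in table is used.
    """
    baseline_zone = Zone(baseline_zone)
    chosen = (table or STAGE_ORDER_TABLE)[baseline_zone]
    return StagePlan(baseline_zone=baseline_zone, targets=tuple(Zone(z) for z in chosen))


def daily_goal(state) -> DailyGoal:
    """The goal for the current calendar day of an experiment.

    Raises ``ValueError`` once the experiment is complete.
    """
    if state.completed:
        raise ValueError("experiment already completed; no further goals")
    attempt = state.current_attempt
    spec: ExperimentSpec = state.spec
    if attempt.stage_number == 1:
        return DailyGoal(
            stage_number=1,
            target_zone=None,
            target_center=None,
            acceptable=None,
            instruction=f"Maintain your normal {spec.behavior_name}; there is no target today.",
        )
    zone = attempt.target_zone
    center = spec.zone_centers[zone]
    interval = zone_interval(spec, zone)
    return DailyGoal(
        stage_number=attempt.stage_number,
        target_zone=zone,
        target_center=center,
        acceptable=interval,
        instruction=(
            f"Aim for a {spec.behavior_name} of {center:g} {spec.behavior_units} "
            f"(anything in [{interval.lo:g}, {interval.hi:g}) counts)."
        ),
    )
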