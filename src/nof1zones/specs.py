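"""Experiment specifications and target-zone geometry.

A self-experiment manipulates one daily behavior (sleep duration, step
count, leisure time, bedtime regularity) across four sequential stages
and tracks one self-reported or sensed outcome (productivity, stress,
happiness, sleep efficiency).  The behavior axis is quantized into five
zones: three bounded target zones ``O1 < O2 < O3``, each a center value
with a symmetric buffer, flanked by the open-ended ``Under`` and
``Over`` zones.  The buffer ("target zone size") absorbs normal
day-to-day variation so that a participant aiming at a zone center can
plausibly land inside the zone.

Zone membership uses a half-open convention so that every behavior
value belongs to exactly one zone: O-zones are ``[center - buffer,
center + buffer)``, ``Under`` is ``(-inf, under_threshold)`` and
``Over`` is ``[over_threshold, +inf)``.  A value sitting exactly on a
shared boundary therefore belongs to the higher zone.
"""

from __future__ import annotations

import json
import math
import statistics
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Dict, Literal, Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "Zone",
    "TARGET_ZONES",
    "ZoneInterval",
    "ExperimentSpec",
    "builtin_specs",
    "zone_interval",
    "classify_value",
    "in_target_range",
    "sleep_efficiency",
    "bedtime_deviation",
    "reference_bedtime",
    "load_spec",
    "save_spec",
]


class Zone(str, Enum):
    """The five quantized behavior zones."""

    UNDER = "Under"
    O1 = "O1"
    O2 = "O2"
    O3 = "O3"
    OVER = "Over"


#: The three bounded zones that may be assigned as stage targets.
TARGET_ZONES: Tuple[Zone, Zone, Zone] = (Zone.O1, Zone.O2, Zone.O3)


@dataclass(frozen=True)
class ZoneInterval:
    """An interval of behavior values, half-open on the right.

    ``closed_left`` is False only for the ``Under`` zone, whose left end
    is -inf; every bounded zone and ``Over`` include their left edge.
    """

    lo: float
    hi: float
    closed_left: bool = True

    def __contains__(self, value: float) -> bool:
        if self.closed_left:
            return self.lo <= value < self.hi
        return value < self.hi


BehaviorUnits = Literal["steps", "minutes", "hours"]
OutcomeScale = Literal["likert7", "efficiency_percent"]
Optimization = Literal["maximize", "minimize"]
MissedPolicy = Literal["consecutive", "cumulative"]

_TOL = 1e-9


class ExperimentSpec(BaseModel):
    """Full definition of one self-experiment.

    ``zone_centers`` maps O1/O2/O3 to behavior values; the zones must
    tile contiguously, i.e. consecutive centers are exactly ``2 *
    buffer`` apart, ``under_threshold = center(O1) - buffer`` and
    ``over_threshold = center(O3) + buffer``.

    The rule parameters default to the standard stage machinery: stages
    last 5-7 days, need at least ``min_stage_days`` in-range days plus a
    stable outcome to finish early, at least ``min_in_range_days_at_cap``
    in-range days to finish at the 7-day cap, and restart after
    ``max_missed_consecutive`` missed check-ins (consecutive by default;
    set ``missed_policy="cumulative"`` to count all misses within the
    stage).
    """

    model_config = ConfigDict(frozen=True)

    id: str
    behavior_name: str
    behavior_units: BehaviorUnits
    zone_centers: Dict[Zone, float]
    buffer: float = Field(gt=0)
    under_threshold: float
    over_threshold: float
    outcome_name: str
    outcome_scale: OutcomeScale
    optimization: Optimization
    stability_tolerance: Optional[float] = Field(default=None, gt=0)
    min_stage_days: int = Field(default=5, ge=1)
    max_stage_days: int = Field(default=7, ge=1)
    min_in_range_days_at_cap: int = Field(default=4, ge=1)
    max_missed_consecutive: int = Field(default=2, ge=1)
    missed_policy: MissedPolicy = "consecutive"
    # Optional custom stage-order table (baseline zone -> three targets);
    # None selects the built-in table in the scheduler module.
    stage_order: Optional[Dict[Zone, Tuple[Zone, Zone, Zone]]] = None

    @model_validator(mode="after")
    def _check_invariants(self) -> "ExperimentSpec":
        centers = self.zone_centers
        if set(centers) != {Zone.O1, Zone.O2, Zone.O3}:
            raise ValueError("zone_centers must define exactly O1, O2 and O3")
        c1, c2, c3 = centers[Zone.O1], centers[Zone.O2], centers[Zone.O3]
        if not (c1 < c2 < c3):
            raise ValueError("zone centers must be strictly increasing: O1 < O2 < O3")
        if abs((c2 - c1) - 2 * self.buffer) > _TOL or abs((c3 - c2) - 2 * self.buffer) > _TOL:
            raise ValueError("zones must tile contiguously: consecutive centers 2*buffer apart")
        if abs(self.under_threshold - (c1 - self.buffer)) > _TOL:
            raise ValueError("under_threshold must equal center(O1) - buffer")
        if abs(self.over_threshold - (c3 + self.buffer)) > _TOL:
            raise ValueError("over_threshold must equal center(O3) + buffer")
        if self.min_stage_days > self.max_stage_days:
            raise ValueError("min_stage_days must not exceed max_stage_days")
        if self.min_in_range_days_at_cap >= self.min_stage_days:
            raise ValueError("min_in_range_days_at_cap must be below min_stage_days")
        if self.stability_tolerance is None:
            default = 3.0 if self.outcome_scale == "likert7" else 10.0
            object.__setattr__(self, "stability_tolerance", default)
        if self.stage_order is not None:
            if set(self.stage_order) != set(Zone):
                raise ValueError("custom stage_order must cover all five baseline zones")
            for zone, targets in self.stage_order.items():
                if any(t not in TARGET_ZONES for t in targets):
                    raise ValueError("stage targets must be O1/O2/O3")
        return self

    @property
    def outcome_bounds(self) -> Tuple[float, float]:
        """Admissible outcome range for this spec's outcome scale."""
        return (1.0, 7.0) if self.outcome_scale == "likert7" else (0.0, 100.0)


def zone_interval(spec: ExperimentSpec, zone: Zone) -> ZoneInterval:
    """The interval of behavior values belonging to ``zone``.

    O-zones are ``[center - buffer, center + buffer)``; ``Under`` is
    ``(-inf, under_threshold)`` and ``Over`` is ``[over_threshold,
    +inf)``, so the five intervals tile the behavior axis exactly.
    """
    zone = Zone(zone)
    if zone is Zone.UNDER:
        return ZoneInterval(-math.inf, spec.under_threshold, closed_left=False)
    if zone is Zone.OVER:
        return ZoneInterval(spec.over_threshold, math.inf)
    c = spec.zone_centers[zone]
    return ZoneInterval(c - spec.buffer, c + spec.buffer)


def classify_value(spec: ExperimentSpec, value: float) -> Zone:
    """Map a behavior value to the unique zone containing it."""
    if not math.isfinite(value):
        raise ValueError(f"behavior value must be finite, got {value!r}")
    for zone in Zone:
        if value in zone_interval(spec, zone):
            return zone
    raise AssertionError("zones tile the axis; unreachable")  # pragma: no cover


def in_target_range(spec: ExperimentSpec, zone: Zone, value: float) -> bool:
    """Whether a behavior value achieves the target ``zone``.

    Only the bounded zones O1/O2/O3 are ever assigned as targets.
    """
    zone = Zone(zone)
    if zone not in TARGET_ZONES:
        raise ValueError(f"target zone must be one of O1/O2/O3, got {zone.value}")
    return value in zone_interval(spec, zone)


def sleep_efficiency(minutes_asleep: float, minutes_in_bed: float) -> float:
    """Sleep efficiency as a percentage: minutes asleep / minutes in bed.

    >>> round(sleep_efficiency(400, 480), 2)
    83.33
    """
    if minutes_in_bed <= 0:
        raise ValueError("minutes_in_bed must be positive")
    if minutes_asleep < 0 or minutes_asleep > minutes_in_bed:
        raise ValueError("minutes_asleep must lie in [0, minutes_in_bed]")
    return 100.0 * minutes_asleep / minutes_in_bed


def reference_bedtime(bedtimes_minutes: list[float]) -> float:
    """Reference bedtime: the median of the baseline-stage bedtimes.

    Bedtimes are minutes from midnight; times past midnight are encoded
    as values above 1440 so that, e.g., 00:30 following a 23:30 night
    sits at 1470 rather than wrapping to 30.
    """
    if not bedtimes_minutes:
        raise ValueError("need at least one bedtime")
    return float(statistics.median(bedtimes_minutes))


def bedtime_deviation(bedtime_minutes: float, reference_minutes: float) -> float:
    """Daily bed-time-variability value: |bedtime - reference| in minutes.

    The variability experiment needs a per-day scalar; we take the
    absolute deviation of tonight's bedtime from the participant's
    reference (baseline median) bedtime.
    """
    return abs(bedtime_minutes - reference_minutes)


def _spec(**kw) -> ExperimentSpec:
    return ExperimentSpec(**kw)


def builtin_specs() -> Dict[str, ExperimentSpec]:
    """The four built-in self-experiments.

    Zone systems: steps <6500 | 8000 | 11000 | 14000 | >15500 (±1500);
    bed-time variability and leisure time <15 | 30 | 60 | 90 | >105
    (±15 min); sleep duration <6 | 6.5 | 7.5 | 8.5 | >9 h (±0.5).
    """
    specs = [
        _spec(
            id="steps_sleep_efficiency",
            behavior_name="number of steps",
            behavior_units="steps",
            zone_centers={Zone.O1: 8000, Zone.O2: 11000, Zone.O3: 14000},
            buffer=1500,
            under_threshold=6500,
            over_threshold=15500,
            outcome_name="sleep efficiency",
            outcome_scale="efficiency_percent",
            optimization="maximize",
        ),
        _spec(
            id="bedtime_stress",
            behavior_name="bed time variability",
            behavior_units="minutes",
            zone_centers={Zone.O1: 30, Zone.O2: 60, Zone.O3: 90},
            buffer=15,
            under_threshold=15,
            over_threshold=105,
            outcome_name="stress",
            outcome_scale="likert7",
            optimization="minimize",
        ),
        _spec(
            id="sleep_productivity",
            behavior_name="sleep duration",
            behavior_units="hours",
            zone_centers={Zone.O1: 6.5, Zone.O2: 7.5, Zone.O3: 8.5},
            buffer=0.5,
            under_threshold=6.0,
            over_threshold=9.0,
            outcome_name="productivity",
            outcome_scale="likert7",
            optimization="maximize",
        ),
        _spec(
            id="leisure_happiness",
            behavior_name="leisure time",
            behavior_units="minutes",
            zone_centers={Zone.O1: 30, Zone.O2: 60, Zone.O3: 90},
            buffer=15,
            under_threshold=15,
            over_threshold=105,
            outcome_name="happiness",
            outcome_scale="likert7",
            optimization="maximize",
        ),
    ]
    return {s.id: s for s in specs}


def load_spec(path: str | Path) -> ExperimentSpec:
    """Read an ExperimentSpec from a YAML or JSON file and validate it."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of spec fields")
    return ExperimentSpec.model_validate(data)


def save_spec(spec: ExperimentSpec, path: str | Path) -> None:
    """Write an ExperimentSpec to YAML or JSON (chosen by extension)."""
    path = Path(path)
    data = spec.model_dump(mode="json")
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))
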