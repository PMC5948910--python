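"""Canonical scripted participants for the design's boundary cases.

These day tables exercise the documented envelope of the four-stage
design: the fastest possible completion (5 in-range, stable days per
stage -> 20 calendar days), the sparsest analyzable experiment (exactly
4 of 7 days in range in every stage -> 16 analysis days), and the
longest analyzable one (every stage runs its full 7 days with an
unstable outcome but all days in range -> 28 analysis days).  A fourth
builder reconstructs a realistic multi-restart sleep-duration
experiment used in the worked-example documentation and tests.

All builders are generic over any valid spec: in-range days sit on the
stage's zone center, out-of-range days below the Under threshold, and
"unstable" outcomes alternate across more than the stability tolerance.
"""

from __future__ import annotations

from typing import List

from .engine import CheckInRecord
from .scheduler import stage_targets
from .simulator import ScriptedParticipant
from .specs import ExperimentSpec, Zone

__all__ = [
    "fully_adherent_participant",
    "four_of_seven_participant",
    "unstable_all_in_range_participant",
    "multi_restart_sleep_days",
]


def _stable_outcome(spec: ExperimentSpec) -> float:
    return 4.0 if spec.outcome_scale == "likert7" else 80.0


def _unstable_outcomes(spec: ExperimentSpec, n: int) -> List[float]:
    lo, hi = (1.0, 7.0) if spec.outcome_scale == "likert7" else (40.0, 80.0)
    return [lo if i % 2 == 0 else hi for i in range(n)]


def _out_of_range_value(spec: ExperimentSpec) -> float:
    # Below every bounded zone (and non-negative for count/duration units).
    return max(0.0, spec.under_threshold - spec.buffer)


def _day(checked: bool, behavior, outcome, adherence=None) -> CheckInRecord:
    return CheckInRecord(
        day_index=1,  # reassigned by ScriptedParticipant
        checked_in=checked,
        behavior_value=behavior,
        outcome_value=outcome,
        self_adherence=adherence,
    )


def fully_adherent_participant(spec: ExperimentSpec) -> ScriptedParticipant:
    """Checks in daily, lands exactly on target, constant outcome.

    The baseline behavior sits on the O2 center, so the plan is the O2
    row of the order table; every stage finishes at the 5-day minimum
    and the experiment completes on day 20.
    """
    c2 = spec.zone_centers[Zone.O2]
    y = _stable_outcome(spec)
    days = [_day(True, c2, y, 7) for _ in range(5)]
    plan = stage_targets(Zone.O2, table=spec.stage_order)
    for zone in plan.targets:
        center = spec.zone_centers[zone]
        days += [_day(True, center, y, 7) for _ in range(5)]
    return ScriptedParticipant(days)


def four_of_seven_participant(spec: ExperimentSpec) -> ScriptedParticipant:
    """In the target range on exactly 4 of each stage's 7 days.

    The baseline runs its full 7 days (its outcome is kept unstable so
    the early-advance rule cannot fire) with 4 days at the O2 center
    and 3 at the O3 center; the mean lands inside O2, so exactly 4
    baseline days survive the post-hoc zone filter.  Intervention
    stages hit the target on days 1-4 and miss afterwards, advancing at
    the 7-day cap with 4 valid days each: 16 analysis days in total.
    """
    c2, c3 = spec.zone_centers[Zone.O2], spec.zone_centers[Zone.O3]
    unstable = _unstable_outcomes(spec, 7)
    baseline_behaviors = [c2] * 4 + [c3] * 3
    days = [_day(True, b, y, 5) for b, y in zip(baseline_behaviors, unstable)]
    plan = stage_targets(Zone.O2, table=spec.stage_order)
    y = _stable_outcome(spec)
    miss = _out_of_range_value(spec)
    for zone in plan.targets:
        center = spec.zone_centers[zone]
        days += [_day(True, center, y, 6) for _ in range(4)]
        days += [_day(True, miss, y, 2) for _ in range(3)]
    return ScriptedParticipant(days)


def unstable_all_in_range_participant(spec: ExperimentSpec) -> ScriptedParticipant:
    """Always in range but never stable: every stage runs 7 days.

    All 28 days carry in-range behavior and an outcome, so all 28 enter
    the analysis.
    """
    c2 = spec.zone_centers[Zone.O2]
    days: List[CheckInRecord] = [
        _day(True, c2, y, 7) for y in _unstable_outcomes(spec, 7)
    ]
    plan = stage_targets(Zone.O2, table=spec.stage_order)
    for zone in plan.targets:
        center = spec.zone_centers[zone]
        days += [_day(True, center, y, 7) for y in _unstable_outcomes(spec, 7)]
    return ScriptedParticipant(days)


def multi_restart_sleep_days() -> List[CheckInRecord]:
    """A realistic 47-day sleep-duration -> productivity trajectory.

    Baseline days 1-6 (one night without a sensed sleep value) give a
    mean of 8.75 h (zone O3), so the intervention order is 6.5 h, 8.5 h,
    7.5 h.  Stage 2 fails twice on too few in-range days before a third
    attempt (days 21-27) succeeds with the target achieved on days 21,
    25, 26 and 27.  Stage 3 fails once on in-range days and once on two
    consecutive missed check-ins before succeeding on days 38-44 (in
    range on days 39, 41, 42, 44).  Stage 4 is still in progress when
    the log ends on day 47.
    """
    days: List[CheckInRecord] = []

    def add(checked, behavior, outcome, adherence=None):
        days.append(_day(checked, behavior, outcome, adherence))

    # Stage 1 (days 1-6): completes at day 6 via 5 recorded-behavior days.
    for behavior, outcome in [(8.8, 4), (8.7, 5), (None, 4), (8.9, 5), (8.6, 4), (8.75, 5)]:
        add(True, behavior, outcome, 4)
    # Stage 2, attempts 1-2 (days 7-20): never in the 6.5 h zone -> restarts.
    for _ in range(2):
        for outcome in [3, 4, 3, 5, 4, 3, 4]:
            add(True, 8.0, outcome, 3)
    # Stage 2, attempt 3 (days 21-27): in range on days 21, 25, 26, 27.
    for behavior, outcome in [(6.5, 5), (8.0, 4), (8.0, 3), (8.0, 4), (6.4, 6), (6.6, 5), (6.5, 6)]:
        add(True, behavior, outcome, 5)
    # Stage 3, attempt 1 (days 28-34): short sleep, never in the 8.5 h zone.
    for outcome in [4, 4, 5, 4, 3, 4, 4]:
        add(True, 7.5, outcome, 3)
    # Stage 3, attempt 2 (days 35-37): two consecutive missed check-ins.
    add(True, 7.5, 4, 3)
    add(False, None, None)
    add(False, None, None)
    # Stage 3, attempt 3 (days 38-44): in range on days 39, 41, 42, 44.
    for behavior, outcome in [(7.8, 4), (8.5, 6), (7.9, 5), (8.6, 5), (8.4, 6), (7.7, 4), (8.5, 5)]:
        add(True, behavior, outcome, 5)
    # Stage 4 (days 45-47): started, unfinished.
    for behavior, outcome in [(7.5, 5), (7.4, 4), (7.6, 5)]:
        add(True, behavior, outcome, 6)
    for i, rec in enumerate(days, start=1):
        rec.day_index = i
    return days
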