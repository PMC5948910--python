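"""Replay a realistic 47-day sleep-duration experiment from a day log.

The participant restarts stage 2 twice (too few in-range days) and
stage 3 twice (once for in-range days, once for two consecutive missed
check-ins) before each succeeds; stage 4 is still running when the log
ends.  The replay shows which days would enter the analysis: only
checked-in days whose sleep fell in the stage's target zone.
"""

import nof1zones as nz
from nof1zones.analysis import valid_days
from nof1zones.scenarios import multi_restart_sleep_days

sleep = nz.builtin_specs()["sleep_productivity"]
state, decisions = nz.replay(sleep, multi_restart_sleep_days())

print(f"Days ingested: {state.total_days}; completed: {state.completed}")
print(f"Baseline mean: {state.baseline_mean:g} h "
      f"-> zone {nz.classify_baseline(sleep, state.baseline_mean).value}")
print(f"Stage 2-4 targets: {[sleep.zone_centers[z] for z in state.plan.targets]} h")

for attempt in state.attempts:
    span = f"days {attempt.records[0].day_index}-{attempt.records[-1].day_index}" \
        if attempt.records else "not started"
    print(f"  stage {attempt.stage_number} attempt {attempt.attempt_index}: "
          f"{span}, {attempt.status.value}")

for stage in (2, 3):
    attempt = next(a for a in state.completed_attempts() if a.stage_number == stage)
    kept = [r.day_index for r in valid_days(sleep, attempt)]
    print(f"Stage {stage} analysis days: {kept} "
          f"(target {sleep.zone_centers[attempt.target_zone]:g} h)")
# The analysis days are the only ones whose productivity scores enter
# that stage's mean; everything else is discarded as off-target.
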