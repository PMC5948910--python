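# Methods

## Design model

`nof1zones` implements a four-stage single-case experimental design
(AB₁B₂B₃): one baseline phase with no behavioral target, followed by three
intervention phases at different magnitudes of the same behavior, never
returning to baseline. Each phase ("stage") accumulates 4–7 days of data.
The design's purpose is dose-finding within a single person: the stage whose
mean outcome is best under the experiment's optimization direction names the
personalized optimal behavior zone.

Assumptions inherited from the design itself: outcome effects are assumed to
follow the behavior quickly enough that a 5–7-day phase reflects them
(no carry-over modelling); each intervention level is attempted once (no
replication of phases); days are exchangeable within a stage (means, not
trends, are compared); and no significance testing is attached to the
stage-mean comparison — the output is a ranking, not an inference.

## Zone geometry

A behavior axis is quantized into five zones: `O1 < O2 < O3`, each
`[center − buffer, center + buffer)`, plus open-ended `Under` and `Over`.
The built-in zone systems are:

| experiment | Under | O1 | O2 | O3 | Over | buffer | outcome (direction) |
|---|---|---|---|---|---|---|---|
| steps_sleep_efficiency | <6500 | 8000 | 11000 | 14000 | >15500 | ±1500 | sleep efficiency, % (max) |
| bedtime_stress (min of variability) | <15 | 30 | 60 | 90 | >105 | ±15 | stress, Likert 1–7 (min) |
| sleep_productivity (h) | <6 | 6.5 | 7.5 | 8.5 | >9 | ±0.5 | productivity, Likert 1–7 (max) |
| leisure_happiness (min) | <15 | 30 | 60 | 90 | >105 | ±15 | happiness, Likert 1–7 (max) |

All four systems tile: consecutive centers are exactly `2 × buffer` apart
and the open zones begin exactly one buffer beyond the outer centers, so the
five intervals cover the axis with no gaps or overlaps.

**Boundary convention.** Intervals are half-open on the right and `Over` is
closed on the left, so a value on a shared boundary belongs to the higher
zone and classification is total and unique (property-tested on dense grids
and with hypothesis). The lower open zone keeps the strict reading of its
threshold (exactly 6.0 h is O1, not Under); symmetrically strict treatment
of the upper threshold would leave the single point `over_threshold`
zoneless, so uniqueness wins there and `over_threshold` itself classifies as
Over. No worked example sits on a boundary, so this choice only affects
degenerate inputs.

**Bed-time variability** needs a per-day scalar that the raw data (a clock
time) does not directly provide. We define it as |tonight's bedtime −
reference bedtime| in minutes, with the reference taken as the median
baseline bedtime (`reference_bedtime` / `bedtime_deviation`); bedtimes past
midnight are encoded as minutes > 1440 to avoid wrap-around. This is a
package definition, chosen because a median reference is robust to a single
wild night; any monotone alternative (e.g. deviation from a fixed goal
bedtime) can be computed upstream and fed in as the behavior value.

## Stage ordering

The baseline mean behavior — unweighted arithmetic mean over checked-in
baseline days with a recorded behavior value, unrounded — is classified into
a zone, and that zone selects the intervention order:

| baseline | stage 2 | stage 3 | stage 4 |
|---|---|---|---|
| O1 | O3 | O1 | O2 |
| O2 | O3 | O1 | O2 |
| O3 | O1 | O3 | O2 |
| Under | O1 | O3 | O2 |
| Over | O3 | O1 | O2 |

The table encodes two conventions — O2 is always last, and every ordering
contains at least one increase and one decrease — and is otherwise data:
a custom table can be supplied per spec (`stage_order`). The O1 and O2 rows
are identical; the table is reproduced as designed rather than symmetrized.
Targets are fixed once, when the baseline completes, and are never
recomputed after later-stage restarts. Participants are shown only the
current stage's goal.

## Daily rules

After each ingested calendar day the engine evaluates, in order:

1. **Missed check-ins:** ≥2 *consecutive* missed days restart the stage
   immediately. Consecutiveness is the default because the stated concern
   is a participant who no longer knows the current target; a
   `missed_policy="cumulative"` switch counts all misses within the stage
   instead. Missed days still advance the day counter and count as
   out-of-range.
2. **Early advance:** ≥5 elapsed days, ≥5 in-range days, and a stable
   outcome. Stability = within-attempt outcome range ≤ tolerance
   (3 Likert points or 10 efficiency points), bound inclusive, over all
   checked-in outcome days of the attempt (not just in-range days). An
   attempt with no outcomes yet is treated as vacuously stable.
3. **Day-7 cap:** ≥5 in-range (necessarily unstable, or rule 2 would have
   fired) or exactly 4 in-range advance; ≤3 restart.

The baseline stage runs the same machinery with every checked-in
behavior-bearing day counted as in range (there is no target). A stage can
therefore not complete before day 5, never exceeds day 7, and an advance out
of stage 4 completes the experiment — giving the 20-day minimum duration and
the 16–28-day analysis envelope checked by the acceptance suite. Requiring
stability before day 7 means a 6-day stage with 5 in-range days but an
unstable outcome continues to day 7 rather than completing; and the ≥5
in-range requirement of rule 2 means one missed check-in within the first
five days always delays early advancement to day 6 at the earliest.

## Analysis

Valid days are checked-in days with both a behavior value inside the stage's
zone and a recorded outcome; days without a sensed behavior value can never
be valid. Intervention stages filter on their target zone. Baseline days
are filtered *post hoc* to the zone containing the final baseline mean
(the open Under/Over interval when the mean lands there): this is the
reading under which the 16-day analysis floor (4 × 4) applies to all four
stages. Restarted attempts are retained in the state for audit but excluded
from analysis. Stage means are unweighted; ties are broken toward the lower
stage number and flagged. If the baseline wins, the recommendation is the
baseline mean itself rather than a zone center.

A consequence of the post-hoc baseline filter worth stating plainly: when
the baseline mean lands near a zone boundary, fewer than 4 baseline days may
survive filtering, so the 16-day floor is a property of the intervention
stages plus a well-centered baseline, not a theorem. In a cohort of 1,000
simulated completed experiments under the simulator's realistic defaults,
2 runs retained 14–15 analysis days; the guaranteed envelope (4–7 valid days
per intervention stage, ≤28 days overall) holds always and is tested
separately. Baseline stages left with zero valid days are excluded from the
optimum rather than crashing the analysis.

Adherence is summarized three ways, matching how study compliance is usually
reported: check-in rate (checked-in / elapsed days), objective rate
(in-target-range / elapsed intervention days), and the median self-reported
1–7 adherence rating.

## Simulator

`ParticipantModel` emulates the dominant failure modes of real
self-experimenters — skipping check-ins and failing to move the behavior —
with per-day Bernoulli draws: check in with probability `p_checkin`; if a
target exists, aim at its center with probability `p_comply` (Normal around
the center, SD `comply_sd`), otherwise fall back to habit (Normal around
`habitual_mean`, SD `habitual_sd`); behavior values are truncated at 0.
During baseline, behavior always comes from the habitual distribution.

Outcomes follow a quadratic peak,
`E[y | b] = level + amplitude · (1 − ((b − b_star)/width)²)`, plus Gaussian
noise, then discretized per scale (Likert: round half-up, clip to 1–7;
efficiency: clip to 0–100). The quadratic form is a testability device — it
gives parameter-recovery tests a ground-truth optimal zone — not a claim
about real dose-response curves. Deliberately not modelled: weekday/weekend
structure, autocorrelated adherence lapses, carry-over of behavior effects
across days, learning/fatigue trends, and any personality covariates of
adherence. Passing simulation tests therefore show the *engine* is correct
under the design's own assumptions, not that the design identifies causal
effects in messier real data.

Default study conditions used by the cohort-level tests: habitual mean
uniform across the bounded-zone span; habitual and compliance SD of half a
buffer (the buffer is sized to absorb normal day-to-day variation, so
day-level noise comparable to half a buffer is the realistic regime);
check-in probability 0.85–1.0 and compliance 0.8–1.0 (engaged participants;
lower values rarely complete within six weeks, mirroring how hard full
completion is in practice); outcome noise 0.5 Likert points or 5 efficiency
points. Monte-Carlo sizes are 200 replicates per condition (1,000 for the
cohort envelope), which keeps the full suite under a minute while leaving
binomial noise of ~±3.5 percentage points on any rate, and the monotonicity
checks allow 0.10 slack (~2 binomial SDs) accordingly.

Determinism: every stochastic path is driven by one `numpy` Generator seeded
per run; replicate seeds are spawned from a `SeedSequence`, and identical
(spec, participant, seed) triples serialize byte-identically.

## Numerical and degenerate-input choices

- Stage means and the baseline mean use exact `fmean` over floats; no
  rounding before classification or comparison. Tie detection uses exact
  float equality — with integer Likert outcomes and small day counts, exact
  ties are meaningful (identical day sets), not float accidents.
- Likert outcome validation rejects non-integer values at ingest;
  efficiency outcomes may be fractional.
- The state file is versioned JSON written atomically (write-then-rename);
  replaying an exported log reproduces the state exactly.
- `ScriptedParticipant` tables reassign day indices sequentially, so
  scenario tables can be assembled stage by stage.

## Known limitations

- Single attempt per intervention level: no ABAB-style replication, so the
  design cannot distinguish a behavior effect from a coinciding time trend.
- No inferential statistics on the stage comparison (no non-overlap indices
  or randomization tests); the result is a descriptive optimum.
- The post-hoc baseline filter can under-supply baseline analysis days near
  zone boundaries (see Analysis above).
- Calendar structure is abstract (`day_index`); real deployments must map
  days to dates and handle time zones upstream.
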