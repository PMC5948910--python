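# nof1zones

A single-case (N-of-1) self-experimentation engine for daily behaviors.

Quantified-self data usually yields correlations: you slept longer and felt
more productive, but nothing was manipulated. `nof1zones` implements the
experimental alternative — a **single-case experimental design** in which one
person actively varies one behavior (sleep duration, step count, leisure
time, bedtime regularity) across sequential stages and tracks one outcome
(productivity, sleep efficiency, happiness, stress), so that within-person
causal structure can be probed and a *personalized optimal behavior level*
reported.

The package is aimed at researchers running or studying guided
self-experiments: it provides the full decision engine a coaching app or
study backend needs, plus a participant simulator so every rule and design
bound can be tested without collecting a single day of human data.

## The design

The behavior axis is quantized into five zones: bounded target zones
`O1 < O2 < O3` (each a center `c` with half-width buffer `b`, covering
`[c − b, c + b)`) flanked by open-ended `Under` and `Over`. For sleep
duration the zones are `<6 | 6.5 | 7.5 | 8.5 | >9` hours with `b = 0.5`.

An experiment is a non-terminated **AB₁B₂B₃** sequence:

1. **Stage 1 (baseline, A):** no target; the mean behavior over checked-in
   days is classified into a zone, which selects the intervention order.
   The ordering always includes an increase and a decrease and always ends
   on the middle zone O2 (e.g. baseline in O1 → targets O3, O1, O2).
2. **Stages 2–4 (interventions, B₁–B₃):** each day the participant checks
   in, reports the outcome, and aims for the stage's zone. A stage
   *advances* after ≥5 in-range days with a *stable* outcome (within-stage
   outcome range ≤ 3 Likert points, or ≤ 10 percentage points of sleep
   efficiency); at the 7-day cap it advances with ≥4 in-range days and
   *restarts* with ≤3; two consecutive missed check-ins restart it
   immediately.
3. **Analysis:** per stage, the outcome is averaged over *valid* days only
   (checked-in, outcome present, behavior inside the stage's zone; baseline
   days are filtered post hoc to the zone of the baseline mean). The stage
   with the best mean under the experiment's direction (maximize or
   minimize) names the optimal zone and its center is the recommendation.

Consequences pinned by the test suite: a fully adherent participant finishes
in exactly **20 days**; a completed experiment contributes between **16**
(4 × 4 valid days) and **28** (4 × 7) days to the analysis.

## Worked example

A realistic 47-day sleep-duration → productivity trajectory with repeated
stage restarts (`examples/scripted_replay.py`):

```
Days ingested: 47; completed: False
Baseline mean: 8.75 h -> zone O3
Stage 2-4 targets: [6.5, 8.5, 7.5] h
  stage 1 attempt 1: days 1-6, completed
  stage 2 attempt 1: days 7-13, restarted
  stage 2 attempt 2: days 14-20, restarted
  stage 2 attempt 3: days 21-27, completed
  stage 3 attempt 1: days 28-34, restarted
  stage 3 attempt 2: days 35-37, restarted
  stage 3 attempt 3: days 38-44, completed
  stage 4 attempt 1: days 45-47, in_progress
Stage 2 analysis days: [21, 25, 26, 27] (target 6.5 h)
Stage 3 analysis days: [39, 41, 42, 44] (target 8.5 h)
```

The six baseline nights average 8.75 h (zone O3), so the participant is sent
to 6.5 h, then 8.5 h, then 7.5 h. Stage 2 fails twice on too few in-range
nights; its successful attempt achieved 6.5 h on days 21, 25, 26 and 27, and
only those four days' productivity scores form the 6.5-h mean. Stage 3's
second attempt dies on two consecutive missed check-ins.

The other examples print zone tables and stage schedules
(`examples/zones_and_schedules.py`) and Monte-Carlo completion/recovery
statistics for synthetic participants (`examples/simulate_cohort.py`).

## Command line

The same machinery is scriptable from the shell:

```bash
nof1zones init sleep_productivity -o exp.json
nof1zones checkin exp.json --behavior 7.4 --outcome 5 --adherence 6
nof1zones skip exp.json                 # an explicitly missed day
nof1zones status exp.json
nof1zones replay log.csv sleep_productivity -o exp.json
nof1zones analyze exp.json --json report.json
nof1zones simulate sleep_productivity --participant p.yaml --reps 200 -o runs.csv
nof1zones validate-config myspec.yaml
```

State is a versioned JSON file written atomically; check-in history is plain
CSV (`day_index,date,checked_in,behavior_value,outcome_value,self_adherence`).

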