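"""Monte-Carlo completion and zone-recovery statistics.

A synthetic participant whose productivity truly peaks at 8.5 h of
sleep runs the full four-stage experiment 200 times at two adherence
levels.  With full adherence the design always completes in the
20-day minimum and recovers the true optimal zone; with patchy
check-ins most six-week windows end without a completed experiment.
"""

import nof1zones as nz

sleep = nz.builtin_specs()["sleep_productivity"]
truth = nz.QuadraticOutcome(b_star=8.5, amplitude=3.0, level=4.0, width=1.0)


def participant(p_checkin: float, p_comply: float) -> nz.ParticipantModel:
    return nz.ParticipantModel(
        habitual_mean=7.5, habitual_sd=0.25,
        p_checkin=p_checkin, p_comply=p_comply, comply_sd=0.2,
        outcome_model=truth, outcome_noise_sd=0.3,
    )


for label, p in [("fully adherent", participant(1.0, 1.0)),
                 ("patchy check-ins", participant(0.6, 0.8))]:
    stats = nz.completion_stats(sleep, p, n_reps=200, max_days=42, seed=42)
    d = stats.duration_summary()
    print(f"{label}:")
    print(f"  completion rate over 42-day windows: {stats.completion_rate:.2f}")
    if d["n"]:
        print(f"  duration of completed runs: mean {d['mean']:.1f} d "
              f"(min {d['min']:.0f}, max {d['max']:.0f})")
        print(f"  true-zone recovery rate: {stats.zone_recovery_rate:.2f}")
# Recovery = the reported optimal zone contains the participant's true
# best behavior (8.5 h, zone O3).
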