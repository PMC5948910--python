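import pytest
from hypothesis import HealthCheck, settings

import nof1zones as nz
from nof1zones.engine import AttemptStatus, CheckInRecord, StageAttempt

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def builtins():
    return nz.builtin_specs()


@pytest.fixture(scope="session")
def sleep_spec(builtins):
    return builtins["sleep_productivity"]


@pytest.fixture(scope="session")
def steps_spec(builtins):
    return builtins["steps_sleep_efficiency"]


@pytest.fixture(scope="session")
def leisure_spec(builtins):
    return builtins["leisure_happiness"]


@pytest.fixture(scope="session")
def bedtime_spec(builtins):
    return builtins["bedtime_stress"]


def make_attempt(stage_number, target_zone, days, status=AttemptStatus.IN_PROGRESS, start_day=1):
    """Build a StageAttempt from (checked_in, behavior, outcome) triples."""
    records = [
        CheckInRecord(
            day_index=start_day + i,
            checked_in=checked,
            behavior_value=behavior,
            outcome_value=outcome,
        )
        for i, (checked, behavior, outcome) in enumerate(days)
    ]
    return StageAttempt(
        stage_number=stage_number, target_zone=target_zone, records=records, status=status
    )


def random_participant(spec, rng):
    """A realistic random self-experimenter for cohort-level properties.

    Habitual behavior is uniform across the bounded-zone span with
    day-to-day noise of half a buffer (the buffer is sized to absorb
    normal variation); check-in and compliance probabilities sit in the
    engaged-user range; the outcome peaks at a random zone center.
    """
    center = float(rng.choice([spec.zone_centers[z] for z in nz.TARGET_ZONES]))
    likert = spec.outcome_scale == "likert7"
    return nz.ParticipantModel(
        habitual_mean=float(rng.uniform(spec.under_threshold, spec.over_threshold)),
        habitual_sd=spec.buffer / 2,
        p_checkin=float(rng.uniform(0.85, 1.0)),
        p_comply=float(rng.uniform(0.8, 1.0)),
        comply_sd=spec.buffer / 2,
        outcome_model=nz.QuadraticOutcome(
            b_star=center,
            amplitude=2.0 if likert else 20.0,
            level=4.0 if likert else 70.0,
            width=4 * spec.buffer,
        ),
        outcome_noise_sd=0.5 if likert else 5.0,
    )
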