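import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from emadhere.config import (  # noqa: E402
    CohortConfig,
    DeviationModel,
    DiscontinuationModel,
    IntakeModel,
    InterruptionModel,
)


def tiny_config(**overrides) -> CohortConfig:
    """A small calibrated cohort for fast end-to-end tests."""
    base = dict(
        n_patients=10,
        horizon_days=60,
        baseline_days=7,
        cyclic_fraction=0.2,
        multi_monitor_fraction=0.2,
        intake_model=IntakeModel(
            control_day180=0.92, intervention_day180=0.97, anchor_day=40
        ),
        interruption_model=InterruptionModel(
            prone_fraction=0.5, prevalence_day180=0.06, ramp_until_day=30
        ),
        discontinuation_model=DiscontinuationModel(
            event_survival_day180_intervention=0.9,
            event_survival_day180_control=0.85,
            censor_hazard_per_day_intervention=0.002,
            censor_hazard_per_day_control=0.002,
        ),
        deviation_model=DeviationModel(
            pocket_episode_rate=0.02, curiosity_rate=0.01, nonmonitored_rate=0.3
        ),
    )
    base.update(overrides)
    cfg = CohortConfig(**base)
    cfg.validate()
    return cfg


@pytest.fixture(scope="session")
def small_cohort():
    from emadhere.simulate import generate_cohort

    return generate_cohort(tiny_config(), seed=42)


@pytest.fixture(scope="session")
def small_clean(small_cohort):
    from emadhere.clean import clean_cohort

    return clean_cohort(
        small_cohort.events,
        small_cohort.prescriptions,
        small_cohort.reports,
        small_cohort.pill_counts,
        small_cohort.patients,
        tz_offset_minutes=120,
    )


def segments(rows):
    """Build a prescriptions frame from (pid, em, start, end, exp, type, label) tuples."""
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "em_id",
            "start_date",
            "end_date",
            "expected_openings_per_day",
            "segment_type",
            "label_openings_per_day",
        ],
    )
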