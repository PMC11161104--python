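"""Cohort and analysis configuration.

The synthetic cohort is parameterized by marginal *targets* rather than by
raw logistic coefficients: the generator calibrates its latent intake model at
run time so that the cohort's marginal day-level implementation and
persistence probabilities match the configured anchors.  The default
configuration reproduces the study conditions of a two-arm (1:1) electronic
monitoring trial of oral protein kinase inhibitors: ~120 patients, a 21-day
baseline period before randomization, 12 months of daily monitoring, high
daily intake probabilities (0.95-0.98 at six months), oncologist-prescribed
transient treatment interruptions, cyclic regimens and premature treatment
discontinuation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml


class ConfigError(ValueError):
    """Invalid configuration value; the message names the offending field."""


def _check_prob(value: float, name: str, *, closed: bool = True) -> None:
    lo_ok = value >= 0.0 if closed else value > 0.0
    if not (lo_ok and value <= 1.0):
        raise ConfigError(f"{name} must be a probability in [0, 1], got {value!r}")


@dataclass
class IntakeModel:
    """Marginal daily-intake trajectory targets on the probability scale.

    The marginal probability of correct intake on *active* treatment days is
    a logistic trajectory::

        logit m(t) = a + slope * t + effect_per_day * TI(t)

    where ``TI(t)`` is the number of days spent in the intervention arm up to
    day ``t``.  ``a`` and ``effect_per_day`` are solved from the two
    ``*_day180`` anchors; heterogeneity between patients enters through a
    normal random intercept on the log-odds scale, which induces the
    within-patient autocorrelation that the AR(1) working correlation of the
    downstream marginal model is designed to absorb.

    calibration:
        "realized"   -- the conditional intercept is solved each day against
                        the realized random intercepts of the patients at
                        risk, so the cohort marginal matches the target
                        trajectory exactly (up to Bernoulli noise).
        "population" -- the conditional intercept is solved against the
                        population distribution of the random intercept
                        (Gauss-Hermite quadrature); patients remain mutually
                        independent.
    """

    control_day180: float = 0.9503
    intervention_day180: float = 0.9810
    logit_slope_per_day: float = -0.002
    random_intercept_sd: float = 1.0
    anchor_day: int = 180
    calibration: str = "realized"
    #: optional (column, value, extra_effect_per_day) triple giving a patient
    #: subgroup a larger/smaller intervention effect, e.g. ("gender", "M", 0.004)
    effect_modifier: Optional[tuple] = None

    def validate(self) -> None:
        _check_prob(self.control_day180, "intake_model.control_day180")
        _check_prob(self.intervention_day180, "intake_model.intervention_day180")
        if self.random_intercept_sd < 0:
            raise ConfigError("intake_model.random_intercept_sd must be >= 0")
        if self.calibration not in ("realized", "population"):
            raise ConfigError(
                "intake_model.calibration must be 'realized' or 'population', "
                f"got {self.calibration!r}"
            )
        if self.anchor_day <= 0:
            raise ConfigError("intake_model.anchor_day must be positive")


@dataclass
class InterruptionModel:
    """Prescribed transient treatment interruptions.

    A fraction of patients (drawn among those on continuous regimens) is
    interruption-prone; for them interruptions start with a daily hazard that
    ramps up linearly until ``ramp_until_day`` (toxicity accumulates over
    months of treatment) and stays flat afterwards.  Durations are rounded
    log-normal.  The peak hazard is solved at run time so that the expected
    fraction of patient-days spent under interruption around
    ``ramp_until_day`` equals ``prevalence_day180``; that prevalence is what
    separates implementation measured against the prescribed regimen from
    implementation measured against the manufacturer's (on-label) regimen.
    """

    prone_fraction: float = 0.70
    duration_median_days: float = 7.0
    duration_log_sd: float = 0.6
    prevalence_day180: float = 0.0804
    ramp_until_day: int = 180

    def validate(self) -> None:
        _check_prob(self.prone_fraction, "interruption_model.prone_fraction")
        _check_prob(self.prevalence_day180, "interruption_model.prevalence_day180")
        if self.duration_median_days < 1:
            raise ConfigError("interruption_model.duration_median_days must be >= 1 day")
        if self.duration_log_sd < 0:
            raise ConfigError("interruption_model.duration_log_sd must be >= 0")
        if self.ramp_until_day <= 0:
            raise ConfigError("interruption_model.ramp_until_day must be positive")


@dataclass
class DiscontinuationModel:
    """Treatment discontinuation (event) and censoring processes.

    Discontinuation-for-cause (adverse events, patient unilateral decision)
    is the *event* of the persistence analysis; all other exits (progression,
    asymptomatic toxicity, study exit) are censoring.  Both are constant-
    hazard; the event hazard is parameterized through the target Kaplan-Meier
    survival at day 180 post randomization.
    """

    event_survival_day180_intervention: float = 0.915
    event_survival_day180_control: float = 0.893
    censor_hazard_per_day_intervention: float = 0.0025
    censor_hazard_per_day_control: float = 0.0014

    def validate(self) -> None:
        for name in (
            "event_survival_day180_intervention",
            "event_survival_day180_control",
        ):
            _check_prob(getattr(self, name), f"discontinuation_model.{name}", closed=False)
        for name in (
            "censor_hazard_per_day_intervention",
            "censor_hazard_per_day_control",
        ):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ConfigError(f"discontinuation_model.{name} must be in [0, 1)")


@dataclass
class DeviationModel:
    """Reported deviations from nominal monitor use."""

    #: per-day probability that an intake day starts a pocket-dose episode
    pocket_episode_rate: float = 0.008
    #: probability that a pocket episode spans two days rather than one
    pocket_two_day_fraction: float = 0.3
    #: per monitor-day probability of a curiosity opening (no intake)
    curiosity_rate: float = 0.004
    #: per-patient probability of one nonmonitored period (e.g. hospitalization)
    nonmonitored_rate: float = 0.15
    nonmonitored_min_days: int = 3
    nonmonitored_max_days: int = 10

    def validate(self) -> None:
        for name in (
            "pocket_episode_rate",
            "pocket_two_day_fraction",
            "curiosity_rate",
            "nonmonitored_rate",
        ):
            _check_prob(getattr(self, name), f"deviation_model.{name}")
        if not 1 <= self.nonmonitored_min_days <= self.nonmonitored_max_days:
            raise ConfigError(
                "deviation_model.nonmonitored_min_days/max_days must satisfy "
                "1 <= min <= max"
            )


@dataclass
class QuestionnaireModel:
    """Target scale means for simulated questionnaire responses.

    Items are drawn independently around the item-level mean implied by the
    scale target; both arms share the same targets (the trial found no group
    differences in beliefs about medicines or quality of life).
    """

    bmq_means: dict = field(
        default_factory=lambda: {
            "necessity": 18.0,
            "concerns": 15.0,
            "overprescribing": 13.0,
            "prejudices": 12.0,
        }
    )
    qlq_means: dict = field(
        default_factory=lambda: {"functional": 75.0, "symptom": 25.0, "global": 60.0}
    )
    bmq_item_sd: float = 1.0
    qlq_item_sd: float = 0.8
    response_rate: float = 0.9

    def validate(self) -> None:
        _check_prob(self.response_rate, "questionnaire_model.response_rate")
        if self.bmq_item_sd < 0 or self.qlq_item_sd < 0:
            raise ConfigError("questionnaire_model item SDs must be >= 0")


@dataclass
class CohortConfig:
    """Full synthetic-cohort configuration (defaults = study conditions)."""

    n_patients: int = 120
    allocation_ratio: float = 0.5
    baseline_days: int = 21
    horizon_days: int = 360
    #: fraction of patients on a cyclic regimen (e.g. 21 days on / 7 off)
    cyclic_fraction: float = 0.3
    cycle_on_days: int = 21
    cycle_off_days: int = 7
    #: fraction of (continuous-regimen) patients monitored with two monitors
    multi_monitor_fraction: float = 0.1
    #: openings expected per day while on active treatment
    openings_per_day: int = 1
    #: daily intake window (hours, local civil time); a placeholder -- the
    #: within-day distribution of opening times is not informed by data
    intake_window_start_hour: float = 7.0
    intake_window_end_hour: float = 22.0
    #: fraction of openings that land between 00:00 and 03:00 of the next
    #: calendar date (attributed to the previous dosing day by the 03:00 rule)
    after_midnight_fraction: float = 0.05
    utc_offset_minutes: int = 120
    intake_model: IntakeModel = field(default_factory=IntakeModel)
    interruption_model: InterruptionModel = field(default_factory=InterruptionModel)
    discontinuation_model: DiscontinuationModel = field(default_factory=DiscontinuationModel)
    deviation_model: DeviationModel = field(default_factory=DeviationModel)
    questionnaire_model: QuestionnaireModel = field(default_factory=QuestionnaireModel)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        _check_prob(self.allocation_ratio, "allocation_ratio")
        if self.horizon_days < self.baseline_days:
            raise ConfigError("horizon_days must be >= baseline_days")
        if self.baseline_days < 0:
            raise ConfigError("baseline_days must be >= 0")
        _check_prob(self.cyclic_fraction, "cyclic_fraction")
        _check_prob(self.multi_monitor_fraction, "multi_monitor_fraction")
        _check_prob(self.after_midnight_fraction, "after_midnight_fraction")
        if self.openings_per_day < 1:
            raise ConfigError("openings_per_day must be >= 1")
        if not 0 <= self.intake_window_start_hour < self.intake_window_end_hour <= 24:
            raise ConfigError(
                "intake window hours must satisfy 0 <= start < end <= 24"
            )
        if self.cycle_on_days < 1 or self.cycle_off_days < 0:
            raise ConfigError("cycle_on_days must be >= 1 and cycle_off_days >= 0")
        if self.cyclic_fraction >= 1.0 and self.interruption_model.prone_fraction > 0:
            raise ConfigError(
                "interruption_model.prone_fraction requires some patients on a "
                "continuous regimen (cyclic_fraction < 1)"
            )
        if self.cyclic_fraction < 1.0:
            prone_given_continuous = self.interruption_model.prone_fraction / (
                1.0 - self.cyclic_fraction
            )
            if prone_given_continuous > 1.0:
                raise ConfigError(
                    "interruption_model.prone_fraction exceeds the fraction of "
                    "patients on continuous regimens"
                )
        for sub in (
            self.intake_model,
            self.interruption_model,
            self.discontinuation_model,
            self.deviation_model,
            self.questionnaire_model,
        ):
            sub.validate()

    # ------------------------------------------------------------------ presets
    @classmethod
    def paper_calibration(cls, **overrides) -> "CohortConfig":
        """The calibrated study scenario (these are also the plain defaults)."""
        return cls(**overrides)

    @classmethod
    def noiseless(cls, **overrides) -> "CohortConfig":
        """Degenerate deterministic scenario: perfect intake, no dropout,
        no interruptions, no reported deviations.  Downstream implementation
        is exactly 100% on every day and persistence is exactly 1."""
        base = dict(
            cyclic_fraction=0.0,
            multi_monitor_fraction=0.0,
            after_midnight_fraction=0.0,
            intake_model=IntakeModel(
                control_day180=1.0,
                intervention_day180=1.0,
                logit_slope_per_day=0.0,
                random_intercept_sd=0.0,
                calibration="population",
            ),
            interruption_model=InterruptionModel(prone_fraction=0.0),
            discontinuation_model=DiscontinuationModel(
                event_survival_day180_intervention=1.0,
                event_survival_day180_control=1.0,
                censor_hazard_per_day_intervention=0.0,
                censor_hazard_per_day_control=0.0,
            ),
            deviation_model=DeviationModel(
                pocket_episode_rate=0.0,
                curiosity_rate=0.0,
                nonmonitored_rate=0.0,
            ),
        )
        base.update(overrides)
        return cls(**base)

    # ------------------------------------------------------------------ YAML io
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        em = d["intake_model"]["effect_modifier"]
        if em is not None:
            d["intake_model"]["effect_modifier"] = list(em)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        subs = {
            "intake_model": IntakeModel,
            "interruption_model": InterruptionModel,
            "discontinuation_model": DiscontinuationModel,
            "deviation_model": DeviationModel,
            "questionnaire_model": QuestionnaireModel,
        }
        for key, sub_cls in subs.items():
            if key in d and isinstance(d[key], dict):
                d[key] = sub_cls(**d[key])
        if isinstance(d.get("intake_model"), IntakeModel):
            em = d["intake_model"].effect_modifier
            if em is not None:
                d["intake_model"].effect_modifier = tuple(em)
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
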