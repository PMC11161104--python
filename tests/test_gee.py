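"""Marginal-model layer: fitting, predictions, identifiability, recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from emadhere.config import CohortConfig, IntakeModel
from emadhere.clean import clean_cohort
from emadhere.estimators import daily_outcome
from emadhere.gee import (
    DegenerateOutcomeError,
    GeeFit,
    GeeSpec,
    bootstrap_representative,
    build_adherence_panel,
    build_panel,
    fit_adherence_gee,
    fit_implementation_gee,
    fit_population_gee,
    predict_representative,
    subgroup_analysis,
)
from emadhere.simulate import generate_cohort, marginal_parameters, simulate_outcome_panel


def _small_scenario(p_ctrl=0.90, p_int=0.96, n=40, horizon=120, calibration="population"):
    return CohortConfig(
        n_patients=n,
        horizon_days=horizon,
        baseline_days=21,
        cyclic_fraction=0.0,
        multi_monitor_fraction=0.0,
        intake_model=IntakeModel(
            control_day180=p_ctrl,
            intervention_day180=p_int,
            logit_slope_per_day=0.0,
            calibration=calibration,
        ),
    )


class TestFitBasics:
    def test_all_correct_outcomes_are_degenerate(self):
        panel = pd.DataFrame(
            {
                "patient_id": np.repeat(["a", "b", "c"], 10),
                "day_index": np.tile(np.arange(10), 3),
                "value": 1.0,
                "arm": "control",
                "randomized": True,
                "randomization_day": 2,
            }
        )
        from emadhere.gee import add_exposures

        with pytest.raises(DegenerateOutcomeError, match="all correct"):
            fit_implementation_gee(add_exposures(panel))

    def test_zero_coefficients_predict_one_half(self):
        class _Zero:
            params = np.zeros(6)

            def cov_params(self):
                return np.zeros((6, 6))

        fit = GeeFit(
            result=_Zero(), spec=GeeSpec(), exposure="ti_tc",
            day_center=0.0, day_scale=1.0, exposure_scale=1.0,
        )
        pred = predict_representative(fit, 180, 21)
        assert pred.p_intervention == pytest.approx(0.5)
        assert pred.p_control == pytest.approx(0.5)
        assert pred.delta == pytest.approx(0.0)

    def test_model_card_records_fit_metadata(self):
        panel, _ = simulate_outcome_panel(_small_scenario(), seed=0)
        from emadhere.gee import add_exposures

        fit = fit_implementation_gee(add_exposures(panel))
        card = fit.model_card
        assert card["degree"] == 3
        assert card["correlation"] == "ar1"
        assert card["n_patients"] == panel["patient_id"].nunique()
        assert card["exposure"] == "ti_tc"

    def test_zero_effect_contrast_is_small(self):
        cfg = _small_scenario(p_ctrl=0.92, p_int=0.92, n=60, horizon=120)
        panel, _ = simulate_outcome_panel(cfg, seed=1)
        from emadhere.gee import add_exposures

        fit = fit_implementation_gee(add_exposures(panel))
        pred = predict_representative(fit, day=90, randomization_day=21)
        assert abs(pred.delta) < 4 * pred.se + 1e-6
        assert pred.lo <= pred.delta <= pred.hi


class TestInvariances:
    def test_predictions_invariant_to_time_rescaling(self):
        panel, _ = simulate_outcome_panel(_small_scenario(), seed=2)
        from emadhere.gee import add_exposures

        p1 = add_exposures(panel)
        fit1 = fit_implementation_gee(p1)
        pred1 = predict_representative(fit1, 90, 21)

        scaled = panel.copy()
        scaled["day_index"] = scaled["day_index"] / 100.0
        scaled["randomization_day"] = scaled["randomization_day"] / 100.0
        p2 = add_exposures(scaled)
        fit2 = fit_implementation_gee(p2)
        pred2 = predict_representative(fit2, 90 / 100.0, 21 / 100.0)
        assert pred2.p_intervention == pytest.approx(pred1.p_intervention, abs=1e-6)
        assert pred2.p_control == pytest.approx(pred1.p_control, abs=1e-6)
        assert pred2.delta == pytest.approx(pred1.delta, abs=1e-6)

    def test_parameter_recovery_over_replicates(self):
        """Mean representative difference over replicates matches the
        generating marginal difference within Monte-Carlo error."""
        cfg = _small_scenario(p_ctrl=0.88, p_int=0.95, n=40, horizon=120)
        a, s, d = marginal_parameters(cfg)
        day, r = 90, 21
        true_delta = float(expit(a + s * day + d * (day - r)) - expit(a + s * day))
        from emadhere.gee import add_exposures

        deltas = []
        for seed in range(100):
            panel, _ = simulate_outcome_panel(cfg, seed=seed)
            fit = fit_implementation_gee(add_exposures(panel))
            deltas.append(predict_representative(fit, day, r).delta)
        mean = float(np.mean(deltas))
        mc_se = float(np.std(deltas) / np.sqrt(len(deltas)))
        assert mean == pytest.approx(true_delta, abs=max(4 * mc_se, 0.01))


@pytest.fixture(scope="module")
def modifier_cohort():
    cfg = CohortConfig(
        n_patients=90,
        horizon_days=150,
        cyclic_fraction=0.0,
        multi_monitor_fraction=0.0,
        intake_model=IntakeModel(
            control_day180=0.90,
            intervention_day180=0.95,
            logit_slope_per_day=0.0,
            effect_modifier=("gender", "M", 0.012),
        ),
    )
    cohort = generate_cohort(cfg, 21)
    res = clean_cohort(
        cohort.events, cohort.prescriptions, cohort.reports,
        cohort.pill_counts, cohort.patients, tz_offset_minutes=120,
    )
    oc = daily_outcome(res.table, "prescribed")
    return build_panel(oc, cohort.patients)


class TestSubgroupsAndAdherence:
    def test_modified_subgroup_shows_larger_contrast(self, modifier_cohort):
        tab = subgroup_analysis(
            modifier_cohort, "gender", GeeSpec(), day=120, randomization_day=21
        )
        by = tab.set_index("stratum")["delta"]
        assert by["gender = M"] > by["gender = F"]

    def test_continuous_covariable_dichotomized_at_cut(self, modifier_cohort):
        tab = subgroup_analysis(
            modifier_cohort, "age", GeeSpec(), day=120, randomization_day=21, cut=60
        )
        assert set(tab["stratum"]) == {"age <= 60", "age > 60"}

    def test_tiny_stratum_marked_inestimable(self, modifier_cohort):
        panel = modifier_cohort.copy()
        # make one stratum contain a single patient
        one = panel["patient_id"] == panel["patient_id"].iloc[0]
        panel["rare_flag"] = np.where(one, "yes", "no")
        tab = subgroup_analysis(panel, "rare_flag", GeeSpec(), 120, 21)
        row = tab.set_index("stratum").loc["rare_flag = yes"]
        assert np.isnan(row["delta"])

    def test_adherence_panel_fills_zeros_after_events(self):
        pat = pd.DataFrame(
            {
                "patient_id": ["a", "b"],
                "arm": ["intervention", "control"],
                "randomized": [True, True],
                "inclusion_date": ["2022-01-01"] * 2,
                "randomization_date": ["2022-01-08"] * 2,
                "end_date": ["2022-01-28", "2022-02-28"],
                "exit_reason": ["adverse_event", "study_completed"],
            }
        )
        oc = pd.DataFrame(
            {
                "patient_id": np.repeat(["a", "b"], 40),
                "day_index": np.tile(np.arange(40), 2),
                "value": 1.0,
            }
        )
        oc = oc[
            (oc["patient_id"] == "b") | (oc["day_index"] <= 27)
        ]
        panel = build_adherence_panel(oc, pat, window_days=50)
        after = panel[(panel["patient_id"] == "a") & (panel["day_index"] > 20)]
        assert (after["value"] == 0.0).all()
        assert after["day_index"].max() == 50

    def test_no_discontinuation_adherence_fit_close_to_implementation(self):
        cfg = _small_scenario(p_ctrl=0.9, p_int=0.9, n=50, horizon=120)
        cfg.discontinuation_model.event_survival_day180_intervention = 1.0
        cfg.discontinuation_model.event_survival_day180_control = 1.0
        cfg.discontinuation_model.censor_hazard_per_day_intervention = 0.0
        cfg.discontinuation_model.censor_hazard_per_day_control = 0.0
        cohort = generate_cohort(cfg, 8)
        res = clean_cohort(
            cohort.events, cohort.prescriptions, cohort.reports,
            cohort.pill_counts, cohort.patients, tz_offset_minutes=120,
        )
        oc = daily_outcome(res.table, "prescribed")
        adh_panel = build_adherence_panel(oc, cohort.patients, window_days=95)
        fit = fit_adherence_gee(adh_panel)
        pred = predict_representative(fit, day=60, randomization_day=0)
        impl_panel = build_panel(oc, cohort.patients, extra_covariables=False)
        pop = fit_population_gee(impl_panel)
        p_impl = pop.predict_probability(81)[0]  # day 60 post-randomization
        assert pred.p_control == pytest.approx(p_impl, abs=0.04)
        assert pred.p_intervention == pytest.approx(p_impl, abs=0.04)

    def test_bootstrap_option_returns_interval(self):
        panel, _ = simulate_outcome_panel(_small_scenario(n=25, horizon=60), seed=4)
        from emadhere.gee import add_exposures

        out = bootstrap_representative(
            add_exposures(panel), GeeSpec(degree=2), day=50, randomization_day=21,
            n_boot=8, seed=0,
        )
        assert out["n_effective"] > 0
        assert out["lo"] <= out["hi"]
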