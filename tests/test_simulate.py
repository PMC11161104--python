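"""Synthetic-cohort generator: determinism, calibration, degenerate cases."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from emadhere.clean import clean_cohort
from emadhere.config import CohortConfig, ConfigError, IntakeModel
from emadhere.estimators import daily_outcome, km_persistence, persistence_records
from emadhere.schedule import transient_interruptions
from emadhere.simulate import (
    generate_cohort,
    interruption_duration_pmf,
    marginal_parameters,
    simulate_outcome_panel,
    solve_conditional_intercept,
    solve_interruption_hazard,
)

from conftest import tiny_config


class TestConfig:
    def test_invalid_probability_names_the_field(self):
        cfg = tiny_config()
        cfg.intake_model.control_day180 = 1.7
        with pytest.raises(ConfigError, match="control_day180"):
            cfg.validate()

    def test_duration_below_one_day_rejected(self):
        cfg = tiny_config()
        cfg.interruption_model.duration_median_days = 0.2
        with pytest.raises(ConfigError, match="duration_median_days"):
            cfg.validate()

    def test_horizon_must_cover_baseline(self):
        with pytest.raises(ConfigError, match="horizon"):
            CohortConfig(horizon_days=10, baseline_days=21).validate()

    def test_yaml_round_trip(self, tmp_path):
        cfg = tiny_config()
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        again = CohortConfig.from_yaml(path)
        assert again == cfg


class TestDeterminism:
    def test_same_seed_same_bytes(self, tmp_path):
        cfg = tiny_config()
        a_dir, b_dir = tmp_path / "a", tmp_path / "b"
        generate_cohort(cfg, 9).write(a_dir)
        generate_cohort(cfg, 9).write(b_dir)
        for name in ("patients.csv", "events.csv", "prescriptions.csv",
                     "reports.csv", "pill_counts.csv", "questionnaires.csv",
                     "truth.json"):
            assert (a_dir / name).read_bytes() == (b_dir / name).read_bytes(), name

    def test_different_seeds_differ(self):
        cfg = tiny_config()
        a = generate_cohort(cfg, 1)
        b = generate_cohort(cfg, 2)
        assert not a.events.equals(b.events)


class TestNoiselessScenario:
    def test_perfect_cohort_has_perfect_implementation_and_persistence(self):
        cfg = CohortConfig.noiseless(n_patients=15, horizon_days=50)
        cohort = generate_cohort(cfg, 3)
        res = clean_cohort(
            cohort.events, cohort.prescriptions, cohort.reports,
            cohort.pill_counts, cohort.patients, tz_offset_minutes=120,
        )
        # openings equal prescribed expectations on every patient-day
        assert (
            res.table["observed_openings"] == res.table["expected_prescribed"]
        ).all()
        oc = daily_outcome(res.table, "prescribed")
        assert (oc["value"] == 1.0).all()
        rec = persistence_records(cohort.patients)
        km = km_persistence(rec, max_day=cfg.horizon_days - 1 - cfg.baseline_days)
        assert (km["estimate"] == 1.0).all()


class TestTruthConsistency:
    def test_injected_deviations_are_reported_exactly(self, small_cohort):
        truth_eps = sum(
            len(p["pocket_episodes"]) for p in small_cohort.truth["patients"].values()
        )
        rep = small_cohort.reports
        assert truth_eps == (rep["report_type"] == "pocket_dose").sum()
        truth_days = sum(
            mon_e - s + 1
            for p in small_cohort.truth["patients"].values()
            for _, s, mon_e in [(e[0], e[1], e[2]) for e in p["pocket_episodes"]]
        )
        assert truth_days == rep.query("report_type == 'pocket_dose'")["count"].sum()
        truth_nm = sum(
            len(p["nonmonitored"]) for p in small_cohort.truth["patients"].values()
        )
        per_monitor = rep.query("report_type == 'nonmonitored'")
        # one report row per monitor per window
        n_monitors = {
            pid: p["n_monitors"] for pid, p in small_cohort.truth["patients"].items()
        }
        expected_rows = sum(
            len(p["nonmonitored"]) * p["n_monitors"]
            for p in small_cohort.truth["patients"].values()
        )
        assert len(per_monitor) == expected_rows
        assert truth_nm >= 0  # structural sanity

    def test_no_events_after_observation_end(self, small_cohort):
        pat = small_cohort.patients.set_index("patient_id")
        ev = small_cohort.events.copy()
        from emadhere.clean import assign_dosing_day

        ev["day"] = assign_dosing_day(ev["timestamp"], 120)
        for pid, grp in ev.groupby("patient_id"):
            assert grp["day"].max() <= pd.Timestamp(pat.loc[pid, "end_date"])


class TestCalibration:
    def test_conditional_intercept_matches_target_at_large_n(self):
        # law of large numbers: the realized-mode solver hits the marginal
        rng = np.random.default_rng(0)
        b = rng.normal(0, 1.0, 5000)
        for target in (0.5, 0.9, 0.95, 0.98):
            c = solve_conditional_intercept(target, b_values=b)
            assert np.mean(expit(c + b)) == pytest.approx(target, abs=1e-9)
        c_pop = solve_conditional_intercept(0.95, sigma=1.0)
        assert np.mean(expit(c_pop + b)) == pytest.approx(0.95, abs=0.01)

    def test_marginal_parameters_solve_the_anchors(self):
        cfg = CohortConfig()
        a, s, d = marginal_parameters(cfg)
        assert expit(a + s * 180) == pytest.approx(0.9503)
        assert expit(a + s * 180 + d * 159) == pytest.approx(0.9810)

    def test_constant_probability_panel_recovers_binomial_marginal(self):
        # flat trajectory p = 0.9, no interruptions: every day's empirical
        # implementation stays within a 99.9% binomial band around 0.9
        cfg = CohortConfig.noiseless(
            n_patients=1000,
            horizon_days=30,
            baseline_days=5,
            intake_model=IntakeModel(
                control_day180=0.9, intervention_day180=0.9,
                logit_slope_per_day=0.0, anchor_day=20,
                random_intercept_sd=1.0, calibration="population",
            ),
        )
        panel, truth = simulate_outcome_panel(cfg, seed=5)
        daily = panel.groupby("day_index")["value"].mean()
        band = 3.29 * np.sqrt(0.9 * 0.1 / 1000)
        assert (np.abs(daily - 0.9) < band + 0.005).all()

    def test_interruption_hazard_reproduces_target_prevalence(self):
        cfg = CohortConfig()
        pmf = interruption_duration_pmf(
            cfg.interruption_model.duration_median_days,
            cfg.interruption_model.duration_log_sd,
        )
        assert pmf.sum() == pytest.approx(1.0)
        h = solve_interruption_hazard(cfg)
        assert h > 0
        # simulate the renewal process directly and measure day-180 prevalence
        rng = np.random.default_rng(0)
        m = cfg.interruption_model
        hits = 0
        n_sim = 3000
        for _ in range(n_sim):
            t, interrupted_at_180 = 0, False
            while t <= 180:
                if rng.random() < h * min(t, m.ramp_until_day) / m.ramp_until_day:
                    dur = max(1, int(round(rng.lognormal(np.log(m.duration_median_days),
                                                         m.duration_log_sd))))
                    if t <= 180 <= t + dur - 1:
                        interrupted_at_180 = True
                    t += dur + 2
                else:
                    t += 1
            hits += interrupted_at_180
        target = m.prevalence_day180 / m.prone_fraction
        assert hits / n_sim == pytest.approx(target, abs=0.025)


class TestStudyScenario:
    def test_interruption_descriptives_match_study_conditions(self):
        cfg = CohortConfig.paper_calibration()
        durations, fractions = [], []
        for seed in (11, 12, 13):
            cohort = generate_cohort(cfg, seed)
            res = clean_cohort(
                cohort.events, cohort.prescriptions, cohort.reports,
                cohort.pill_counts, cohort.patients, tz_offset_minutes=120,
            )
            wins = transient_interruptions(res.table, min_run=3)
            durations.extend(wins["duration_days"].tolist())
            fractions.append(wins["patient_id"].nunique() / cfg.n_patients)
        assert np.median(durations) == pytest.approx(7, abs=1)
        # roughly half the cohort experiences a >2-day interruption
        assert np.mean(fractions) == pytest.approx(0.56, abs=0.10)

    def test_events_only_within_monitored_windows(self, small_cohort, small_clean):
        assert small_clean.qc["n_events_flagged_out_of_window"] == 0

    def test_truth_is_not_consumed_by_the_pipeline(self, small_cohort, tmp_path):
        # the cleaning pipeline runs identically with truth.json absent
        small_cohort.write(tmp_path)
        (tmp_path / "truth.json").unlink()
        res = clean_cohort(
            pd.read_csv(tmp_path / "events.csv"),
            pd.read_csv(tmp_path / "prescriptions.csv"),
            pd.read_csv(tmp_path / "reports.csv"),
            pd.read_csv(tmp_path / "pill_counts.csv"),
            pd.read_csv(tmp_path / "patients.csv"),
            tz_offset_minutes=120,
        )
        assert len(res.table) > 0
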