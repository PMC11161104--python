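"""Outcome definitions and the implementation/persistence/adherence curves."""

import numpy as np
import pandas as pd
import pytest

from emadhere.estimators import (
    curve_at,
    daily_outcome,
    empirical_adherence,
    empirical_implementation,
    km_persistence,
    persistence_records,
    to_randomization_clock,
)


def _table(rows):
    return pd.DataFrame(
        rows,
        columns=["patient_id", "em_id", "day_index", "observed_openings",
                 "pocket_dose_credit", "expected_prescribed", "expected_onlabel",
                 "monitored"],
    )


def _records(rows):
    return pd.DataFrame(rows, columns=["patient_id", "time_days", "event"])


class TestDailyOutcome:
    def test_at_least_rule(self):
        t = _table(
            [
                ("P1", "E1", 0, 2, 0, 2, 2, True),   # exactly enough
                ("P1", "E1", 1, 3, 0, 2, 2, True),   # more than enough
                ("P1", "E1", 2, 1, 0, 2, 2, True),   # deficit
            ]
        )
        oc = daily_outcome(t, "prescribed").set_index("day_index")["value"]
        assert list(oc) == [1.0, 1.0, 0.0]

    def test_every_monitor_must_be_satisfied(self):
        t = _table(
            [
                ("P1", "E1", 0, 1, 0, 1, 1, True),
                ("P1", "E2", 0, 0, 0, 1, 1, True),
            ]
        )
        assert daily_outcome(t, "prescribed")["value"].iloc[0] == 0.0

    def test_interruption_day_correct_prescribed_incorrect_onlabel(self):
        t = _table([("P1", "E1", 0, 0, 0, 0, 1, True)])
        assert daily_outcome(t, "prescribed")["value"].iloc[0] == 1.0
        assert daily_outcome(t, "onlabel")["value"].iloc[0] == 0.0

    def test_pocket_credit_counts_toward_expected(self):
        t = _table([("P1", "E1", 0, 0, 1, 1, 1, True)])
        assert daily_outcome(t, "prescribed")["value"].iloc[0] == 1.0

    def test_unmonitored_day_is_missing(self):
        t = _table([("P1", "E1", 0, 0, 0, 1, 1, False)])
        assert np.isnan(daily_outcome(t, "prescribed")["value"].iloc[0])


class TestImplementationCurve:
    def test_three_of_four_is_75_percent(self):
        oc = pd.DataFrame(
            {"patient_id": list("abcd"), "day_index": 0, "value": [1, 1, 1, 0.0]}
        )
        cur = empirical_implementation(oc)
        assert curve_at(cur, 0) == pytest.approx(0.75)
        assert cur.loc[0, "n"] == 4
        assert cur.loc[0, "lo"] <= 0.75 <= cur.loc[0, "hi"]

    def test_all_correct_gives_constant_one(self):
        oc = pd.DataFrame(
            {"patient_id": ["a"] * 5 + ["b"] * 5, "day_index": list(range(5)) * 2,
             "value": 1.0}
        )
        cur = empirical_implementation(oc)
        assert (cur["estimate"] == 1.0).all()

    def test_missing_values_leave_denominator(self):
        oc = pd.DataFrame(
            {"patient_id": list("abc"), "day_index": 0, "value": [1.0, np.nan, 0.0]}
        )
        cur = empirical_implementation(oc)
        assert cur.loc[0, "n"] == 2
        assert curve_at(cur, 0) == pytest.approx(0.5)


class TestKaplanMeier:
    def test_no_events_means_survival_one_everywhere(self):
        rec = _records([(f"p{i}", 100, False) for i in range(10)])
        km = km_persistence(rec, max_day=100)
        assert (km["estimate"] == 1.0).all()

    def test_single_event_among_ten(self):
        rec = _records([("p0", 10, True)] + [(f"p{i}", 50, False) for i in range(1, 10)])
        km = km_persistence(rec, max_day=50)
        assert curve_at(km, 9) == pytest.approx(1.0)
        assert curve_at(km, 10) == pytest.approx(0.9)
        assert curve_at(km, 50) == pytest.approx(0.9)

    def test_staggered_censoring_matches_hand_product_limit(self):
        # events at 2 (6 at risk) and 5 (3 at risk); censor at 3, 4, 7; one to 10
        rec = _records(
            [
                ("a", 2, True),
                ("b", 3, False),
                ("c", 4, False),
                ("d", 5, True),
                ("e", 7, False),
                ("f", 10, False),
            ]
        )
        km = km_persistence(rec, max_day=10)
        assert curve_at(km, 2) == pytest.approx(5 / 6)
        assert curve_at(km, 4) == pytest.approx(5 / 6)
        assert curve_at(km, 5) == pytest.approx(5 / 6 * 2 / 3)
        assert curve_at(km, 10) == pytest.approx(5 / 6 * 2 / 3)
        assert (km["estimate"].diff().dropna() <= 1e-12).all()

    def test_km_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(0)
        times = rng.integers(1, 60, 40)
        rec = _records([(f"p{i}", t, True) for i, t in enumerate(times)])
        km = km_persistence(rec, max_day=60)
        for d in (0, 10, 30, 59):
            assert curve_at(km, d) == pytest.approx((times > d).mean())

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            km_persistence(_records([("a", -1, True)]))


class TestAdherence:
    def _outcomes(self, n=6, days=30, value=1.0):
        return pd.DataFrame(
            {
                "patient_id": np.repeat([f"p{i}" for i in range(n)], days),
                "day_index": np.tile(np.arange(days), n),
                "value": value,
            }
        )

    def test_no_discontinuation_adherence_equals_implementation(self):
        oc = self._outcomes()
        rec = _records([(f"p{i}", 29, False) for i in range(6)])
        adh = empirical_adherence(oc, rec, window_days=29)["product"]
        impl = empirical_implementation(oc, max_day=29)
        np.testing.assert_allclose(adh["estimate"], impl["estimate"])

    def test_product_form_value(self):
        # I = 0.98 and S = 0.9 combine to A = 0.882
        assert 0.98 * 0.90 == pytest.approx(0.882)
        n, days = 50, 20
        oc = self._outcomes(n, days)
        # five events on day 9 -> S(10+) = 0.9
        rec = _records(
            [(f"p{i}", 9, True) for i in range(5)]
            + [(f"p{i}", days - 1, False) for i in range(5, n)]
        )
        oc = oc[~((oc["patient_id"].isin([f"p{i}" for i in range(5)])) & (oc["day_index"] > 9))]
        adh = empirical_adherence(oc, rec, window_days=days - 1)
        assert curve_at(adh["product"], 15) == pytest.approx(0.9)

    def test_product_bounded_by_both_factors(self):
        oc = self._outcomes(10, 20)
        rng = np.random.default_rng(1)
        oc["value"] = (rng.random(len(oc)) < 0.9).astype(float)
        rec = _records(
            [(f"p{i}", int(t), bool(e)) for i, (t, e) in enumerate(
                zip(rng.integers(5, 20, 10), rng.random(10) < 0.5))]
        )
        oc = oc.merge(rec[["patient_id", "time_days"]], on="patient_id")
        oc = oc[oc["day_index"] <= oc["time_days"]].drop(columns=["time_days"])
        curves = empirical_adherence(oc, rec, window_days=19)
        impl = empirical_implementation(oc, max_day=19)
        km = km_persistence(rec, max_day=19)
        a = curves["product"]["estimate"]
        ok = ~a.isna()
        assert (a[ok] <= impl["estimate"][ok] + 1e-12).all()
        assert (a[ok] <= km["estimate"][ok] + 1e-12).all()

    def test_empirical_variant_counts_discontinued_as_zero(self):
        oc = self._outcomes(4, 10)
        rec = _records(
            [("p0", 4, True)] + [(f"p{i}", 9, False) for i in range(1, 4)]
        )
        oc = oc[~((oc["patient_id"] == "p0") & (oc["day_index"] > 4))]
        emp = empirical_adherence(oc, rec, window_days=9)["empirical"]
        # day 6: three observed correct + one discontinued zero
        assert curve_at(emp, 6) == pytest.approx(3 / 4)

    def test_mismatched_cohorts_raise(self):
        oc = self._outcomes(3, 5)
        rec = _records([("p0", 4, False), ("p1", 4, False)])
        with pytest.raises(ValueError, match="without persistence"):
            empirical_adherence(oc, rec, window_days=4)


class TestClocksAndRecords:
    def test_persistence_classification_from_exit_reasons(self):
        pat = pd.DataFrame(
            {
                "patient_id": ["a", "b", "c", "d"],
                "arm": ["intervention"] * 4,
                "randomized": [True, True, True, False],
                "inclusion_date": ["2022-01-01"] * 4,
                "randomization_date": ["2022-01-22"] * 3 + [""],
                "end_date": ["2022-03-01", "2022-04-01", "2022-02-10", "2022-01-10"],
                "exit_reason": ["adverse_event", "progression", "personal", "study_exit"],
            }
        )
        rec = persistence_records(pat, clock="randomization")
        assert len(rec) == 3  # never-randomized patient excluded
        assert rec.set_index("patient_id")["event"].to_dict() == {
            "a": True, "b": False, "c": True,
        }

    def test_randomization_clock_drops_baseline_days(self):
        oc = pd.DataFrame(
            {"patient_id": "a", "day_index": np.arange(30), "value": 1.0}
        )
        pat = pd.DataFrame(
            {
                "patient_id": ["a"],
                "randomized": [True],
                "inclusion_date": ["2022-01-01"],
                "randomization_date": ["2022-01-08"],
            }
        )
        shifted = to_randomization_clock(oc, pat, window_days=340)
        assert shifted["day_index"].min() == 0
        assert shifted["day_index"].max() == 22  # 29 - 7
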