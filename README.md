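# emadhere

Analysis pipeline for **electronic-monitor (EM) dosing histories** in oral
anticancer therapy trials — from raw cap-opening event logs to implementation,
persistence and adherence estimates.

Oral protein kinase inhibitors (PKIs) are self-managed at home, so whether
patients actually take them as prescribed is invisible to the clinic. EM pill
bottles record a timestamp at every opening, a proxy for drug intake. Turning
those logs into defensible adherence statistics requires a surprising amount
of reconciliation: prescriptions change over time, oncologists prescribe
transient treatment interruptions (so *not* opening the bottle is optimal
implementation), some regimens are cyclic (e.g. 21 days on / 7 off), patients
take "pocket doses" removed from the bottle in advance, open caps out of
curiosity, or spend hospitalized days unmonitored. `emadhere` implements this
reconciliation and the downstream estimators as a tested, reusable package,
with a synthetic-cohort generator that reproduces the statistical structure of
a two-arm randomized adherence trial (~120 patients, 21-day baseline before
randomization, 12 months of daily monitoring).

## The outcomes and models

For each patient and day *t*, intake is **correct** (y = 1) when every one of
the patient's monitors shows at least as many openings (plus confirmed
pocket-dose credits) as the expected openings that day; days under a
prescribed interruption or a scheduled cycle-off week have expectation 0 and
are correct by definition. Three curves summarize the cohort:

- **Implementation** I(t): proportion of correct outcomes among patients still
  observed on day *t*.
- **Persistence** S(t): Kaplan–Meier probability of remaining on treatment;
  the event is premature discontinuation for adverse events or patient
  unilateral reasons, every other exit is censoring.
- **Adherence** A(t) = I(t) · S(t): correct intake among all patients
  initially included (an empirical variant keeping discontinued patients in
  the denominator with outcome 0 is also computed).

The intervention effect on the daily binary outcome is estimated by a
**GEE** (logit link, AR(1) working correlation, robust covariance) with a
polynomial time trend and two time-dependent exposures — days spent in the
intervention arm TI(t) and in the control arm TC(t) since randomization:

    logit P(y_it = 1) = β₀ + Σ_k β_k t^k + β_TI · TI_i(t) + β_TC · TC_i(t)

Effects are reported as *representative-patient* probabilities at 6 months: a
patient randomized to the intervention at day 21 (TI = 159, TC = 0) versus a
control patient (TI = 0, TC = 159), with the difference Δ and a delta-method
95% CI. A second comparison recomputes implementation against the
manufacturer's **on-label** regimen, in which prescribed interruptions count
as missed doses — quantifying how much naive on-label scoring underestimates
implementation. BMQ (beliefs about medicines) and EORTC QLQ-C30 (quality of
life) questionnaires are scored with the instruments' standard formulas and
compared between arms with Welch's t tests.

## Worked example

```python
from emadhere import (CohortConfig, generate_cohort, clean_cohort, daily_outcome,
                      build_panel, fit_implementation_gee, predict_representative,
                      persistence_records, km_persistence, GeeSpec)
from emadhere.estimators import curve_at

config = CohortConfig.paper_calibration()      # the calibrated study scenario
cohort = generate_cohort(config, seed=7)       # raw EM logs + prescriptions + reports
result = clean_cohort(cohort.events, cohort.prescriptions, cohort.reports,
                      cohort.pill_counts, cohort.patients, tz_offset_minutes=120)
outcomes = daily_outcome(result.table, "prescribed")
panel = build_panel(outcomes, cohort.patients)
fit = fit_implementation_gee(panel, GeeSpec(degree=3))
pred = predict_representative(fit, day=180, randomization_day=21)
print(f"implementation at 6 months: intervention {pred.p_intervention:.1%}, "
      f"control {pred.p_control:.1%}")
print(f"difference {pred.delta * 100:.2f} points "
      f"(95% CI {pred.lo * 100:.2f}; {pred.hi * 100:.2f})")
records = persistence_records(cohort.patients, clock="randomization")
for arm in ("intervention", "control"):
    km = km_persistence(records[records["arm"] == arm], max_day=340)
    print(f"persistence at 6 months ({arm}): {curve_at(km, 180):.1%}")
```

prints

```
implementation at 6 months: intervention 98.2%, control 95.6%
difference 2.67 points (95% CI 1.56; 3.78)
persistence at 6 months (intervention): 84.7%
persistence at 6 months (control): 91.9%
```

The implementation model says a representative intervention-arm patient takes
the prescribed doses on ~98% of days at month 6 versus ~96% for a control
patient — a ~2.7-point benefit for this simulated trial. Kaplan–Meier
persistence from a single 120-patient trial is noisy (± 4–5 points at 6
months with ~58 patients per arm); the seed-averaged replication below is
what recovers the calibrated values (91.5% / 89.3%).

The same stages are available from a shell:

```bash
emadhere simulate --out raw/ --seed 7
emadhere clean --events raw/events.csv --prescriptions raw/prescriptions.csv \
    --reports raw/reports.csv --pill-counts raw/pill_counts.csv \
    --patients raw/patients.csv --out cleaned/ --tz-offset 120
emadhere report --out artifacts/ --seed 7     # full pipeline + figures + manifest
```

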