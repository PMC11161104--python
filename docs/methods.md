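# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `emadhere`. It is the package's own
account of its science; every number quoted here is computed by the test
suite or by `scripts/acceptance.py` / `scripts/calibrate.py`.

## 1. Dosing-day construction and cleaning

EM timestamps are converted to local civil time and assigned to *dosing days*
running 03:00–02:59 (an opening at 01:30 on date D belongs to day D−1). The
early-morning boundary makes daylight-saving transitions (02:00–03:00) safe by
construction. Events outside a monitor's period of use are flagged, never
silently dropped. Cleaning is deterministic; a brute-force day-by-day
reference implementation (pure-python loops) reproduces the production table
exactly on small cohorts, which is the pipeline's correctness oracle.

Corrections applied, in order:

1. **Curiosity openings** (reported openings without intake) are subtracted
   from the day's count, floor 0. The treatment of curiosity checks is
   genuinely open — they could also simply be ignored — so the policy is a
   parameter (`curiosity_policy: subtract | ignore`, default `subtract`,
   symmetric with pocket-dose crediting).
2. **Pocket doses** (doses removed in advance and taken on a day with no
   opening) are credited back onto deficit days inside the reported window —
   chronologically, one credit per day — but only up to the surplus confirmed
   by the pharmacy pill count for the covering refill period(s): pills that
   left the bottle beyond the recorded openings, in units of tablets per
   opening. A report with no covering pill count or no surplus yields no
   credit and a QC warning. The chronological tie-break is a design choice
   (auditable; the alternative — crediting the largest deficits first — is
   indistinguishable for 1-opening regimens).
3. **Nonmonitored periods** (e.g. hospitalizations) set `monitored = False`;
   the daily outcome is missing there and those patient-days leave every
   denominator. Masking never alters counts on other days.

Expected openings come from the prescription history under two conventions:
**prescribed** (interruption days have expectation 0 — taking nothing is
optimal implementation) and **on-label** (the manufacturer's regimen stays in
force during interruptions). Cycle-off weeks have expectation 0 under both.
Prescription segments are inclusive on both ends, must not overlap, and must
cover the monitor's span without gaps (a day under monitoring must have a
defined expectation); interruption reason codes (clinical / administrative /
patient request) are carried through for reporting but treated identically in
computation. A *transient interruption* for descriptive statistics is a
maximal run of prescribed-zero / label-positive days longer than 2 days.

## 2. Marginal models

The daily binary outcome is modelled population-averaged with GEE: logit
link, polynomial time trend (default degree 3, reported in the model card —
high enough to track the early post-randomization rise and late drift of the
empirical curves), AR(1) working correlation (`grid` variant: observations
are treated as equally spaced; masked days make the spacing only
approximately even, which affects efficiency, not consistency), robust
sandwich covariance, warm-started from an independence GLM.

**Exposure parameterization.** Group membership enters through
time-dependent exposures: TI(t) and TC(t), the days spent post-randomization
in the intervention and control arm. Both are 0 during the baseline period
and for never-randomized patients (who thereby contribute to the shared
baseline trajectory, behaving as control patients until lost to follow-up).
This is an identifiability requirement, not a taste: if baseline time were
counted toward TC, then TI + TC ≡ t and the design would be exactly
collinear with any time trend. With the post-randomization definition,
TI + TC = (t − r)⁺ is a kinked function of study time that a polynomial
cannot absorb, so both coefficients are estimable (their sum direction is
weakly determined; the reported contrast is not). Representative-patient
predictions at day d use (TI = d − r, TC = 0) versus (TI = 0, TC = d − r),
r = 21 by default. The 95% CI of the difference is the delta method on the
two linear predictors with the robust covariance; a patient-level bootstrap
(default 500 resamples, seeded) is available as an option because no single
method is canonical for this contrast.

On the **randomization clock** (adherence model: baseline excluded, outcome 0
after a discontinuation event through day 340, missing after censoring) the
kink disappears — TI + TC = t exactly — so the adherence model keeps TI only
and the group contrast is the TI-versus-baseline slope difference.

Time is internally standardized (centered/scaled) before the polynomial is
built, so predictions are invariant to affine rescaling of the day axis
(verified by refitting with days/100). An all-correct outcome has no finite
MLE; the fit raises a dedicated degenerate-outcome error and the pipeline
reports implementation ≡ 100% without fitting. Subgroup (one-covariable-at-
a-time) analyses are stratified refits — separate model per stratum, matching
paired per-stratum estimates — with continuous covariables dichotomized at
the cohort median or at an explicit cut (60 years, 60 days since PKI
initiation, 2 years since metastatic diagnosis in the default report);
an interaction-term parameterization was considered and rejected because
stratified refits also let the time trend differ by stratum. Strata with
fewer than 2 patients per arm are marked inestimable.

**Curves.** Implementation uses Wilson 95% bounds per day; persistence uses
lifelines' Kaplan–Meier with its Greenwood-type log(−log) bounds. The primary
adherence curve is the product I(t)·S(t); its displayed band is the product
of the two marginal envelopes — a conservative display device, not a joint
interval. The empirical adherence variant keeps discontinued patients in the
denominator with outcome 0 and drops censored patients after censoring; the
two variants disagree exactly when censoring exists, which is why both are
returned and the product form is primary.

## 3. The synthetic cohort: what it emulates

The generator works backwards from *marginal targets* so that every
downstream stage is testable against known truth (the truth file is emitted
alongside the data and never consumed by the pipeline).

- **Intake.** Latent per-patient daily intake is Bernoulli with
  `P(intake | b_i) = expit(c_arm(t) + b_i)`, `b_i ~ N(0, σ²)` a patient
  random intercept (default σ = 1.0) that induces the within-patient
  autocorrelation the AR(1) working correlation is meant to absorb. The
  conditional intercept `c_arm(t)` is *calibrated* each day so that the
  cohort marginal equals the target trajectory
  `logit m(t) = a + s·t + δ·TI(t)`, with `a` and `δ` solved from two anchors
  (control 95.03% and intervention 98.10% implementation at day 180 in the
  default scenario; secular slope s = −0.002/day on the log-odds scale, a
  mild decline consistent with implementation eroding over a year of
  treatment). The observed outcome marginal decomposes as
  `m(t) = f(t) + (1 − f(t))·p*(t)` where `f(t)` is the fraction of
  zero-expectation (auto-correct) patient-days, so the solver targets
  `p* = (m − f)/(1 − f)` among active days. In `realized` mode (default) the
  intercept is solved against the realized random intercepts of the patients
  at risk — marginals then match the targets exactly up to Bernoulli noise,
  at the price of a weak cross-patient dependence; `population` mode solves
  against the N(0, σ²) law by Gauss–Hermite quadrature and keeps patients
  independent (used for the interval-coverage study). A patient's monitors
  share one intake draw (drugs are taken together), so multi-monitor
  patients have the same outcome marginal as single-monitor ones.
- **Regimens.** 30% of patients are on a 21-on/7-off cyclic regimen with a
  random phase (the share of cyclic PKIs such as palbociclib in this
  population); 10% of continuous-regimen patients carry two monitors
  (combination therapy). One opening per day otherwise.
- **Transient interruptions.** All continuous-regimen patients (70% of the
  cohort) are interruption-prone; onset hazard ramps linearly to day 180 and
  stays flat, and the peak hazard is solved by a discrete renewal recursion
  so that the fraction of patient-days under interruption at day 180 equals
  8.04% — the value that separates prescribed-convention implementation
  (96.3%) from on-label implementation (88.5%) at 6 months, since an
  interrupted day is correct under the prescribed convention and incorrect
  under the on-label one. Durations are rounded log-normal (median 7 days,
  log-SD 0.6, giving a >2-day-run median of 7 and an IQR of roughly 5–10
  days). The three descriptive facts this process is asked to reproduce —
  affected-patient share, duration median, and the 6-month on-label gap —
  overconstrain any renewal process with per-patient counts as low as the
  descriptive tables suggest; the calibration privileges the duration median
  and the on-label gap, leaving the realized affected share at ≈0.51 and
  per-patient counts higher (mean ≈3 among the affected) than the
  descriptive ideal. Interruptions pause all of a patient's monitors at
  once and are kept off cyclic regimens, where a prescribed pause would
  fragment into short label-positive runs and distort the duration
  statistics.
- **Dropout.** Discontinuation-for-cause and censoring are independent
  constant-hazard processes per arm; the event hazard is parameterized by
  the target Kaplan–Meier survival at day 180 post randomization (91.5% /
  89.3%), censor hazards (0.0025 / 0.0014 per day) reproduce the heavier
  study attrition of the intervention arm. Observation (and the EM record)
  ends at the first of event, censoring, or the 360-day horizon.
- **Deviations.** Pocket-dose episodes (0.8%/day on intake days, 1–2 days
  long), curiosity openings (0.4%/monitor-day), and one nonmonitored period
  of 3–10 days for 15% of patients. All deviations are reported exactly, and
  pill counts are consistent with them, so a correct pipeline recovers the
  latent outcome exactly; rates are of the order a monthly pharmacy visit
  would plausibly collect.
- **Timestamps.** Openings fall uniformly in a 07:00–22:00 window, with 5%
  between 00:00 and 03:00 of the next calendar date to exercise the
  day-boundary rule. The within-day distribution is a placeholder — no data
  inform it — and is configurable.
- **Questionnaires.** Item responses are independent discretized normals
  around the item-level mean implied by per-scale targets (necessity 18,
  concerns 15, overprescribing 13, prejudices 12; functioning 75, symptoms
  25, global health 60 — beliefs in the upper half of the scale and a
  moderate global QoL, as in this population), identical in both arms;
  response probability 0.9 per reached wave (0, 6, 12 months).

**What the generator does not emulate**, hence what passing tests do not
show about real data: informative dropout or interruptions correlated with
intake behaviour (everything is independent given the arm); partial-day
intake (opening some but not all monitors); dose-strength changes within a
day; seasonal or weekday structure; unreported deviations (a real cohort's
pocket doses are only as complete as its interviews); measurement error in
pill counts. The calibration also means recovery tests certify the
*pipeline*, not the plausibility of the latent model.

## 4. Replication protocol and problem sizes

The replication suite (`tests/test_acceptance.py`, `scripts/acceptance.py`)
runs the full chain on the calibrated 120-patient × 360-day scenario.
Model-based quantities (three GEE fits per seed) are averaged over 20 seeds;
survival-side quantities over 60–80 seeds, because a single trial's
Kaplan–Meier value at 6 months carries ±4–5 points of noise at ~58 patients
per arm and the cheap replicates buy the averages down to a few tenths of a
point. Seeds are derived from one base seed via `numpy.random.SeedSequence`.

One structural fact is worth stating plainly: with implementation and
persistence both calibrated to their 6-month study values, the product
identity caps control-arm adherence at I·S ≈ 84.9%, about a point below the
86.0% the study-style GEE-on-zero-filled-data estimator can report on real
data; the corresponding replication assertion is expected to fail and is
kept as an honest statement of that incompatibility.

## 5. Questionnaire scoring

BMQ: every item (1 "strongly agree" … 5 "strongly disagree") is
reverse-scored (6 − raw) and subscales are sums — necessity and concerns
(5 items, range 5–25), overprescribing and prejudices (4 items, 4–20);
higher = stronger beliefs. A subscale with any missing item is missing under
the default sum-based policy (`prorate` available). QLQ-C30 is scored as its
three summary domains from the mean raw score RS of available items:
functioning `(1 − (RS−1)/3)·100`, symptoms `((RS−1)/3)·100`, global health
`((RS−1)/6)·100`. The mean-based RS tolerates missing items by construction.
Item-to-scale maps ship as an editable YAML (`emadhere/data/instruments.yaml`);
the reverse-scoring direction of individual BMQ items is instrument-defined
and should be verified against the instrument manual before scoring real
data. Group comparisons are two-sided Welch t tests with Welch–Satterthwaite
degrees of freedom; groups with fewer than two non-missing scores are marked
inestimable, and missing counts are always reported.

## 6. Numerical choices and degenerate inputs

- Intercept calibration: Brent root-finding on [−40, 40] (the mean of
  expits is monotone in the intercept); targets at 0 or 1 short-circuit to
  deterministic intake. Gauss–Hermite quadrature uses 41 nodes.
- Interruption hazard: bisection on the discrete renewal recursion with the
  duration PMF truncated at 400 days.
- GEE: maxiter 30, warm start from the independence GLM; non-finite
  coefficients raise with diagnostics. Constant outcomes raise the
  degenerate-outcome error before fitting.
- Kaplan–Meier day grid uses step interpolation of the lifelines fit;
  negative durations are a data error.
- Pill-count reconciliation: discrepancy flag at |consumed − recorded| > 2
  tablets (configurable).
- All randomness flows from a single `numpy.random.default_rng(seed)`;
  identical (config, seed) pairs produce byte-identical output files.

## 7. Known limitations

- The AR(1) `grid` approximation treats within-patient observations as
  equally spaced across masked days.
- The product-form adherence band is conservative, not a joint interval.
- The empirical adherence variant's Wilson band back-computes an effective
  numerator from the displayed proportion (exact for the point estimate,
  approximate for the band).
- Calibration in `realized` mode introduces O(1/n) cross-patient dependence;
  use `population` mode for studies of estimator sampling properties.
- The generator's questionnaire model has no latent patient factor linking
  beliefs, quality of life and intake behaviour.
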