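"""Marginal (GEE) models for daily intake outcomes.

The longitudinal binary outcome (correct intake 1/0 per patient-day) is
modelled with generalized estimating equations: logit link, a polynomial
effect of time since inclusion (default degree 3), a first-order
autoregressive working correlation within patients, and robust (sandwich)
covariance.  The intervention enters through time-dependent exposure
covariates:

* ``TI(t)`` -- days spent in the intervention arm up to day ``t`` (0 until
  the patient's randomization day, then ``t - r``);
* ``TC(t)`` -- days spent in the control arm post randomization.

Because every day after randomization is spent in exactly one arm,
``TI + TC`` equals time-since-randomization for all randomized patients;
including both terms is identifiable only because the post-randomization
clock is a kinked (not polynomial) function of study time.  On the
randomization clock (adherence model) the kink disappears, so there the
model keeps ``TI`` only, and the group contrast is the identified
``TI``-versus-``TC`` slope difference.

Effects are reported as *representative-patient* predictions: the fitted
probability at a target day (default 180) for a patient randomized to the
intervention at day 21 versus a patient who stayed in the control arm, with
the difference and its 95% CI by the delta method on the two linear
predictors (a patient-level bootstrap is available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .simulate import ARM_INTERVENTION

Z95 = 1.959963984540054


class DegenerateOutcomeError(RuntimeError):
    """Raised when the outcome is constant (no finite MLE).

    An all-ones outcome means implementation is identically 100%; report that
    directly instead of fitting.
    """


@dataclass
class GeeSpec:
    """Model specification for the intake GEE."""

    convention: str = "prescribed"
    degree: int = 3
    correlation: str = "ar1"  # 'ar1' | 'exchangeable' | 'independence'
    maxiter: int = 30

    def cov_struct(self):
        if self.correlation == "ar1":
            return sm.cov_struct.Autoregressive(grid=True)
        if self.correlation == "exchangeable":
            return sm.cov_struct.Exchangeable()
        if self.correlation == "independence":
            return sm.cov_struct.Independence()
        raise ValueError(f"unknown working correlation {self.correlation!r}")


@dataclass
class GeeFit:
    """A fitted marginal model plus the design metadata needed to predict."""

    result: object
    spec: GeeSpec
    exposure: str  # 'ti_tc' | 'ti' | 'none'
    day_center: float
    day_scale: float
    exposure_scale: float
    model_card: dict = field(default_factory=dict)

    def design_row(self, day: float, ti: float = 0.0, tc: float = 0.0) -> np.ndarray:
        u = (day - self.day_center) / self.day_scale
        cols = [1.0] + [u ** k for k in range(1, self.spec.degree + 1)]
        if self.exposure in ("ti_tc", "ti"):
            cols.append(ti / self.exposure_scale)
        if self.exposure == "ti_tc":
            cols.append(tc / self.exposure_scale)
        return np.asarray(cols)

    def predict_probability(self, day: float, ti: float = 0.0, tc: float = 0.0):
        """Fitted probability and delta-method 95% CI at one covariate point."""
        x = self.design_row(day, ti, tc)
        beta = np.asarray(self.result.params)
        V = np.asarray(self.result.cov_params())
        lp = float(x @ beta)
        se = float(np.sqrt(x @ V @ x))
        return expit(lp), expit(lp - Z95 * se), expit(lp + Z95 * se)


def build_panel(
    outcomes: pd.DataFrame, patients: pd.DataFrame, extra_covariables: bool = True
) -> pd.DataFrame:
    """Join daily outcomes with arm/randomization data and covariables.

    Never-randomized patients are kept: they contribute baseline days with
    zero exposure on both arms (they behave as control patients until lost
    to follow-up).
    """
    p = patients.copy()
    p["inclusion_date"] = pd.to_datetime(p["inclusion_date"])
    rand = pd.to_datetime(p["randomization_date"].replace("", pd.NaT), errors="coerce")
    p["randomization_day"] = (rand - p["inclusion_date"]).dt.days
    cols = ["patient_id", "arm", "randomized", "randomization_day"]
    if extra_covariables:
        for c in (
            "age",
            "gender",
            "metastasis",
            "days_since_pki_initiation",
            "years_since_metastasis",
            "prior_adherence_tool",
        ):
            if c in p.columns:
                cols.append(c)
    panel = outcomes.merge(p[cols], on="patient_id", how="left")
    return add_exposures(panel)


def add_exposures(panel: pd.DataFrame) -> pd.DataFrame:
    """Add the TI/TC time-dependent exposure columns (days)."""
    panel = panel.copy()
    r = panel["randomization_day"].fillna(np.inf)
    post = np.maximum(0.0, panel["day_index"] - r)
    post = np.where(panel["randomized"].astype(bool).fillna(False), post, 0.0)
    is_int = panel["arm"] == ARM_INTERVENTION
    panel["ti"] = np.where(is_int, post, 0.0)
    panel["tc"] = np.where(~is_int, post, 0.0)
    return panel


def _fit(panel: pd.DataFrame, spec: GeeSpec, exposure: str) -> GeeFit:
    data = panel.dropna(subset=["value"]).copy()
    if data.empty:
        raise ValueError("no non-missing outcomes to fit")
    y = data["value"].to_numpy(dtype=float)
    if np.all(y == y[0]):
        raise DegenerateOutcomeError(
            "outcome is constant "
            f"({'all correct' if y[0] == 1 else 'all incorrect'}): the marginal "
            "probability is degenerate and no finite model fit exists; report "
            "the constant directly"
        )
    n_pat = data["patient_id"].nunique()
    if n_pat < 2 or data.groupby("patient_id").size().max() < 2:
        raise ValueError("need >= 2 patients with >= 2 observed days each")

    day = data["day_index"].to_numpy(dtype=float)
    center, scale = float(day.mean()), float(day.std() or 1.0)
    u = (day - center) / scale
    cols = [np.ones_like(u)] + [u ** k for k in range(1, spec.degree + 1)]
    names = ["const"] + [f"t^{k}" for k in range(1, spec.degree + 1)]
    exp_scale = 1.0
    if exposure in ("ti_tc", "ti"):
        both = np.concatenate([data["ti"].to_numpy(), data["tc"].to_numpy()])
        exp_scale = float(both.std() or 1.0)
        cols.append(data["ti"].to_numpy(dtype=float) / exp_scale)
        names.append("ti")
    if exposure == "ti_tc":
        cols.append(data["tc"].to_numpy(dtype=float) / exp_scale)
        names.append("tc")
    X = np.column_stack(cols)

    # warm start from an independence GLM, then the GEE proper
    glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    cov = spec.cov_struct()
    model = sm.GEE(
        y,
        X,
        groups=data["patient_id"].to_numpy(),
        time=day[:, None],
        family=sm.families.Binomial(),
        cov_struct=cov,
    )
    result = model.fit(maxiter=spec.maxiter, start_params=glm.params)
    if not np.all(np.isfinite(result.params)):
        raise RuntimeError(
            "GEE did not converge to finite coefficients; "
            f"params={result.params}"
        )
    card = {
        "n_patients": int(n_pat),
        "n_patient_days": int(len(data)),
        "degree": spec.degree,
        "correlation": spec.correlation,
        "dep_params": _dep_params(cov),
        "exposure": exposure,
        "convention": spec.convention,
        "coef": {n: float(b) for n, b in zip(names, result.params)},
    }
    return GeeFit(
        result=result,
        spec=spec,
        exposure=exposure,
        day_center=center,
        day_scale=scale,
        exposure_scale=exp_scale,
        model_card=card,
    )


def _dep_params(cov) -> float | None:
    try:
        return float(np.atleast_1d(cov.dep_params)[0])
    except Exception:
        return None


def fit_implementation_gee(panel: pd.DataFrame, spec: GeeSpec | None = None) -> GeeFit:
    """Implementation model on the inclusion clock with TI and TC exposures."""
    return _fit(panel, spec or GeeSpec(), exposure="ti_tc")


def fit_population_gee(panel: pd.DataFrame, spec: GeeSpec | None = None) -> GeeFit:
    """Whole-sample model: polynomial time trend only, no group terms.

    Used for the prescribed-versus-on-label comparison, where the quantity of
    interest is the implementation of the entire sample under each convention.
    """
    return _fit(panel, spec or GeeSpec(), exposure="none")


@dataclass
class RepresentativePrediction:
    day: int
    p_intervention: float
    p_control: float
    delta: float
    lo: float
    hi: float
    se: float

    def as_dict(self) -> dict:
        return {
            "day": self.day,
            "p_intervention": self.p_intervention,
            "p_control": self.p_control,
            "delta": self.delta,
            "lo": self.lo,
            "hi": self.hi,
        }


def predict_representative(
    fit: GeeFit, day: int = 180, randomization_day: int = 21
) -> RepresentativePrediction:
    """Representative-patient predictions at ``day`` and their difference.

    The intervention patient is randomized to the intervention at
    ``randomization_day`` (exposure ``TI = day - r``); the control patient
    spends the same post-randomization time in the control arm.  The 95% CI
    of the difference is the delta method on the two linear predictors with
    the robust covariance.
    """
    if fit.exposure == "none":
        raise ValueError("whole-sample fit has no group contrast; use predict_probability")
    post = max(0.0, day - randomization_day)
    if fit.exposure == "ti_tc":
        x_i = fit.design_row(day, ti=post, tc=0.0)
        x_c = fit.design_row(day, ti=0.0, tc=post)
    else:  # randomization clock: TI only, control is the baseline trajectory
        x_i = fit.design_row(day, ti=day)
        x_c = fit.design_row(day, ti=0.0)
    beta = np.asarray(fit.result.params)
    V = np.asarray(fit.result.cov_params())
    p_i = float(expit(x_i @ beta))
    p_c = float(expit(x_c @ beta))
    grad = p_i * (1 - p_i) * x_i - p_c * (1 - p_c) * x_c
    se = float(np.sqrt(grad @ V @ grad))
    delta = p_i - p_c
    return RepresentativePrediction(
        day=day,
        p_intervention=p_i,
        p_control=p_c,
        delta=delta,
        lo=delta - Z95 * se,
        hi=delta + Z95 * se,
        se=se,
    )


def bootstrap_representative(
    panel: pd.DataFrame,
    spec: GeeSpec,
    day: int = 180,
    randomization_day: int = 21,
    n_boot: int = 500,
    seed: int = 0,
    exposure: str = "ti_tc",
) -> dict:
    """Patient-level bootstrap CI for the representative difference."""
    rng = np.random.default_rng(seed)
    ids = panel["patient_id"].unique()
    groups = {pid: df for pid, df in panel.groupby("patient_id")}
    deltas = []
    for _ in range(n_boot):
        sample = rng.choice(ids, size=len(ids), replace=True)
        parts = []
        for j, pid in enumerate(sample):
            df = groups[pid].copy()
            df["patient_id"] = f"bs{j}"
            parts.append(df)
        bs = pd.concat(parts, ignore_index=True)
        try:
            fit = _fit(bs, spec, exposure=exposure)
        except (DegenerateOutcomeError, RuntimeError, ValueError):
            continue
        deltas.append(predict_representative(fit, day, randomization_day).delta)
    deltas = np.asarray(deltas)
    return {
        "n_effective": int(deltas.size),
        "delta_mean": float(deltas.mean()) if deltas.size else np.nan,
        "lo": float(np.percentile(deltas, 2.5)) if deltas.size else np.nan,
        "hi": float(np.percentile(deltas, 97.5)) if deltas.size else np.nan,
    }


def subgroup_analysis(
    panel: pd.DataFrame,
    covariable: str,
    spec: GeeSpec | None = None,
    day: int = 180,
    randomization_day: int = 21,
    cut: float | None = None,
) -> pd.DataFrame:
    """One-at-a-time covariable analysis by stratified refits.

    Continuous covariables are dichotomized at the cohort median (or at an
    explicit ``cut``); each stratum gets its own model fit and
    representative-patient prediction pair.  Strata with fewer than 2
    patients per arm are marked inestimable (NaN row).
    """
    spec = spec or GeeSpec()
    if covariable not in panel.columns:
        raise KeyError(f"covariable {covariable!r} not in panel")
    values = panel[[covariable, "patient_id"]].drop_duplicates("patient_id")[covariable]
    numeric = pd.api.types.is_numeric_dtype(values) and values.nunique() > 2
    work = panel.copy()
    if numeric:
        if cut is None:
            cut = float(values.median())
        lab_lo, lab_hi = f"{covariable} <= {cut:g}", f"{covariable} > {cut:g}"
        work["_stratum"] = np.where(work[covariable] <= cut, lab_lo, lab_hi)
        order = [lab_lo, lab_hi]
    else:
        work["_stratum"] = work[covariable].astype(str).map(
            lambda v: f"{covariable} = {v}"
        )
        order = sorted(work["_stratum"].unique())

    rows = []
    for stratum in order:
        sub = work[work["_stratum"] == stratum]
        pat = sub[["patient_id", "arm"]].drop_duplicates()
        n_pat = len(pat)
        arm_counts = pat["arm"].value_counts()
        estimable = n_pat >= 2 and (arm_counts >= 2).sum() == len(arm_counts) >= 2
        if not estimable:
            rows.append((stratum, n_pat, np.nan, np.nan, np.nan, np.nan, np.nan))
            continue
        try:
            fit = _fit(sub, spec, exposure="ti_tc")
            pred = predict_representative(fit, day, randomization_day)
            rows.append(
                (stratum, n_pat, pred.p_intervention, pred.p_control,
                 pred.delta, pred.lo, pred.hi)
            )
        except (DegenerateOutcomeError, RuntimeError, ValueError):
            rows.append((stratum, n_pat, np.nan, np.nan, np.nan, np.nan, np.nan))
    return pd.DataFrame(
        rows,
        columns=["stratum", "n_patients", "p_intervention", "p_control",
                 "delta", "lo", "hi"],
    )


def build_adherence_panel(
    outcomes: pd.DataFrame,
    patients: pd.DataFrame,
    window_days: int = 340,
) -> pd.DataFrame:
    """Panel for the adherence model on the randomization clock.

    Baseline days are excluded; after a discontinuation event the outcome is
    0 through the end of the window (a discontinued patient takes nothing);
    after a censoring time the outcome is missing.
    """
    from .estimators import persistence_records, to_randomization_clock

    oc = to_randomization_clock(outcomes, patients, window_days)
    rec = persistence_records(patients, clock="randomization")
    extra = []
    for r in rec.itertuples(index=False):
        if r.event and r.time_days < window_days:
            days = np.arange(r.time_days + 1, window_days + 1)
            extra.append(
                pd.DataFrame(
                    {"patient_id": r.patient_id, "day_index": days, "value": 0.0}
                )
            )
    if extra:
        oc = pd.concat([oc] + extra, ignore_index=True)
    p = patients[["patient_id", "arm", "randomized"]].copy()
    panel = oc.merge(p, on="patient_id", how="left")
    panel["randomization_day"] = 0  # clock already starts at randomization
    return add_exposures(panel)


def fit_adherence_gee(
    adherence_panel: pd.DataFrame, spec: GeeSpec | None = None
) -> GeeFit:
    """Adherence model: TI-only exposure on the randomization clock."""
    return _fit(adherence_panel, spec or GeeSpec(), exposure="ti")
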