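"""Outcome curves: daily intake, implementation, persistence, adherence.

Definitions
-----------
daily intake outcome
    Binary per patient-day: 1 when, for *every* monitor of the patient that
    day, observed openings plus pocket-dose credits reach the expected
    openings under the chosen convention (prescribed or on-label); 0
    otherwise; missing on nonmonitored days.  Days with a zero expectation
    (prescribed interruptions, scheduled cycle-off weeks) are therefore
    correct by definition.

implementation I(t)
    Daily proportion of correct outcomes among patients still observed with
    a non-missing outcome on day t.

persistence S(t)
    Kaplan-Meier probability of remaining on treatment: the event is
    premature discontinuation for adverse events or patient
    personal/unilateral reasons; every other exit (progression, asymptomatic
    toxicity, study exit) is censoring.

adherence A(t)
    Proportion with correct intake among all patients initially included;
    estimated primarily as the product I(t) * S(t), with an empirical
    variant that keeps discontinued patients in the denominator with
    outcome 0 and drops censored patients after their censoring day.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from statsmodels.stats.proportion import proportion_confint

CONVENTIONS = ("prescribed", "onlabel")
EVENT_REASONS = ("adverse_event", "personal")


def daily_outcome(table: pd.DataFrame, convention: str = "prescribed") -> pd.DataFrame:
    """Collapse the adherence table to one binary outcome per patient-day.

    Returns columns ``patient_id, day_index, value`` where ``value`` is 1.0,
    0.0 or NaN (missing: some monitor unmonitored that day).
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}")
    col = "expected_prescribed" if convention == "prescribed" else "expected_onlabel"
    t = table.copy()
    t["_ok"] = (t["observed_openings"] + t["pocket_dose_credit"]) >= t[col]
    g = t.groupby(["patient_id", "day_index"], sort=True)
    out = g.agg(all_ok=("_ok", "all"), monitored=("monitored", "all")).reset_index()
    out["value"] = np.where(out["monitored"], out["all_ok"].astype(float), np.nan)
    return out[["patient_id", "day_index", "value"]]


def empirical_implementation(
    outcomes: pd.DataFrame, max_day: int | None = None
) -> pd.DataFrame:
    """Daily proportion of correct intake among observed, non-missing outcomes.

    Returns ``day, estimate, lo, hi, n`` with Wilson 95% bounds; days with an
    empty denominator get NaN estimates (undefined, not an error).
    """
    obs = outcomes.dropna(subset=["value"])
    if max_day is None:
        max_day = int(outcomes["day_index"].max()) if len(outcomes) else -1
    grid = np.arange(max_day + 1)
    g = obs.groupby("day_index")["value"]
    n = g.size().reindex(grid, fill_value=0)
    k = g.sum().reindex(grid, fill_value=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        est = np.where(n > 0, k / n, np.nan)
    lo, hi = proportion_confint(k.to_numpy(), np.maximum(n.to_numpy(), 1), method="wilson")
    lo = np.where(n > 0, lo, np.nan)
    hi = np.where(n > 0, hi, np.nan)
    return pd.DataFrame(
        {"day": grid, "estimate": est, "lo": lo, "hi": hi, "n": n.to_numpy()}
    )


def persistence_records(
    patients: pd.DataFrame, clock: str = "randomization"
) -> pd.DataFrame:
    """Time-to-discontinuation records from the patient roster.

    The event is premature treatment cessation for adverse events or patient
    personal/unilateral reasons; all other exit reasons are censoring.  With
    ``clock="randomization"`` only randomized patients contribute, with time
    measured from their randomization date; ``clock="inclusion"`` measures
    from inclusion for everybody.
    """
    if clock not in ("randomization", "inclusion"):
        raise ValueError("clock must be 'randomization' or 'inclusion'")
    p = patients.copy()
    p["inclusion_date"] = pd.to_datetime(p["inclusion_date"])
    p["end_date"] = pd.to_datetime(p["end_date"])
    if clock == "randomization":
        p = p[p["randomized"].astype(bool)].copy()
        origin = pd.to_datetime(p["randomization_date"])
    else:
        origin = p["inclusion_date"]
    time = (p["end_date"] - origin).dt.days
    if (time < 0).any():
        raise ValueError("negative persistence times (end before clock origin)")
    return pd.DataFrame(
        {
            "patient_id": p["patient_id"].to_numpy(),
            "time_days": time.to_numpy(),
            "event": p["exit_reason"].isin(EVENT_REASONS).to_numpy(),
            "reason": p["exit_reason"].to_numpy(),
            "arm": p["arm"].to_numpy() if "arm" in p.columns else "",
        }
    )


def km_persistence(
    records: pd.DataFrame, max_day: int | None = None
) -> pd.DataFrame:
    """Product-limit persistence curve with Greenwood-type 95% bounds.

    Returns ``day, estimate, lo, hi, n_at_risk`` on an integer day grid; the
    curve starts at 1 and is monotone non-increasing.
    """
    if (records["time_days"] < 0).any():
        raise ValueError("negative times in persistence records")
    if max_day is None:
        max_day = int(records["time_days"].max()) if len(records) else 0
    grid = np.arange(max_day + 1)
    kmf = KaplanMeierFitter()
    kmf.fit(records["time_days"], event_observed=records["event"].astype(bool))
    est = kmf.survival_function_at_times(grid).to_numpy()
    ci = kmf.confidence_interval_survival_function_
    lo = _step_at(ci.iloc[:, 0], grid)
    hi = _step_at(ci.iloc[:, 1], grid)
    times = records["time_days"].to_numpy()
    n_at_risk = np.array([(times >= d).sum() for d in grid])
    return pd.DataFrame(
        {"day": grid, "estimate": est, "lo": lo, "hi": hi, "n_at_risk": n_at_risk}
    )


def _step_at(series: pd.Series, grid: np.ndarray) -> np.ndarray:
    s = series.sort_index()
    idx = np.searchsorted(s.index.to_numpy(), grid, side="right") - 1
    idx = np.clip(idx, 0, len(s) - 1)
    return s.to_numpy()[idx]


def to_randomization_clock(
    outcomes: pd.DataFrame, patients: pd.DataFrame, window_days: int = 340
) -> pd.DataFrame:
    """Re-index daily outcomes to days since randomization.

    Baseline (pre-randomization) days are excluded, as are never-randomized
    patients; the clock is truncated at ``window_days``.
    """
    p = patients.copy()
    p["inclusion_date"] = pd.to_datetime(p["inclusion_date"])
    rand = pd.to_datetime(p["randomization_date"].replace("", pd.NaT), errors="coerce")
    p["randomization_day"] = (rand - p["inclusion_date"]).dt.days
    keep = p[p["randomized"].astype(bool)][["patient_id", "randomization_day"]]
    out = outcomes.merge(keep, on="patient_id", how="inner")
    out["day_index"] = out["day_index"] - out["randomization_day"]
    out = out[(out["day_index"] >= 0) & (out["day_index"] <= window_days)]
    return out.drop(columns=["randomization_day"]).reset_index(drop=True)


def empirical_adherence(
    outcomes: pd.DataFrame,
    records: pd.DataFrame,
    window_days: int = 340,
) -> dict[str, pd.DataFrame]:
    """Adherence curves on the randomization clock.

    ``outcomes`` must already be on the randomization clock (see
    :func:`to_randomization_clock`) and ``records`` measured from
    randomization for the same cohort.  Returns two curves:

    * ``"product"`` (primary): A(t) = I(t) * S(t).  The interval is the
      product of the two marginal 95% envelopes -- a conservative display
      band, not a joint interval.
    * ``"empirical"``: discontinued patients stay in the denominator with
      outcome 0 from their event day onward; censored patients leave the
      denominator after their censoring day.
    """
    missing = set(records["patient_id"]) - set(outcomes["patient_id"])
    extra = set(outcomes["patient_id"]) - set(records["patient_id"])
    if extra:
        raise ValueError(
            f"outcomes contain patients without persistence records: {sorted(extra)[:5]}"
        )
    impl = empirical_implementation(outcomes, max_day=window_days)
    km = km_persistence(records, max_day=window_days)
    product = pd.DataFrame(
        {
            "day": impl["day"],
            "estimate": impl["estimate"] * km["estimate"],
            "lo": impl["lo"] * km["lo"],
            "hi": impl["hi"] * km["hi"],
            "n": impl["n"],
        }
    )

    rec = records.set_index("patient_id")
    obs = outcomes.dropna(subset=["value"])
    by_day_num = obs[obs["value"] == 1.0].groupby("day_index").size()
    by_day_obs = obs.groupby("day_index").size()
    times = rec["time_days"]
    events = rec["event"].astype(bool)
    grid = np.arange(window_days + 1)
    est = np.full(len(grid), np.nan)
    n_out = np.zeros(len(grid), dtype=int)
    for d in grid:
        n_obs = int(by_day_obs.get(d, 0))
        k = int(by_day_num.get(d, 0))
        n_disc = int(((times < d) & events).sum())
        denom = n_obs + n_disc
        n_out[d] = denom
        if denom > 0:
            est[d] = k / denom
    lo, hi = proportion_confint(
        np.round(est * np.maximum(n_out, 1)).astype(int),
        np.maximum(n_out, 1),
        method="wilson",
    )
    empirical = pd.DataFrame(
        {
            "day": grid,
            "estimate": est,
            "lo": np.where(n_out > 0, lo, np.nan),
            "hi": np.where(n_out > 0, hi, np.nan),
            "n": n_out,
        }
    )
    return {"product": product, "empirical": empirical}


def curve_at(curve: pd.DataFrame, day: int) -> float:
    """Point estimate of a curve frame at an exact day."""
    row = curve[curve["day"] == day]
    if row.empty:
        raise KeyError(f"day {day} outside the curve grid")
    return float(row["estimate"].iloc[0])
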