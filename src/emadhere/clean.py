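"""Cleaning and enrichment of raw EM event logs into the adherence table.

The adherence table is the pipeline's central artifact: one row per
(patient, monitor, dosing day) carrying observed openings, pocket-dose
credits, the expected openings under the prescribed and on-label conventions,
a monitored flag, and patient covariables.  The stages mirror standard EM
dosing-history practice:

1. events are assigned to *dosing days* (03:00 to 02:59 local time) and
   truncated to each monitor's actual period of use;
2. daily openings are counted per monitor;
3. reported curiosity openings (openings without intake) are subtracted,
   floor zero;
4. reported pocket doses -- doses removed in advance and taken on a day with
   no recorded opening -- are credited back onto deficit days, earliest
   first, but only up to the surplus that the pharmacy pill count confirms;
5. reported nonmonitored periods (e.g. hospitalizations) are masked: the
   daily outcome is missing there.

The pipeline is deterministic and purely additive on flags: nothing is
silently dropped, and a QC report collects every correction it made.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schedule import build_schedule, monitor_windows


class CleaningError(ValueError):
    pass


DAY_BOUNDARY_HOUR = 3


def assign_dosing_day(
    timestamps: pd.Series,
    tz_offset_minutes: int | None = None,
    boundary_hour: int = DAY_BOUNDARY_HOUR,
) -> pd.Series:
    """Dosing date for each timestamp under the 03:00 day-boundary rule.

    Timestamps are ISO-8601 strings with a UTC offset.  They are converted to
    local civil (wall) time first -- with ``tz_offset_minutes`` when given,
    else each stamp's own offset -- so an opening at 01:30 on date D counts
    for dosing day D-1.  The early-morning boundary also makes daylight
    saving transitions (02:00-03:00) safe by construction.
    """
    ts = pd.to_datetime(timestamps, utc=True, format="ISO8601")
    if tz_offset_minutes is not None:
        from datetime import timedelta, timezone

        wall = ts.dt.tz_convert(timezone(timedelta(minutes=tz_offset_minutes)))
        wall = wall.dt.tz_localize(None)
    else:
        # keep each stamp's own wall time
        raw = pd.to_datetime(timestamps, format="ISO8601")
        wall = pd.to_datetime(raw.astype(str).str.slice(0, 19))
    return (wall - pd.Timedelta(hours=boundary_hour)).dt.normalize()


def truncate(
    events: pd.DataFrame, windows: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split events into (retained, flagged) by each monitor's window of use.

    ``events`` must carry a ``dosing_date`` column; ``windows`` has one row
    per monitor with ``start``/``end`` dates (inclusive).  Events from a
    monitor without any window raise an error; events outside the window are
    returned in the flagged frame for the QC report, never silently dropped.
    """
    merged = events.merge(windows, on=["patient_id", "em_id"], how="left")
    unknown = merged["start"].isna()
    if unknown.any():
        ems = sorted(merged.loc[unknown, "em_id"].unique())
        raise CleaningError(f"events recorded for monitors without a use window: {ems}")
    inside = (merged["dosing_date"] >= merged["start"]) & (
        merged["dosing_date"] <= merged["end"]
    )
    cols = list(events.columns)
    return merged.loc[inside, cols].copy(), merged.loc[~inside, cols].copy()


def count_daily_openings(events: pd.DataFrame) -> pd.DataFrame:
    """Observed openings per (patient, monitor, dosing day)."""
    if events.empty:
        return pd.DataFrame(
            columns=["patient_id", "em_id", "date", "observed_openings"]
        )
    out = (
        events.groupby(["patient_id", "em_id", "dosing_date"], sort=True)
        .size()
        .rename("observed_openings")
        .reset_index()
        .rename(columns={"dosing_date": "date"})
    )
    return out


def reconcile_pill_count(
    dispensed: float,
    returned: float,
    expected_pills: float,
    openings_plus_credits: float,
    tablets_per_opening: int = 1,
    tolerance: float = 2.0,
) -> tuple[float, bool]:
    """Aggregated intake percentage for a refill period plus a discrepancy flag.

    percentage = (dispensed - returned) / expected_pills * 100 (NaN when no
    pills were expected); the flag is set when consumption disagrees with the
    opening record (openings + pocket credits, times tablets per opening) by
    more than ``tolerance`` tablets.
    """
    if returned > dispensed:
        raise CleaningError(
            f"returned pills ({returned}) exceed dispensed pills ({dispensed})"
        )
    if returned < 0:
        raise CleaningError("returned pills must be non-negative")
    consumed = dispensed - returned
    pct = np.nan if expected_pills <= 0 else consumed / expected_pills * 100.0
    flag = abs(consumed - openings_plus_credits * tablets_per_opening) > tolerance
    return pct, bool(flag)


@dataclass
class CleanResult:
    table: pd.DataFrame
    qc: dict
    flagged_events: pd.DataFrame = field(default_factory=pd.DataFrame)


def _expand_report_days(reports: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for r in reports.itertuples(index=False):
        for d in pd.date_range(r.start_date, r.end_date):
            rows.append((r.patient_id, r.em_id, d, r.count))
    return pd.DataFrame(rows, columns=["patient_id", "em_id", "date", "count"])


def apply_pocket_doses(
    grid: pd.DataFrame,
    pocket_reports: pd.DataFrame,
    pill_counts: pd.DataFrame | None,
) -> tuple[pd.DataFrame, dict]:
    """Insert pocket-dose credits onto deficit days, pill-count permitting.

    For each report (monitor, window, count): candidate days are the window's
    days with ``observed_openings + credit < expected_prescribed``; credits
    are assigned chronologically, one per day, up to the reported count and
    up to the surplus the covering pill-count periods confirm (pills that
    left the bottle beyond recorded openings).  A report with no covering
    pill count, or no confirmed surplus, yields no credit and a warning.
    """
    grid = grid.copy()
    grid["pocket_dose_credit"] = 0
    info = {"pocket_reports": int(len(pocket_reports)), "pocket_credits": 0,
            "pocket_unconfirmed_reports": 0}
    if pocket_reports.empty:
        return grid, info

    pc_groups: dict = {}
    if pill_counts is not None and len(pill_counts):
        pc = pill_counts.copy()
        pc["period_start"] = pd.to_datetime(pc["period_start"]).dt.normalize()
        pc["period_end"] = pd.to_datetime(pc["period_end"]).dt.normalize()
        pc_groups = {em: sub for em, sub in pc.groupby("em_id")}

    em_index: dict = {em: idx for em, idx in grid.groupby("em_id").indices.items()}
    observed = grid["observed_openings"].to_numpy().copy()
    expected = grid["expected_prescribed"].to_numpy()
    credit = np.zeros(len(grid), dtype=int)
    dates = grid["date"].to_numpy()

    reports = pocket_reports.sort_values(
        ["patient_id", "em_id", "start_date"], kind="mergesort"
    )
    for r in reports.itertuples(index=False):
        start = np.datetime64(pd.to_datetime(r.start_date))
        end = np.datetime64(pd.to_datetime(r.end_date))
        periods = pc_groups.get(r.em_id)
        if periods is not None:
            periods = periods[
                (periods["period_start"] <= end) & (periods["period_end"] >= start)
            ]
        if periods is None or periods.empty:
            info["pocket_unconfirmed_reports"] += 1
            continue
        idx = em_index[r.em_id]  # positions of this monitor's rows (date-sorted)
        d_em = dates[idx]
        tpo = int(periods["tablets_per_opening"].iloc[0])
        period_mask = np.zeros(len(idx), dtype=bool)
        for p in periods.itertuples(index=False):
            period_mask |= (d_em >= np.datetime64(p.period_start)) & (
                d_em <= np.datetime64(p.period_end)
            )
        consumed = float((periods["dispensed"] - periods["returned"]).sum())
        recorded = float((observed[idx] + credit[idx])[period_mask].sum()) * tpo
        surplus = consumed - recorded
        max_credit = min(int(r.count), int(surplus // tpo) if surplus > 0 else 0)
        if max_credit <= 0:
            info["pocket_unconfirmed_reports"] += 1
            continue
        given = 0
        window = idx[(d_em >= start) & (d_em <= end)]
        for i in window:  # chronological: earliest deficit first
            if given >= max_credit:
                break
            if observed[i] + credit[i] < expected[i]:
                credit[i] += 1
                given += 1
        info["pocket_credits"] += given

    grid["pocket_dose_credit"] = credit
    return grid, info


def mask_nonmonitored(
    grid: pd.DataFrame, nonmonitored_reports: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Set ``monitored=False`` on reported nonmonitored periods.

    Masking only changes the flag: counts on other days are untouched.  Days
    of a reported period falling outside the monitor's window are counted in
    the returned warning info.
    """
    grid = grid.copy()
    if "monitored" not in grid.columns:
        grid["monitored"] = True
    info = {"nonmonitored_reports": int(len(nonmonitored_reports)),
            "masked_days": 0, "nonmonitored_days_outside_window": 0}
    if nonmonitored_reports.empty:
        return grid, info
    key = pd.MultiIndex.from_frame(grid[["em_id", "date"]])
    idx_lookup = {k: i for i, k in enumerate(key)}
    monitored = grid["monitored"].to_numpy().copy()
    for r in nonmonitored_reports.itertuples(index=False):
        for d in pd.date_range(r.start_date, r.end_date):
            i = idx_lookup.get((r.em_id, d))
            if i is None:
                info["nonmonitored_days_outside_window"] += 1
            elif monitored[i]:
                monitored[i] = False
                info["masked_days"] += 1
    grid["monitored"] = monitored
    return grid, info


def clean_cohort(
    events: pd.DataFrame,
    prescriptions: pd.DataFrame,
    reports: pd.DataFrame | None = None,
    pill_counts: pd.DataFrame | None = None,
    patients: pd.DataFrame | None = None,
    curiosity_policy: str = "subtract",
    pill_tolerance: float = 2.0,
    tz_offset_minutes: int | None = None,
) -> CleanResult:
    """Run the full cleaning pipeline and return the adherence table + QC.

    ``curiosity_policy`` is ``"subtract"`` (reported curiosity openings are
    removed from the day's count, floor 0) or ``"ignore"``.
    """
    if curiosity_policy not in ("subtract", "ignore"):
        raise CleaningError("curiosity_policy must be 'subtract' or 'ignore'")
    reports = reports if reports is not None else pd.DataFrame(
        columns=["patient_id", "em_id", "report_type", "start_date", "end_date", "count"]
    )
    schedule = build_schedule(prescriptions)
    windows = monitor_windows(schedule)

    ev = events.copy()
    if len(ev):
        ev["dosing_date"] = assign_dosing_day(ev["timestamp"], tz_offset_minutes)
        retained, flagged = truncate(ev, windows)
    else:
        retained = ev.assign(dosing_date=pd.NaT)
        flagged = retained.iloc[0:0]
    counts = count_daily_openings(retained)

    grid = schedule.merge(counts, on=["patient_id", "em_id", "date"], how="left")
    grid["observed_openings"] = (
        pd.to_numeric(grid["observed_openings"], errors="coerce").fillna(0).astype(int)
    )
    grid["raw_openings"] = grid["observed_openings"]

    rep = reports.copy()
    if len(rep):
        rep["start_date"] = pd.to_datetime(rep["start_date"]).dt.normalize()
        rep["end_date"] = pd.to_datetime(rep["end_date"]).dt.normalize()

    qc: dict = {
        "n_events": int(len(events)),
        "n_events_retained": int(len(retained)),
        "n_events_flagged_out_of_window": int(len(flagged)),
        "curiosity_policy": curiosity_policy,
    }

    # curiosity openings: EM openings without intake, reported by the patient
    cur = rep[rep["report_type"] == "curiosity"] if len(rep) else rep
    removed = 0
    if curiosity_policy == "subtract" and len(cur):
        days = _expand_report_days(cur)
        agg = days.groupby(["patient_id", "em_id", "date"], as_index=False)["count"].sum()
        grid = grid.merge(agg, on=["patient_id", "em_id", "date"], how="left")
        sub = np.minimum(
            grid["count"].fillna(0).astype(int), grid["observed_openings"]
        )
        removed = int(sub.sum())
        grid["observed_openings"] = grid["observed_openings"] - sub
        grid = grid.drop(columns=["count"])
    qc["curiosity_openings_removed"] = removed

    pocket = rep[rep["report_type"] == "pocket_dose"] if len(rep) else rep
    grid, pocket_info = apply_pocket_doses(grid, pocket, pill_counts)
    qc.update(pocket_info)

    nonmon = rep[rep["report_type"] == "nonmonitored"] if len(rep) else rep
    grid, mask_info = mask_nonmonitored(grid, nonmon)
    qc.update(mask_info)

    # pill-count reconciliation (aggregated percentage + discrepancy flags)
    discrepancies = 0
    if pill_counts is not None and len(pill_counts):
        pcs = pill_counts.copy()
        pcs["period_start"] = pd.to_datetime(pcs["period_start"]).dt.normalize()
        pcs["period_end"] = pd.to_datetime(pcs["period_end"]).dt.normalize()
        em_index = {em: idx for em, idx in grid.groupby("em_id").indices.items()}
        g_dates = grid["date"].to_numpy()
        g_exp = grid["expected_prescribed"].to_numpy()
        g_open = (grid["observed_openings"] + grid["pocket_dose_credit"]).to_numpy()
        for p in pcs.itertuples(index=False):
            idx = em_index.get(p.em_id, np.array([], dtype=int))
            in_period = (g_dates[idx] >= np.datetime64(p.period_start)) & (
                g_dates[idx] <= np.datetime64(p.period_end)
            )
            sel = idx[in_period]
            _, flag = reconcile_pill_count(
                p.dispensed,
                p.returned,
                expected_pills=float(g_exp[sel].sum()) * p.tablets_per_opening,
                openings_plus_credits=float(g_open[sel].sum()),
                tablets_per_opening=p.tablets_per_opening,
                tolerance=pill_tolerance,
            )
            discrepancies += int(flag)
    qc["pill_count_discrepancies"] = discrepancies

    # enrichment: day index since inclusion + patient covariables
    if patients is not None:
        pat = patients.copy()
        pat["inclusion_date"] = pd.to_datetime(pat["inclusion_date"]).dt.normalize()
        rand = pd.to_datetime(
            pat["randomization_date"].replace("", pd.NaT), errors="coerce"
        )
        pat["randomization_day"] = (rand - pat["inclusion_date"]).dt.days
        keep = [
            "patient_id",
            "inclusion_date",
            "arm",
            "randomized",
            "randomization_day",
            "age",
            "gender",
            "metastasis",
            "days_since_pki_initiation",
            "years_since_metastasis",
            "prior_adherence_tool",
        ]
        keep = [c for c in keep if c in pat.columns or c == "randomization_day"]
        grid = grid.merge(pat[keep], on="patient_id", how="left")
        grid["day_index"] = (grid["date"] - grid["inclusion_date"]).dt.days
        grid = grid.drop(columns=["inclusion_date"])
    else:
        first = grid.groupby("patient_id")["date"].transform("min")
        grid["day_index"] = (grid["date"] - first).dt.days

    order = ["patient_id", "em_id", "date", "day_index", "observed_openings",
             "raw_openings", "pocket_dose_credit", "expected_prescribed",
             "expected_onlabel", "segment_type", "monitored"]
    rest = [c for c in grid.columns if c not in order]
    grid = grid[order + rest].sort_values(
        ["patient_id", "em_id", "date"], kind="mergesort"
    ).reset_index(drop=True)
    return CleanResult(table=grid, qc=qc, flagged_events=flagged)
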