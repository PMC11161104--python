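"""Naive day-by-day reference implementation of the cleaning pipeline.

Pure-python loops over monitors and calendar days, used only as an
independent oracle for small instances.  Deliberately unvectorized and
structured differently from the production pipeline.
"""

from __future__ import annotations

from datetime import date, datetime, timedelta

import pandas as pd


def _to_date(s) -> date:
    return datetime.fromisoformat(str(s)[:10]).date()


def _dosing_day(stamp: str) -> date:
    # wall-clock time (ignore the offset suffix), minus 3 hours, date part
    wall = datetime.fromisoformat(stamp[:19])
    return (wall - timedelta(hours=3)).date()


def reference_table(
    events: pd.DataFrame,
    prescriptions: pd.DataFrame,
    reports: pd.DataFrame,
    pill_counts: pd.DataFrame,
    curiosity_policy: str = "subtract",
) -> pd.DataFrame:
    """Reference adherence table: one row per (patient, monitor, day)."""
    # 1. expand the schedule monitor by monitor, day by day
    sched: dict[tuple, dict] = {}
    for _, seg in prescriptions.iterrows():
        d = _to_date(seg["start_date"])
        stop = _to_date(seg["end_date"])
        while d <= stop:
            sched[(seg["patient_id"], seg["em_id"], d)] = {
                "expected_prescribed": int(seg["expected_openings_per_day"]),
                "expected_onlabel": int(seg["label_openings_per_day"]),
                "observed": 0,
                "credit": 0,
                "monitored": True,
            }
            d += timedelta(days=1)

    windows: dict[tuple, tuple] = {}
    for (pid, em, d) in sched:
        lo, hi = windows.get((pid, em), (d, d))
        windows[(pid, em)] = (min(lo, d), max(hi, d))

    # 2. count openings per dosing day, inside the window only
    for _, ev in events.iterrows():
        day = _dosing_day(ev["timestamp"])
        key = (ev["patient_id"], ev["em_id"], day)
        if key in sched:
            sched[key]["observed"] += 1

    # 3. subtract reported curiosity openings
    if curiosity_policy == "subtract":
        for _, r in reports.iterrows():
            if r["report_type"] != "curiosity":
                continue
            d = _to_date(r["start_date"])
            stop = _to_date(r["end_date"])
            while d <= stop:
                key = (r["patient_id"], r["em_id"], d)
                if key in sched:
                    take = min(int(r["count"]), sched[key]["observed"])
                    sched[key]["observed"] -= take
                d += timedelta(days=1)

    # 4. pocket credits, pill-count confirmed, earliest deficit first
    pocket = reports[reports["report_type"] == "pocket_dose"]
    pocket = pocket.sort_values(["patient_id", "em_id", "start_date"])
    for _, r in pocket.iterrows():
        start, stop = _to_date(r["start_date"]), _to_date(r["end_date"])
        periods = []
        for _, p in pill_counts.iterrows():
            if p["em_id"] != r["em_id"]:
                continue
            ps, pe = _to_date(p["period_start"]), _to_date(p["period_end"])
            if ps <= stop and pe >= start:
                periods.append((ps, pe, p))
        if not periods:
            continue
        tpo = int(periods[0][2]["tablets_per_opening"])
        consumed = sum(p["dispensed"] - p["returned"] for _, _, p in periods)
        recorded = 0
        for ps, pe, _ in periods:
            d = ps
            while d <= pe:
                key = (r["patient_id"], r["em_id"], d)
                if key in sched:
                    recorded += sched[key]["observed"] + sched[key]["credit"]
                d += timedelta(days=1)
        surplus = consumed - recorded * tpo
        max_credit = min(int(r["count"]), surplus // tpo if surplus > 0 else 0)
        given = 0
        d = start
        while d <= stop and given < max_credit:
            key = (r["patient_id"], r["em_id"], d)
            if key in sched:
                cell = sched[key]
                if cell["observed"] + cell["credit"] < cell["expected_prescribed"]:
                    cell["credit"] += 1
                    given += 1
            d += timedelta(days=1)

    # 5. mask nonmonitored periods
    for _, r in reports.iterrows():
        if r["report_type"] != "nonmonitored":
            continue
        d = _to_date(r["start_date"])
        stop = _to_date(r["end_date"])
        while d <= stop:
            key = (r["patient_id"], r["em_id"], d)
            if key in sched:
                sched[key]["monitored"] = False
            d += timedelta(days=1)

    rows = [
        (pid, em, pd.Timestamp(d), c["observed"], c["credit"],
         c["expected_prescribed"], c["expected_onlabel"], c["monitored"])
        for (pid, em, d), c in sorted(sched.items())
    ]
    return pd.DataFrame(
        rows,
        columns=["patient_id", "em_id", "date", "observed_openings",
                 "pocket_dose_credit", "expected_prescribed", "expected_onlabel",
                 "monitored"],
    )
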