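"""Expected-opening schedules from prescription histories.

A prescription history is a list of dated, inclusive segments per monitor,
each carrying the number of openings per day the oncologist prescribed
(``expected_openings_per_day``) and the number the manufacturer's label would
prescribe over the same days (``label_openings_per_day``).  The builder
expands the segments into a per-day table of expectations under both
conventions:

* **prescribed** -- the oncologist's regimen; during a prescribed transient
  interruption the expectation is 0, so taking nothing is optimal
  implementation.
* **on-label** -- the manufacturer's continuous regimen; during a prescribed
  interruption the label expectation stays positive, which is what makes the
  two conventions diverge.  Scheduled off-weeks of a cyclic regimen have a
  zero expectation under *both* conventions.

Dosing days are calendar days running from 03:00 to 02:59 local time; date
arithmetic here is on calendar dates only -- the 03:00 rule is applied where
timestamps are converted to dosing days (:mod:`emadhere.clean`).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SEGMENT_TYPES = ("regular", "cycle_on", "cycle_off", "interruption")


class ScheduleError(ValueError):
    """Invalid prescription history (overlap, gap, or bad segment)."""


def _as_date(col: pd.Series) -> pd.Series:
    return pd.to_datetime(col).dt.normalize()


def build_schedule(prescriptions: pd.DataFrame) -> pd.DataFrame:
    """Expand prescription segments into a day-level expectation table.

    Parameters
    ----------
    prescriptions:
        One row per segment with columns ``patient_id, em_id, start_date,
        end_date, expected_openings_per_day, segment_type,
        label_openings_per_day`` (an optional ``reason`` column is carried
        through for reporting).

    Returns
    -------
    DataFrame with one row per (monitor, day):
    ``patient_id, em_id, date, expected_prescribed, expected_onlabel,
    segment_type, reason``.

    Raises
    ------
    ScheduleError
        If a segment has ``start > end``, segments of one monitor overlap
        (the offending days are listed), the monitor's span has gaps (a day
        under monitoring must have a defined expectation), or an interruption
        segment has a nonzero prescribed expectation.
    """
    req = {
        "patient_id",
        "em_id",
        "start_date",
        "end_date",
        "expected_openings_per_day",
        "segment_type",
        "label_openings_per_day",
    }
    missing = req - set(prescriptions.columns)
    if missing:
        raise ScheduleError(f"prescriptions missing columns: {sorted(missing)}")

    df = prescriptions.copy()
    df["start_date"] = _as_date(df["start_date"])
    df["end_date"] = _as_date(df["end_date"])
    if "reason" not in df.columns:
        df["reason"] = ""
    df["reason"] = df["reason"].fillna("")

    bad_type = ~df["segment_type"].isin(SEGMENT_TYPES)
    if bad_type.any():
        raise ScheduleError(
            f"unknown segment_type values: {sorted(df.loc[bad_type, 'segment_type'].unique())}"
        )
    bad_span = df["start_date"] > df["end_date"]
    if bad_span.any():
        row = df[bad_span].iloc[0]
        raise ScheduleError(
            f"segment start after end for {row['em_id']} "
            f"({row['start_date'].date()} > {row['end_date'].date()})"
        )
    if (df["expected_openings_per_day"] < 0).any() or (df["label_openings_per_day"] < 0).any():
        raise ScheduleError("expected/label openings per day must be non-negative")
    bad_int = (df["segment_type"] == "interruption") & (df["expected_openings_per_day"] != 0)
    if bad_int.any():
        row = df[bad_int].iloc[0]
        raise ScheduleError(
            f"interruption segment with nonzero prescribed expectation for "
            f"{row['em_id']} starting {row['start_date'].date()}"
        )

    # deterministic, order-independent expansion
    df = df.sort_values(["patient_id", "em_id", "start_date", "end_date"], kind="mergesort")
    prev_end = df.groupby(["patient_id", "em_id"])["end_date"].shift()
    has_prev = prev_end.notna()
    overlap = has_prev & (df["start_date"] <= prev_end)
    if overlap.any():
        row = df[overlap].iloc[0]
        pe = prev_end[overlap].iloc[0]
        days = pd.date_range(row["start_date"], min(pe, row["end_date"]))
        raise ScheduleError(
            f"overlapping segments for monitor {row['em_id']}: days "
            f"{[d.date().isoformat() for d in days[:5]]}"
            + ("..." if len(days) > 5 else "")
        )
    gap = has_prev & (df["start_date"] > prev_end + pd.Timedelta(days=1))
    if gap.any():
        row = df[gap].iloc[0]
        pe = prev_end[gap].iloc[0]
        n_gap = (row["start_date"] - pe).days - 1
        raise ScheduleError(
            f"coverage gap for monitor {row['em_id']}: {n_gap} day(s) starting "
            f"{(pe + pd.Timedelta(days=1)).date().isoformat()} have no "
            "prescribed expectation"
        )
    lengths = (df["end_date"] - df["start_date"]).dt.days.to_numpy() + 1
    dates = np.concatenate(
        [
            pd.date_range(s, periods=k).to_numpy()
            for s, k in zip(df["start_date"], lengths)
        ]
    )
    out = pd.DataFrame(
        {
            "patient_id": np.repeat(df["patient_id"].to_numpy(), lengths),
            "em_id": np.repeat(df["em_id"].to_numpy(), lengths),
            "date": pd.DatetimeIndex(dates),
            "expected_prescribed": np.repeat(
                df["expected_openings_per_day"].to_numpy().astype(int), lengths
            ),
            "expected_onlabel": np.repeat(
                df["label_openings_per_day"].to_numpy().astype(int), lengths
            ),
            "segment_type": np.repeat(df["segment_type"].to_numpy(), lengths),
            "reason": np.repeat(df["reason"].to_numpy(), lengths),
        }
    )
    return out


def monitor_windows(schedule: pd.DataFrame) -> pd.DataFrame:
    """Actual start/end dates of EM use per monitor (the prescription span)."""
    g = schedule.groupby(["patient_id", "em_id"], sort=True)["date"]
    return g.agg(start="min", end="max").reset_index()


def transient_interruptions(schedule: pd.DataFrame, min_run: int = 3) -> pd.DataFrame:
    """Maximal runs of prescribed-zero / label-positive days per monitor.

    A *transient interruption* is a maximal run of consecutive days on which
    the prescribed expectation is 0 while the on-label expectation is
    positive, lasting more than 2 days in a row (``min_run`` = 3 by default,
    i.e. runs of length >= 3 are kept).  Scheduled cycle-off weeks are
    excluded because the label expectation is 0 there as well.

    Returns one row per interruption window:
    ``patient_id, em_id, start_date, end_date, duration_days``.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    rows = []
    flagged = schedule[
        (schedule["expected_prescribed"] == 0) & (schedule["expected_onlabel"] > 0)
    ]
    for (pid, em), grp in flagged.groupby(["patient_id", "em_id"], sort=True):
        dates = grp["date"].sort_values().reset_index(drop=True)
        if dates.empty:
            continue
        run_start = dates.iloc[0]
        prev = dates.iloc[0]
        for d in list(dates.iloc[1:]) + [None]:
            if d is not None and (d - prev).days == 1:
                prev = d
                continue
            length = (prev - run_start).days + 1
            if length >= min_run:
                rows.append((pid, em, run_start, prev, length))
            if d is not None:
                run_start = prev = d
    return pd.DataFrame(
        rows,
        columns=["patient_id", "em_id", "start_date", "end_date", "duration_days"],
    )
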