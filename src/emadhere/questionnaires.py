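"""Questionnaire scoring: BMQ subscales and QLQ-C30 domain scores.

BMQ: each of the 18 items is rated 1 "strongly agree" to 5 "strongly
disagree"; subscale scores add the *reversed* items (6 - raw), so higher
scores indicate stronger beliefs.  Admissible ranges are 5-25 for the 5-item
subscales (necessity, concerns) and 4-20 for the 4-item subscales
(overprescribing, prejudices).  A subscale with any missing item is missing
under the default (sum-based) policy.

QLQ-C30: the raw score RS of a scale is the mean of its available items;
the 0-100 score is ``(1 - (RS-1)/3) * 100`` for functioning,
``((RS-1)/3) * 100`` for symptoms and ``((RS-1)/6) * 100`` for global health
status.  The mean-based RS tolerates missing items by construction.

Group comparisons use Welch's two-sided t test (unequal variances,
Welch-Satterthwaite degrees of freedom); groups with fewer than two
non-missing scores are marked inestimable rather than raising.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy import stats


class ScoringError(ValueError):
    pass


def _load_instruments() -> dict:
    with resources.files("emadhere.data").joinpath("instruments.yaml").open() as fh:
        return yaml.safe_load(fh)


_INSTR = _load_instruments()
BMQ_SUBSCALES: dict[str, list[str]] = _INSTR["bmq"]
QLQ_SCALES: dict[str, list[str]] = _INSTR["qlq"]
QLQ_ITEM_RANGES: dict[str, tuple[int, int]] = {
    item: tuple(_INSTR["qlq_item_range"].get(item, _INSTR["qlq_item_range"]["default"]))
    for items in QLQ_SCALES.values()
    for item in items
}

BMQ_RANGES = {name: (len(items), 5 * len(items)) for name, items in BMQ_SUBSCALES.items()}
_QLQ_KIND = {"functional": "functional", "symptom": "symptom", "global": "global"}


def _pivot(responses: pd.DataFrame, instrument: str) -> pd.DataFrame:
    df = responses[responses["instrument"] == instrument]
    if df.empty:
        return pd.DataFrame()
    dup = df.duplicated(["patient_id", "wave", "item_id"])
    if dup.any():
        raise ScoringError("duplicate item responses for a patient/wave")
    return df.pivot_table(
        index=["patient_id", "wave"], columns="item_id", values="response",
        aggfunc="first",
    )


def score_bmq(
    responses: pd.DataFrame,
    item_map: dict[str, list[str]] | None = None,
    missing_policy: str = "strict",
) -> pd.DataFrame:
    """Score the BMQ subscales (sum of reversed items).

    ``missing_policy``: "strict" (default; any missing item makes the
    subscale missing) or "prorate" (scale the sum of available reversed
    items up to the full item count; at least half the items required).
    Responses outside 1-5 raise a validation error naming the item.
    """
    if missing_policy not in ("strict", "prorate"):
        raise ScoringError("missing_policy must be 'strict' or 'prorate'")
    item_map = item_map or BMQ_SUBSCALES
    wide = _pivot(responses, "BMQ")
    rows = []
    for scale, items in item_map.items():
        k = len(items)
        have = [i for i in items if not wide.empty and i in wide.columns]
        for idx in wide.index if not wide.empty else []:
            vals = wide.loc[idx, have] if have else pd.Series(dtype=float)
            present = vals.dropna()
            bad = present[(present < 1) | (present > 5)]
            if len(bad):
                raise ScoringError(
                    f"BMQ response out of range 1-5 for item {bad.index[0]!r} "
                    f"(patient {idx[0]}, wave {idx[1]}): {bad.iloc[0]}"
                )
            n_missing = k - len(present)
            if n_missing == 0:
                score = float((6 - present).sum())
            elif missing_policy == "prorate" and len(present) >= k / 2:
                score = float((6 - present).sum() * k / len(present))
            else:
                score = np.nan
            rows.append((idx[0], idx[1], scale, score, k, 5 * k, n_missing))
    return pd.DataFrame(
        rows,
        columns=["patient_id", "wave", "scale", "score", "range_min", "range_max",
                 "n_missing_items"],
    )


def score_qlq(
    responses: pd.DataFrame, scale_map: dict[str, list[str]] | None = None
) -> pd.DataFrame:
    """Score the QLQ-C30 domains via the linear 0-100 transformations."""
    scale_map = scale_map or QLQ_SCALES
    wide = _pivot(responses, "QLQC30")
    rows = []
    for scale, items in scale_map.items():
        kind = _QLQ_KIND.get(scale, "symptom")
        span = 6.0 if kind == "global" else 3.0
        have = [i for i in items if not wide.empty and i in wide.columns]
        for idx in wide.index if not wide.empty else []:
            vals = wide.loc[idx, have] if have else pd.Series(dtype=float)
            present = vals.dropna()
            for item, v in present.items():
                lo, hi = QLQ_ITEM_RANGES.get(item, (1, 4))
                if not lo <= v <= hi:
                    raise ScoringError(
                        f"QLQ-C30 response out of range {lo}-{hi} for item "
                        f"{item!r} (patient {idx[0]}, wave {idx[1]}): {v}"
                    )
            if len(present) == 0:
                score = np.nan
            else:
                rs = float(present.mean())
                if kind == "functional":
                    score = (1.0 - (rs - 1.0) / span) * 100.0
                else:
                    score = ((rs - 1.0) / span) * 100.0
            rows.append(
                (idx[0], idx[1], scale, score, 0.0, 100.0, len(items) - len(present))
            )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "wave", "scale", "score", "range_min", "range_max",
                 "n_missing_items"],
    )


def compare_groups(
    scores: pd.DataFrame, grouping: pd.DataFrame | dict
) -> pd.DataFrame:
    """Welch's t test per (scale, wave) between two groups.

    ``grouping`` maps patient_id to a group label (dict or a frame with
    ``patient_id``/``group`` columns).  Returns per-comparison means, SDs,
    sizes, missing counts, Welch t, Welch-Satterthwaite df and two-sided p;
    comparisons with fewer than two non-missing scores in either group are
    flagged inestimable with NaN statistics.
    """
    if isinstance(grouping, dict):
        gmap = pd.Series(grouping, name="group").rename_axis("patient_id").reset_index()
    else:
        gmap = grouping.rename(columns={grouping.columns[-1]: "group"})[
            ["patient_id", "group"]
        ]
    df = scores.merge(gmap, on="patient_id", how="inner")
    labels = sorted(df["group"].unique())
    if len(labels) != 2:
        raise ScoringError(f"need exactly two groups, got {labels}")
    g1, g2 = labels
    rows = []
    for (scale, wave), sub in df.groupby(["scale", "wave"], sort=True):
        a = sub.loc[sub["group"] == g1, "score"]
        b = sub.loc[sub["group"] == g2, "score"]
        a_obs, b_obs = a.dropna(), b.dropna()
        base = {
            "scale": scale,
            "wave": wave,
            "group1": g1,
            "group2": g2,
            "n1": len(a_obs),
            "n2": len(b_obs),
            "missing1": int(a.isna().sum()),
            "missing2": int(b.isna().sum()),
            "mean1": float(a_obs.mean()) if len(a_obs) else np.nan,
            "sd1": float(a_obs.std(ddof=1)) if len(a_obs) > 1 else np.nan,
            "mean2": float(b_obs.mean()) if len(b_obs) else np.nan,
            "sd2": float(b_obs.std(ddof=1)) if len(b_obs) > 1 else np.nan,
        }
        if len(a_obs) < 2 or len(b_obs) < 2:
            base.update(t=np.nan, df=np.nan, p=np.nan, inestimable=True)
        else:
            res = stats.ttest_ind(a_obs, b_obs, equal_var=False)
            base.update(
                t=float(res.statistic),
                df=float(res.df),
                p=float(res.pvalue),
                inestimable=False,
            )
        rows.append(base)
    return pd.DataFrame(rows)
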