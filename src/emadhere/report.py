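"""Config-driven pipeline orchestration and report rendering.

``run_pipeline`` chains simulate -> clean -> estimate -> model -> score and
writes every intermediate and final artifact to disk: the raw cohort CSVs,
the adherence table and QC report, outcome curves, model cards and a
prediction table shaped like a per-covariable results table, questionnaire
scores and group comparisons, trajectory figures, and a reproducibility
manifest (seed, config hash, package versions).  Figures are regenerated
solely from the on-disk intermediate CSVs, so any stage can be re-rendered
without hidden state.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .clean import clean_cohort
from .config import CohortConfig
from .estimators import (
    daily_outcome,
    empirical_adherence,
    empirical_implementation,
    km_persistence,
    persistence_records,
    to_randomization_clock,
)
from .gee import (
    DegenerateOutcomeError,
    GeeSpec,
    build_panel,
    fit_adherence_gee,
    build_adherence_panel,
    fit_implementation_gee,
    fit_population_gee,
    predict_representative,
    subgroup_analysis,
)
from .questionnaires import compare_groups, score_bmq, score_qlq
from .schedule import build_schedule, transient_interruptions
from .simulate import generate_cohort


#: covariables of the one-at-a-time analysis with their dichotomization cuts
#: (None = categorical as-is); continuous cuts follow the reported table
DEFAULT_SUBGROUPS: tuple = (
    ("gender", None),
    ("age", 60.0),
    ("days_since_pki_initiation", 60.0),
    ("metastasis", None),
    ("years_since_metastasis", 2.0),
    ("prior_adherence_tool", None),
)


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    seed: int = 0
    prediction_day: int = 180
    inclusion_window_days: int = 365
    randomization_window_days: int = 340
    degree: int = 3
    conventions: tuple = ("prescribed", "onlabel")
    subgroups: tuple = DEFAULT_SUBGROUPS

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = self.cohort.to_dict()
        d["conventions"] = list(self.conventions)
        d["subgroups"] = [list(s) for s in self.subgroups]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        if "conventions" in d:
            d["conventions"] = tuple(d["conventions"])
        if "subgroups" in d:
            d["subgroups"] = tuple(tuple(s) for s in d["subgroups"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run all stages, write artifacts under ``out_dir``, return the manifest."""
    out = Path(out_dir)
    (out / "raw").mkdir(parents=True, exist_ok=True)
    (out / "figures").mkdir(exist_ok=True)

    stage = "simulate"
    try:
        cohort = generate_cohort(config.cohort, config.seed)
        cohort.write(out / "raw")

        stage = "clean"
        res = clean_cohort(
            cohort.events,
            cohort.prescriptions,
            cohort.reports,
            cohort.pill_counts,
            cohort.patients,
            tz_offset_minutes=config.cohort.utc_offset_minutes,
        )
        res.table.to_csv(out / "adherence_table.csv", index=False)
        build_schedule(cohort.prescriptions).to_csv(out / "schedule.csv", index=False)
        with open(out / "qc_report.json", "w") as fh:
            json.dump(res.qc, fh, indent=1, sort_keys=True)

        stage = "estimate"
        curves = []
        outcomes = {}
        for conv in config.conventions:
            oc = daily_outcome(res.table, conv)
            outcomes[conv] = oc
            impl = empirical_implementation(oc, max_day=config.inclusion_window_days)
            impl.insert(0, "convention", conv)
            impl.insert(0, "curve", "implementation")
            curves.append(impl.rename(columns={"n": "n_at_risk"}))
        records = persistence_records(cohort.patients, clock="randomization")
        km = km_persistence(records, max_day=config.randomization_window_days)
        km.insert(0, "convention", "prescribed")
        km.insert(0, "curve", "persistence")
        km.to_csv(out / "persistence.csv", index=False)
        oc_rand = to_randomization_clock(
            outcomes["prescribed"], cohort.patients, config.randomization_window_days
        )
        adh = empirical_adherence(oc_rand, records, config.randomization_window_days)
        for name, cur in adh.items():
            cur = cur.copy()
            cur.insert(0, "convention", "prescribed")
            cur.insert(0, "curve", f"adherence_{name}")
            curves.append(cur.rename(columns={"n": "n_at_risk"}))
        curves.append(km.rename(columns={"n_at_risk": "n_at_risk"}))
        pd.concat(curves, ignore_index=True).to_csv(out / "curves.csv", index=False)
        transient_interruptions(res.table).to_csv(
            out / "interruptions.csv", index=False
        )

        stage = "model"
        spec = GeeSpec(degree=config.degree)
        panel = build_panel(outcomes["prescribed"], cohort.patients)
        cards: dict = {}
        pred_rows = []
        try:
            fit = fit_implementation_gee(panel, spec)
            cards["implementation"] = fit.model_card
            rep = predict_representative(
                fit, config.prediction_day, config.cohort.baseline_days
            )
            pred_rows.append(
                ("Randomization groups", rep.p_intervention * 100, rep.p_control * 100,
                 rep.delta * 100, rep.lo * 100, rep.hi * 100)
            )
            for cov, cut in config.subgroups:
                tab = subgroup_analysis(
                    panel, cov, spec, config.prediction_day,
                    config.cohort.baseline_days, cut=cut,
                )
                for r in tab.itertuples(index=False):
                    pred_rows.append(
                        (f"In {r.stratum}", r.p_intervention * 100, r.p_control * 100,
                         r.delta * 100, r.lo * 100, r.hi * 100)
                    )
        except DegenerateOutcomeError:
            cards["implementation"] = {"degenerate": True, "note": "all outcomes correct"}
            pred_rows.append(("Randomization groups", 100.0, 100.0, 0.0, 0.0, 0.0))

        for conv in config.conventions:
            pn = build_panel(outcomes[conv], cohort.patients, extra_covariables=False)
            try:
                pop = fit_population_gee(pn, GeeSpec(degree=config.degree, convention=conv))
                cards[f"whole_sample_{conv}"] = pop.model_card
                p, lo, hi = pop.predict_probability(config.prediction_day)
                pred_rows.append(
                    (f"Whole sample ({conv} regimen)", np.nan, np.nan,
                     p * 100, lo * 100, hi * 100)
                )
            except DegenerateOutcomeError:
                cards[f"whole_sample_{conv}"] = {"degenerate": True}
                pred_rows.append(
                    (f"Whole sample ({conv} regimen)", np.nan, np.nan, 100.0, 100.0, 100.0)
                )
        try:
            adh_panel = build_adherence_panel(
                outcomes["prescribed"], cohort.patients,
                config.randomization_window_days,
            )
            adh_fit = fit_adherence_gee(adh_panel, spec)
            cards["adherence"] = adh_fit.model_card
            arep = predict_representative(adh_fit, config.prediction_day, 0)
            pred_rows.append(
                ("Adherence since randomization", arep.p_intervention * 100,
                 arep.p_control * 100, arep.delta * 100, arep.lo * 100, arep.hi * 100)
            )
        except DegenerateOutcomeError:
            cards["adherence"] = {"degenerate": True}
            pred_rows.append(("Adherence since randomization", 100.0, 100.0, 0.0, 0.0, 0.0))

        predictions = pd.DataFrame(
            pred_rows,
            columns=["stratum", "intervention_pct", "control_pct", "delta_pts",
                     "lo", "hi"],
        )
        predictions.to_csv(out / "predictions.csv", index=False)
        with open(out / "model_card.json", "w") as fh:
            json.dump(cards, fh, indent=1, sort_keys=True, default=str)

        stage = "score"
        scores = pd.concat(
            [score_bmq(cohort.questionnaires), score_qlq(cohort.questionnaires)],
            ignore_index=True,
        )
        scores.to_csv(out / "scores.csv", index=False)
        randomized = cohort.patients[cohort.patients["randomized"].astype(bool)]
        if randomized["arm"].nunique() == 2 and len(scores):
            comp = compare_groups(
                scores, randomized[["patient_id", "arm"]]
            )
            comp.to_csv(out / "score_comparisons.csv", index=False)

        stage = "figures"
        render_figures(out)
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline failed during stage {stage!r}: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "versions": _versions(),
        "artifacts": sorted(
            str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()
        ),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _versions() -> dict:
    import lifelines
    import matplotlib
    import scipy
    import statsmodels

    from . import __version__

    return {
        "emadhere": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
        "lifelines": lifelines.__version__,
        "matplotlib": matplotlib.__version__,
    }


def render_figures(out_dir) -> list:
    """Render the trajectory, dual-convention and persistence figures.

    Reads only the intermediate CSVs under ``out_dir``.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    figdir = out / "figures"
    figdir.mkdir(exist_ok=True)
    curves = pd.read_csv(out / "curves.csv")
    written = []

    impl = curves[(curves["curve"] == "implementation")]
    if len(impl):
        fig, (ax, axn) = plt.subplots(
            2, 1, figsize=(8, 5), sharex=True, height_ratios=[4, 1]
        )
        colors = {"prescribed": "black", "onlabel": "firebrick"}
        for conv, sub in impl.groupby("convention"):
            ax.plot(sub["day"], sub["estimate"] * 100, color=colors.get(conv, "gray"),
                    lw=0.8, alpha=0.7, label=f"empirical ({conv})")
            ax.fill_between(sub["day"], sub["lo"] * 100, sub["hi"] * 100,
                            color=colors.get(conv, "gray"), alpha=0.12)
            axn.plot(sub["day"], sub["n_at_risk"], color=colors.get(conv, "gray"), lw=0.8)
        ax.set_ylabel("implementation (%)")
        ax.set_ylim(0, 102)
        ax.legend(loc="lower left", fontsize=8)
        axn.set_ylabel("n observed")
        axn.set_xlabel("days since inclusion")
        fig.tight_layout()
        path = figdir / "implementation.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    pers = curves[curves["curve"] == "persistence"]
    adh = curves[curves["curve"] == "adherence_product"]
    if len(pers):
        fig, ax = plt.subplots(figsize=(7, 4))
        ax.step(pers["day"], pers["estimate"], where="post", color="navy",
                label="persistence (Kaplan-Meier)")
        ax.fill_between(pers["day"], pers["lo"], pers["hi"], step="post",
                        color="navy", alpha=0.15)
        if len(adh):
            ax.plot(adh["day"], adh["estimate"], color="darkgreen",
                    label="adherence (implementation x persistence)")
        ax.set_xlabel("days since randomization")
        ax.set_ylabel("probability")
        ax.set_ylim(0, 1.02)
        ax.legend(loc="lower left", fontsize=8)
        fig.tight_layout()
        path = figdir / "persistence_adherence.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
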