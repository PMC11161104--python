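"""Synthetic two-arm electronic-monitoring (EM) cohort generator.

Emits the raw artifacts of an EM adherence trial -- timestamped monitor
opening events, dated prescription segments (including cyclic regimens and
prescribed transient interruptions), patient reports of pocket doses,
curiosity openings and nonmonitored periods, pharmacy pill counts,
questionnaire item responses -- together with the generating truth, which the
analysis pipeline never reads.

Calibration
-----------
The generator works backwards from *marginal* targets.  Given the target
day-level implementation trajectory ``m(t)`` per arm (a logistic curve
anchored at day 180, see :class:`emadhere.config.IntakeModel`), the observed
daily outcome decomposes as

    m(t) = f(t) + (1 - f(t)) * p*(t)

where ``f(t)`` is the fraction of patient-days on which the prescribed
expectation is zero (cycle-off weeks and prescribed interruptions: the
outcome is then "correct" by definition) and ``p*(t)`` the intake probability
on active days.  The conditional intercept ``c(t)`` of the latent logistic
model ``P(intake | b_i) = expit(c(t) + b_i)`` is solved per arm and day so
that the average over the patients at risk equals ``p*(t)``.  Intake is a
single patient-day draw shared by all of a patient's monitors (patients take
their drugs together), which keeps the patient-level outcome marginal equal
to the calibrated intake probability for multi-monitor patients too.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

from .config import CohortConfig, ConfigError

ARM_INTERVENTION = "intervention"
ARM_CONTROL = "control"

_EVENT_REASONS = ("adverse_event", "personal")
_CENSOR_REASONS = ("progression", "asymptomatic_toxicity", "study_exit")
_INTERRUPTION_REASONS = ("clinical", "administrative", "patient_request")

_STUDY_EPOCH = date(2021, 1, 4)


# --------------------------------------------------------------------------- #
# calibration helpers
# --------------------------------------------------------------------------- #

def marginal_parameters(config: CohortConfig) -> tuple[float, float, float]:
    """Solve the marginal trajectory ``logit m = a + s*t + d*TI(t)``.

    Returns ``(a, s, d)``: intercept, secular log-odds slope per day, and
    intervention effect per day of exposure, from the two day-180 anchors.
    Anchors of exactly 1.0 map to an infinite intercept (certain intake).
    """
    im = config.intake_model
    s = im.logit_slope_per_day
    t0 = im.anchor_day
    if im.control_day180 >= 1.0:
        a = np.inf
    else:
        a = logit(im.control_day180) - s * t0
    exposure = t0 - config.baseline_days
    if exposure <= 0:
        raise ConfigError("intake_model.anchor_day must exceed baseline_days")
    if im.intervention_day180 >= 1.0 or np.isinf(a):
        d = 0.0 if np.isinf(a) else np.inf
    else:
        d = (logit(im.intervention_day180) - logit(im.control_day180)) / exposure
    return float(a), float(s), float(d)


def _gh_nodes(sigma: float, n: int = 41):
    x, w = np.polynomial.hermite_e.hermegauss(n)
    return x * sigma, w / w.sum()


def solve_conditional_intercept(
    p_target: float,
    b_values: np.ndarray | None = None,
    sigma: float | None = None,
    _gh_cache: dict = {},
) -> float:
    """Solve ``mean(expit(c + b)) = p_target`` for ``c``.

    ``b_values`` gives the realized random intercepts ("realized" mode);
    otherwise the expectation is over N(0, sigma^2) via Gauss-Hermite
    quadrature ("population" mode).  Returns +/-inf for targets at 0 or 1.
    """
    if p_target >= 1.0 - 1e-12:
        return np.inf
    if p_target <= 1e-12:
        return -np.inf
    if b_values is None:
        if sigma is None:
            raise ValueError("either b_values or sigma is required")
        if sigma == 0.0:
            return float(logit(p_target))
        key = round(sigma, 12)
        if key not in _gh_cache:
            _gh_cache[key] = _gh_nodes(sigma)
        nodes, weights = _gh_cache[key]

        def f(c):
            return float(np.dot(weights, expit(c + nodes))) - p_target
    else:
        b_values = np.asarray(b_values, dtype=float)
        if b_values.size == 0:
            raise ValueError("empty risk set")

        def f(c):
            return float(np.mean(expit(c + b_values))) - p_target

    return float(brentq(f, -40.0, 40.0, xtol=1e-10))


def interruption_duration_pmf(
    median_days: float, log_sd: float, max_days: int = 400
) -> np.ndarray:
    """PMF of the rounded log-normal interruption duration (support 1..max)."""
    k = np.arange(1, max_days + 1)
    if log_sd == 0.0:
        pmf = np.zeros(max_days)
        pmf[min(max_days, max(1, round(median_days))) - 1] = 1.0
        return pmf
    upper = norm.cdf((np.log(k + 0.5) - np.log(median_days)) / log_sd)
    lower = norm.cdf((np.log(np.maximum(k - 0.5, 1e-9)) - np.log(median_days)) / log_sd)
    pmf = upper - lower
    pmf[0] = upper[0]
    return pmf / pmf.sum()


def solve_interruption_hazard(config: CohortConfig) -> float:
    """Peak daily hazard of interruption onset for interruption-prone patients.

    Solved so that the expected fraction of *all* patient-days spent under a
    prescribed interruption at ``ramp_until_day`` equals the configured
    prevalence.  Uses the discrete renewal recursion
    ``P_int(t) = sum_u h(u) (1 - P_int(u)) P(D >= t - u + 1)``.
    """
    m = config.interruption_model
    if m.prone_fraction <= 0 or m.prevalence_day180 <= 0:
        return 0.0
    target = m.prevalence_day180 / m.prone_fraction
    if target >= 1.0:
        raise ConfigError(
            "interruption_model.prevalence_day180 is unattainable for the "
            "configured prone_fraction"
        )
    pmf = interruption_duration_pmf(m.duration_median_days, m.duration_log_sd)
    surv = np.concatenate([[1.0], 1.0 - np.cumsum(pmf)])  # surv[k] = P(D > k)
    ramp = m.ramp_until_day
    horizon = ramp + 1

    def prevalence(h_peak: float) -> float:
        p_int = np.zeros(horizon)
        starts = np.zeros(horizon)
        for t in range(horizon):
            if t > 0:
                k = t - np.arange(t)
                p_int[t] = float(np.dot(starts[:t], surv[np.minimum(k, len(surv) - 1)]))
                p_int[t] = min(p_int[t], 1.0)
            h = h_peak * min(t, ramp) / ramp
            starts[t] = h * (1.0 - p_int[t])
        return p_int[ramp]

    lo, hi = 0.0, 0.5
    if prevalence(hi) < target:
        raise ConfigError(
            "interruption_model.prevalence_day180 too high for the duration "
            "distribution"
        )
    return float(brentq(lambda h: prevalence(h) - target, lo, hi, xtol=1e-8))


# --------------------------------------------------------------------------- #
# cohort container
# --------------------------------------------------------------------------- #

@dataclass
class SimulatedCohort:
    """In-memory synthetic cohort: raw data frames plus the generating truth."""

    config: CohortConfig
    patients: pd.DataFrame
    events: pd.DataFrame
    prescriptions: pd.DataFrame
    reports: pd.DataFrame
    pill_counts: pd.DataFrame
    questionnaires: pd.DataFrame
    truth: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frames = {
            "patients.csv": self.patients,
            "events.csv": self.events,
            "prescriptions.csv": self.prescriptions,
            "reports.csv": self.reports,
            "pill_counts.csv": self.pill_counts,
            "questionnaires.csv": self.questionnaires,
        }
        for name, df in frames.items():
            df.to_csv(out / name, index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)


def read_cohort_dir(in_dir) -> dict:
    """Read the raw CSVs of a cohort directory into data frames."""
    p = Path(in_dir)
    out = {}
    for name in ("patients", "events", "prescriptions", "reports",
                 "pill_counts", "questionnaires"):
        f = p / f"{name}.csv"
        out[name] = pd.read_csv(f) if f.exists() else None
    return out


# --------------------------------------------------------------------------- #
# generation
# --------------------------------------------------------------------------- #

def _offset_string(minutes: int) -> str:
    sign = "+" if minutes >= 0 else "-"
    minutes = abs(minutes)
    return f"{sign}{minutes // 60:02d}:{minutes % 60:02d}"


def generate_cohort(config: CohortConfig, seed: int | None = None) -> SimulatedCohort:
    """Generate a full synthetic cohort.

    The same (config, seed) pair always produces identical output.  ``seed``
    overrides ``config.seed`` when given.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_patients
    H = config.horizon_days
    epd = config.openings_per_day
    cycle_len = config.cycle_on_days + config.cycle_off_days

    pids = [f"P{i + 1:03d}" for i in range(n)]
    inclusion_offset = rng.integers(0, 365, n)
    inclusion_dates = [_STUDY_EPOCH + timedelta(days=int(o)) for o in inclusion_offset]

    # arm allocation (1:1 by default) and randomization day
    n_int = int(round(n * config.allocation_ratio))
    perm = rng.permutation(n)
    is_int = np.zeros(n, dtype=bool)
    is_int[perm[:n_int]] = True
    r_day = np.full(n, config.baseline_days)

    # covariables (cohort-descriptive distributions)
    age = np.clip(np.round(rng.normal(61, 11, n)), 25, 92).astype(int)
    gender = np.where(rng.random(n) < 0.60, "F", "M")
    metastasis = rng.random(n) < 0.81
    days_since_pki = np.clip(
        np.round(rng.lognormal(np.log(60), 1.1, n)), 1, 4000
    ).astype(int)
    years_since_met = np.where(
        metastasis, np.round(rng.lognormal(np.log(1.7), 0.9, n), 2), np.nan
    )
    prior_tool = rng.random(n) < 0.25

    # regimen structure
    cyclic = rng.random(n) < config.cyclic_fraction
    multi = (~cyclic) & (rng.random(n) < config.multi_monitor_fraction)
    phase = rng.integers(0, max(cycle_len, 1), n)

    # dropout: event (discontinuation for cause) vs censoring
    dm = config.discontinuation_model
    lam_e = np.where(
        is_int,
        -np.log(dm.event_survival_day180_intervention) / 180.0,
        -np.log(dm.event_survival_day180_control) / 180.0,
    )
    lam_c = np.where(
        is_int,
        dm.censor_hazard_per_day_intervention,
        dm.censor_hazard_per_day_control,
    )
    u_e = rng.random(n)
    u_c = rng.random(n)
    with np.errstate(divide="ignore"):
        te = np.where(lam_e > 0, np.floor(-np.log(u_e) / np.maximum(lam_e, 1e-300)), np.inf)
        tc = np.where(lam_c > 0, np.floor(-np.log(u_c) / np.maximum(lam_c, 1e-300)), np.inf)
    end_day = np.minimum(np.minimum(te, tc), H - 1).astype(int)
    status = np.where((te <= tc) & (te <= H - 1), "event", "censored")
    reason_pick = rng.random(n)
    reasons = []
    for i in range(n):
        if status[i] == "event":
            reasons.append(_EVENT_REASONS[0] if reason_pick[i] < 0.7 else _EVENT_REASONS[1])
        elif end_day[i] >= H - 1 and tc[i] > H - 1 and te[i] > H - 1:
            reasons.append("study_completed")
        else:
            j = 0 if reason_pick[i] < 0.6 else (1 if reason_pick[i] < 0.75 else 2)
            reasons.append(_CENSOR_REASONS[j])
    randomized = end_day >= r_day

    # prescribed transient interruptions (continuous-regimen patients only;
    # on cyclic regimens a prescribed pause is absorbed into the cycle record)
    imod = config.interruption_model
    prone_p = (
        imod.prone_fraction / (1.0 - config.cyclic_fraction)
        if config.cyclic_fraction < 1.0
        else 0.0
    )
    prone = (~cyclic) & (rng.random(n) < prone_p)
    h_peak = solve_interruption_hazard(config)
    interruptions: list[list[tuple[int, int, str]]] = []
    for i in range(n):
        wins: list[tuple[int, int, str]] = []
        if prone[i] and h_peak > 0:
            u = rng.random(H)
            t = 0
            while t < H:
                h = h_peak * min(t, imod.ramp_until_day) / imod.ramp_until_day
                if u[t] < h:
                    dur = max(
                        1,
                        int(round(rng.lognormal(np.log(imod.duration_median_days),
                                                imod.duration_log_sd))),
                    )
                    why = _INTERRUPTION_REASONS[
                        int(rng.choice(3, p=[0.7, 0.15, 0.15]))
                    ]
                    wins.append((t, min(t + dur - 1, H - 1), why))
                    t += dur + 2  # at least one active day between interruptions
                else:
                    t += 1
        # clip to the observation window
        wins = [(int(s), int(min(e, end_day[i])), why) for s, e, why in wins if s <= end_day[i]]
        interruptions.append(wins)

    # per-patient day-level schedule (shared by all of a patient's monitors)
    label = np.zeros((n, H), dtype=int)
    for i in range(n):
        d = np.arange(H)
        if cyclic[i]:
            on = ((d + phase[i]) % cycle_len) < config.cycle_on_days
            label[i] = np.where(on, epd, 0)
        else:
            label[i] = epd
    expected = label.copy()
    interrupted = np.zeros((n, H), dtype=bool)
    for i, wins in enumerate(interruptions):
        for s, e, _ in wins:
            interrupted[i, s:e + 1] = True
    expected[interrupted] = 0

    at_risk = np.arange(H)[None, :] <= end_day[:, None]
    auto = (expected == 0) & at_risk  # zero-expectation days: correct by definition

    # --- latent intake calibration ------------------------------------------
    a, s_slope, d_eff = marginal_parameters(config)
    im = config.intake_model
    b = rng.normal(0.0, im.random_intercept_sd, n)
    delta_i = np.where(is_int, d_eff, 0.0)
    if im.effect_modifier is not None:
        col, val, extra = im.effect_modifier
        cov = {"gender": gender, "metastasis": metastasis,
               "prior_adherence_tool": prior_tool}.get(col)
        if cov is None:
            raise ConfigError(f"intake_model.effect_modifier column {col!r} unknown")
        delta_i = delta_i + np.where(is_int & (cov == val), extra, 0.0)

    t_grid = np.arange(H)
    ti = np.maximum(0, t_grid[None, :] - r_day[:, None]) * is_int[:, None]
    p_intake = np.zeros((n, H))
    if np.isinf(a):
        p_intake[:] = 1.0
    else:
        eta_m = a + s_slope * t_grid[None, :] + delta_i[:, None] * ti
        m = expit(eta_m)
        # groups of patients sharing a marginal trajectory
        keys = [(bool(is_int[i]), float(delta_i[i]), int(r_day[i])) for i in range(n)]
        for key in sorted(set(keys)):
            members = np.array([k == key for k in keys])
            for t in range(H):
                risk = members & at_risk[:, t]
                if not risk.any():
                    continue
                active = risk & ~auto[:, t]
                n_risk = int(risk.sum())
                f_auto = 1.0 - active.sum() / n_risk
                if not active.any():
                    continue
                m_t = float(m[members.argmax(), t])
                p_star = (m_t - f_auto) / (1.0 - f_auto)
                p_star = min(max(p_star, 0.0), 1.0)
                if im.calibration == "realized":
                    c = solve_conditional_intercept(p_star, b_values=b[active])
                else:
                    c = solve_conditional_intercept(
                        p_star, sigma=im.random_intercept_sd
                    )
                p_intake[active, t] = expit(c + b[active])

    u_intake = rng.random((n, H))
    intake = (u_intake < p_intake) & at_risk & ~auto

    # --- reported deviations -------------------------------------------------
    dev = config.deviation_model
    nonmon = np.zeros((n, H), dtype=bool)
    nonmon_windows: list[list[tuple[int, int]]] = []
    u_nm = rng.random(n)
    for i in range(n):
        wins = []
        if u_nm[i] < dev.nonmonitored_rate and end_day[i] >= dev.nonmonitored_min_days:
            dur = int(rng.integers(dev.nonmonitored_min_days,
                                   dev.nonmonitored_max_days + 1))
            latest = max(0, end_day[i] - dur + 1)
            start = int(rng.integers(0, latest + 1))
            stop = min(start + dur - 1, end_day[i])
            nonmon[i, start:stop + 1] = True
            wins.append((int(start), int(stop)))
        nonmon_windows.append(wins)

    n_monitors = np.where(multi, 2, 1)
    max_mon = int(n_monitors.max())
    pocket = np.zeros((n, max_mon, H), dtype=bool)
    pocket_episodes: list[list[tuple[int, int, int]]] = []  # (monitor, start, end)
    u_pock = rng.random((n, H))
    u_len = rng.random((n, H))
    for i in range(n):
        eps = []
        t = 0
        while t <= end_day[i]:
            eligible = intake[i, t] and expected[i, t] > 0 and not nonmon[i, t]
            if eligible and u_pock[i, t] < dev.pocket_episode_rate:
                length = 1
                if (
                    u_len[i, t] < dev.pocket_two_day_fraction
                    and t + 1 <= end_day[i]
                    and intake[i, t + 1]
                    and expected[i, t + 1] > 0
                    and not nonmon[i, t + 1]
                ):
                    length = 2
                mon = int(rng.integers(0, n_monitors[i]))
                pocket[i, mon, t:t + length] = True
                eps.append((mon, t, t + length - 1))
                t += length + 1
            else:
                t += 1
        pocket_episodes.append(eps)

    u_cur = rng.random((n, max_mon, H))
    curiosity = np.zeros((n, max_mon, H), dtype=bool)
    for i in range(n):
        for mon in range(n_monitors[i]):
            curiosity[i, mon] = (
                (u_cur[i, mon] < dev.curiosity_rate)
                & at_risk[i]
                & ~nonmon[i]
            )

    # --- assemble output frames ---------------------------------------------
    offset = _offset_string(config.utc_offset_minutes)
    ev_rows: list[tuple[str, str, str]] = []
    presc_rows = []
    report_rows = []
    pill_rows = []
    seg_names = {0: "regular"}

    for i in range(n):
        pid = pids[i]
        inc = inclusion_dates[i]
        seg_type = np.empty(end_day[i] + 1, dtype=object)
        for d in range(end_day[i] + 1):
            if interrupted[i, d]:
                seg_type[d] = "interruption"
            elif cyclic[i]:
                seg_type[d] = "cycle_on" if label[i, d] > 0 else "cycle_off"
            else:
                seg_type[d] = "regular"
        reason_by_day = {}
        for s, e, why in interruptions[i]:
            for d in range(s, e + 1):
                reason_by_day[d] = why
        for mon in range(n_monitors[i]):
            em = f"{pid}-EM{mon + 1}"
            # prescription segments: maximal runs of constant (expected, label, type)
            d0 = 0
            for d in range(1, end_day[i] + 2):
                boundary = d > end_day[i] or (
                    expected[i, d] != expected[i, d0]
                    or label[i, d] != label[i, d0]
                    or seg_type[d] != seg_type[d0]
                )
                if boundary:
                    presc_rows.append(
                        (
                            pid,
                            em,
                            (inc + timedelta(days=d0)).isoformat(),
                            (inc + timedelta(days=d - 1)).isoformat(),
                            int(expected[i, d0]),
                            seg_type[d0],
                            int(label[i, d0]),
                            reason_by_day.get(d0, ""),
                        )
                    )
                    if d <= end_day[i]:
                        d0 = d
            # daily openings and event timestamps
            for d in range(end_day[i] + 1):
                count = 0
                if (
                    intake[i, d]
                    and expected[i, d] > 0
                    and not pocket[i, mon, d]
                    and not nonmon[i, d]
                ):
                    count += int(expected[i, d])
                if curiosity[i, mon, d]:
                    count += 1
                for _ in range(count):
                    if rng.random() < config.after_midnight_fraction:
                        stamp_date = inc + timedelta(days=d + 1)
                        secs = int(rng.random() * 3 * 3600)
                    else:
                        stamp_date = inc + timedelta(days=d)
                        lo = config.intake_window_start_hour * 3600
                        hi = config.intake_window_end_hour * 3600
                        secs = int(lo + rng.random() * (hi - lo))
                    hh, rem = divmod(secs, 3600)
                    mm, ss = divmod(rem, 60)
                    ev_rows.append(
                        (
                            pid,
                            em,
                            f"{stamp_date.isoformat()}T{hh:02d}:{mm:02d}:{ss:02d}{offset}",
                        )
                    )
            # pill counts per 28-day refill period
            p0 = 0
            while p0 <= end_day[i]:
                p1 = min(p0 + 27, end_day[i])
                days = np.arange(p0, p1 + 1)
                consumed = int(
                    np.sum(intake[i, days] & (expected[i, days] > 0) & ~nonmon[i, days])
                )
                dispensed = int(np.sum(expected[i, days])) + 2
                pill_rows.append(
                    (
                        pid,
                        em,
                        (inc + timedelta(days=p0)).isoformat(),
                        (inc + timedelta(days=int(p1))).isoformat(),
                        dispensed,
                        dispensed - consumed,
                        1,
                    )
                )
                p0 = p1 + 1
            # reports
            for mon_ep, s, e in pocket_episodes[i]:
                if mon_ep == mon:
                    report_rows.append(
                        (
                            pid,
                            em,
                            "pocket_dose",
                            (inc + timedelta(days=s)).isoformat(),
                            (inc + timedelta(days=e)).isoformat(),
                            e - s + 1,
                        )
                    )
            for s, e in nonmon_windows[i]:
                report_rows.append(
                    (
                        pid,
                        em,
                        "nonmonitored",
                        (inc + timedelta(days=s)).isoformat(),
                        (inc + timedelta(days=e)).isoformat(),
                        e - s + 1,
                    )
                )
            for d in np.nonzero(curiosity[i, mon])[0]:
                day_str = (inc + timedelta(days=int(d))).isoformat()
                report_rows.append((pid, em, "curiosity", day_str, day_str, 1))

    events = pd.DataFrame(ev_rows, columns=["patient_id", "em_id", "timestamp"])
    prescriptions = pd.DataFrame(
        presc_rows,
        columns=[
            "patient_id",
            "em_id",
            "start_date",
            "end_date",
            "expected_openings_per_day",
            "segment_type",
            "label_openings_per_day",
            "reason",
        ],
    )
    reports = pd.DataFrame(
        report_rows,
        columns=["patient_id", "em_id", "report_type", "start_date", "end_date", "count"],
    )
    pill_counts = pd.DataFrame(
        pill_rows,
        columns=[
            "patient_id",
            "em_id",
            "period_start",
            "period_end",
            "dispensed",
            "returned",
            "tablets_per_opening",
        ],
    )

    patients = pd.DataFrame(
        {
            "patient_id": pids,
            "arm": np.where(is_int, ARM_INTERVENTION, ARM_CONTROL),
            "randomized": randomized,
            "inclusion_date": [d.isoformat() for d in inclusion_dates],
            "randomization_date": [
                (inclusion_dates[i] + timedelta(days=int(r_day[i]))).isoformat()
                if randomized[i]
                else ""
                for i in range(n)
            ],
            "end_date": [
                (inclusion_dates[i] + timedelta(days=int(end_day[i]))).isoformat()
                for i in range(n)
            ],
            "exit_reason": reasons,
            "age": age,
            "gender": gender,
            "metastasis": metastasis,
            "days_since_pki_initiation": days_since_pki,
            "years_since_metastasis": years_since_met,
            "prior_adherence_tool": prior_tool,
        }
    )

    questionnaires = _generate_questionnaires(
        config, rng, pids, end_day, H
    )

    truth = {
        "marginal": {
            "logit_intercept": a if np.isfinite(a) else None,
            "logit_slope_per_day": s_slope,
            "effect_per_day": d_eff if np.isfinite(d_eff) else None,
            "control_day180": im.control_day180,
            "intervention_day180": im.intervention_day180,
            "persistence_day180": {
                ARM_INTERVENTION: dm.event_survival_day180_intervention,
                ARM_CONTROL: dm.event_survival_day180_control,
            },
        },
        "interruption_peak_hazard": h_peak,
        "patients": {
            pids[i]: {
                "arm": ARM_INTERVENTION if is_int[i] else ARM_CONTROL,
                "random_intercept": float(b[i]),
                "randomization_day": int(r_day[i]),
                "end_day": int(end_day[i]),
                "status": str(status[i]),
                "exit_reason": reasons[i],
                "cyclic": bool(cyclic[i]),
                "n_monitors": int(n_monitors[i]),
                "interruptions": [[int(s), int(e)] for s, e, _ in interruptions[i]],
                "pocket_episodes": [
                    [int(mon), int(s), int(e)] for mon, s, e in pocket_episodes[i]
                ],
                "nonmonitored": [[int(s), int(e)] for s, e in nonmon_windows[i]],
                "curiosity_days": [
                    [int(mon), int(d)]
                    for mon in range(n_monitors[i])
                    for d in np.nonzero(curiosity[i, mon])[0]
                ],
                "latent_intake_p": [round(float(x), 4) for x in p_intake[i, : end_day[i] + 1]],
            }
            for i in range(n)
        },
    }

    return SimulatedCohort(
        config=config,
        patients=patients,
        events=events,
        prescriptions=prescriptions,
        reports=reports,
        pill_counts=pill_counts,
        questionnaires=questionnaires,
        truth=truth,
    )


def _generate_questionnaires(config, rng, pids, end_day, horizon) -> pd.DataFrame:
    from .questionnaires import BMQ_SUBSCALES, QLQ_SCALES, QLQ_ITEM_RANGES

    qm = config.questionnaire_model
    wave_days = {0: 0, 6: 182, 12: 364}
    rows = []
    for i, pid in enumerate(pids):
        for wave, wday in wave_days.items():
            reached = end_day[i] >= min(wday, horizon - 1)
            if not reached or rng.random() > qm.response_rate:
                continue
            for scale, items in BMQ_SUBSCALES.items():
                mu = 6.0 - qm.bmq_means[scale] / len(items)
                for item in items:
                    resp = int(np.clip(round(rng.normal(mu, qm.bmq_item_sd)), 1, 5))
                    rows.append((pid, wave, "BMQ", item, resp))
            for scale, items in QLQ_SCALES.items():
                s_target = qm.qlq_means[scale]
                for item in items:
                    lo, hi = QLQ_ITEM_RANGES[item]
                    span = hi - lo
                    if scale == "functional":
                        mu = lo + span * (1.0 - s_target / 100.0)
                    else:
                        mu = lo + span * s_target / 100.0
                    resp = int(np.clip(round(rng.normal(mu, qm.qlq_item_sd)), lo, hi))
                    rows.append((pid, wave, "QLQC30", item, resp))
    return pd.DataFrame(
        rows, columns=["patient_id", "wave", "instrument", "item_id", "response"]
    )


# --------------------------------------------------------------------------- #
# lightweight outcome panel (for model-level simulation studies)
# --------------------------------------------------------------------------- #

def simulate_outcome_panel(config: CohortConfig, seed: int | None = None):
    """Daily binary outcome panel straight from the latent model.

    Skips the file-level artifacts (events, reports, pill counts): returns a
    tidy frame of patient-day outcomes under the prescribed-regimen
    convention plus a small truth dict.  Used for parameter-recovery and
    confidence-interval calibration studies where only the marginal model
    matters.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, H = config.n_patients, config.horizon_days

    n_int = int(round(n * config.allocation_ratio))
    perm = rng.permutation(n)
    is_int = np.zeros(n, dtype=bool)
    is_int[perm[:n_int]] = True
    r_day = np.full(n, config.baseline_days)

    dm = config.discontinuation_model
    lam_e = np.where(
        is_int,
        -np.log(dm.event_survival_day180_intervention) / 180.0,
        -np.log(dm.event_survival_day180_control) / 180.0,
    )
    lam_c = np.where(
        is_int,
        dm.censor_hazard_per_day_intervention,
        dm.censor_hazard_per_day_control,
    )
    u_e, u_c = rng.random(n), rng.random(n)
    te = np.where(lam_e > 0, np.floor(-np.log(u_e) / np.maximum(lam_e, 1e-300)), np.inf)
    tc = np.where(lam_c > 0, np.floor(-np.log(u_c) / np.maximum(lam_c, 1e-300)), np.inf)
    end_day = np.minimum(np.minimum(te, tc), H - 1).astype(int)

    a, s_slope, d_eff = marginal_parameters(config)
    im = config.intake_model
    b = rng.normal(0.0, im.random_intercept_sd, n)
    t_grid = np.arange(H)
    ti = np.maximum(0, t_grid[None, :] - r_day[:, None]) * is_int[:, None]
    at_risk = t_grid[None, :] <= end_day[:, None]

    if np.isinf(a):
        p = np.ones((n, H))
    else:
        m = expit(a + s_slope * t_grid[None, :] + d_eff * ti)
        p = np.zeros((n, H))
        for key in (True, False):
            members = is_int == key
            for t in range(H):
                risk = members & at_risk[:, t]
                if not risk.any():
                    continue
                m_t = float(m[members.argmax(), t])
                if im.calibration == "realized":
                    c = solve_conditional_intercept(m_t, b_values=b[risk])
                else:
                    c = solve_conditional_intercept(m_t, sigma=im.random_intercept_sd)
                p[risk, t] = expit(c + b[risk])

    y = (rng.random((n, H)) < p) & at_risk
    idx_i, idx_t = np.nonzero(at_risk)
    panel = pd.DataFrame(
        {
            "patient_id": np.array([f"P{i + 1:03d}" for i in range(n)])[idx_i],
            "day_index": idx_t,
            "value": y[idx_i, idx_t].astype(float),
            "arm": np.where(is_int[idx_i], ARM_INTERVENTION, ARM_CONTROL),
            "randomized": end_day[idx_i] >= r_day[idx_i],
            "randomization_day": r_day[idx_i],
        }
    )
    truth = {
        "effect_per_day": d_eff,
        "logit_intercept": a,
        "logit_slope_per_day": s_slope,
    }
    return panel, truth
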