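"""Synthetic replicate of the high-dose oral baclofen steady-state trial.

The generator reproduces the study design: 57 completers in four daily-dose
groups (10/15/16/16; <60, 60-120, >120-180, >180 mg/d), 2-8 intended intakes
per day at least 4 h apart, a 3-day (72 h) run-in to steady state, and a
sparse sampling day (D1) with 9-10 samples per subject drawn within fixed
windows around two consecutive intakes (pre-dose, 0-1, 1-2, 2-3 h and the
late window after the primary intake N; pre-dose, 0-1, 1-2 h after the
secondary intake n) plus a next-day (D2) pre-dose trough.  Concentrations
below the 5 ng/mL quantification limit are censored (BLQ).

Group-level dose, age, sex and intake-count distributions are the published
study summaries; weight/height/creatinine and liver markers, which the study
does not tabulate, use documented default distributions (they only feed the
covariate screen, which the study found empty).

All randomness flows from one master seed through numpy SeedSequence
spawning: one child stream for covariates, then one per subject (regimen,
sampling times, eta, epsilon), so subject k's data do not depend on how many
draws earlier subjects consumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .covariates import bmi as _bmi, cockcroft_gault, lbm_james
from .data import LLOQ_NG_ML, NG_PER_MG_L, StudyDataset
from .engine import OmegaMatrix, SigmaModel
from .model import ThetaVector, concentration_mgL


@dataclass(frozen=True)
class GroupDesign:
    """One dose group: size and its dose / age / sex / intake distributions."""

    n: int
    dose_mean: float
    dose_sd: float
    dose_min: float
    dose_max: float
    age_mean: float
    age_sd: float
    age_min: float
    age_max: float
    female_frac: float
    intakes_mean: float
    intakes_sd: float
    intakes_min: int
    intakes_max: int


@dataclass(frozen=True)
class StudyDesign:
    groups: tuple = ()
    lloq_ng_ml: float = LLOQ_NG_ML
    run_in_h: float = 72.0
    first_dose_clock_h: float = 8.0     # clock time of the first daily intake
    min_gap_h: float = 4.0
    miss_rate: float = 0.0              # optional per-sample missingness

    @property
    def n_subjects(self) -> int:
        return sum(g.n for g in self.groups)


def default_design() -> StudyDesign:
    """The trial's design: group sizes 10/15/16/16 with published summaries."""
    groups = (
        GroupDesign(10, 37.00, 9.49, 30.0, 50.0, 56.75, 9.83, 42.2, 75.0, 0.500, 2.80, 0.63, 2, 4),
        GroupDesign(15, 93.33, 21.93, 60.0, 120.0, 44.80, 13.21, 23.4, 66.1, 0.200, 3.40, 0.74, 2, 5),
        GroupDesign(16, 163.13, 17.78, 130.0, 180.0, 45.16, 11.29, 25.6, 68.7, 0.313, 3.44, 1.15, 2, 7),
        GroupDesign(16, 250.63, 39.41, 190.0, 300.0, 43.97, 9.16, 33.8, 59.4, 0.375, 3.94, 1.48, 2, 8),
    )
    return StudyDesign(groups=groups)


def reference_estimates() -> tuple[ThetaVector, OmegaMatrix, SigmaModel]:
    """Published population estimates for racemic oral baclofen in adults
    with alcohol use disorder (used as the simulation truth)."""
    theta = ThetaVector(tvcl=11.6, tvv=72.8, tvka=1.64)
    omega = OmegaMatrix.from_sd(0.21, 0.22, 0.44)
    sigma = SigmaModel(0.24)
    return theta, omega, sigma


@dataclass
class Regimen:
    group: int                  # 1-based
    daily_dose: float           # mg
    n_intakes: int
    amounts: tuple              # per-intake mg, first carries the remainder
    offsets: tuple              # h within the day from the first intake
    dose_times: np.ndarray      # h from record origin, run-in + D1
    gap_h: float                # inter-intake gap (= 24 / n_intakes)


@dataclass
class GeneratedStudy:
    dataset: StudyDataset
    covariates: pd.DataFrame
    truth: dict                 # theta/omega/sigma, per-subject eta, per-obs eps,
                                # noise-free concentrations (ng/mL)
    design: StudyDesign
    seed: int


def _truncnorm(rng, mean, sd, lo, hi, size=None):
    if lo >= hi:
        raise ValueError("impossible truncation bounds")
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_subjects(design: StudyDesign, seed) -> pd.DataFrame:
    """Per-subject covariate table (demographics + biology; dose columns are
    appended by :func:`simulate_study` once regimens are drawn)."""
    rng = np.random.default_rng(seed)
    rows = []
    sid = 0
    for gi, g in enumerate(design.groups, start=1):
        for _ in range(g.n):
            sid += 1
            age = float(_truncnorm(rng, g.age_mean, g.age_sd, g.age_min, g.age_max))
            sex = int(rng.random() < g.female_frac)   # 0 male, 1 female
            # defaults for distributions the study does not tabulate
            wt = float(_truncnorm(rng, 75.0 + (5.0 if sex == 0 else 0.0), 15.0, 45.0, 130.0))
            ht = float(_truncnorm(rng, 170.0 + (8.0 if sex == 0 else 0.0), 10.0, 150.0, 200.0))
            crcl = 0.0
            while True:
                crea = float(_truncnorm(rng, 0.9 + (0.1 if sex == 0 else 0.0), 0.2, 0.5, 1.6))
                crcl = cockcroft_gault(age, wt, crea, sex)
                if crcl > 30.0:     # renal exclusion criterion
                    break
            pt = float(_truncnorm(rng, 95.0, 10.0, 60.0, 130.0))
            bili = float(_truncnorm(rng, 0.8, 0.3, 0.2, 2.0))
            ast = float(np.exp(_truncnorm(rng, np.log(30.0), 0.4, np.log(10.0), np.log(200.0))))
            alt = float(np.exp(_truncnorm(rng, np.log(32.0), 0.45, np.log(8.0), np.log(250.0))))
            rows.append({
                "ID": sid, "GROUP": gi, "SEX": sex, "AGE": age, "WT": wt, "HT": ht,
                "BMI": _bmi(wt, ht / 100.0), "LBM": lbm_james(wt, ht, sex),
                "CREA": crea, "CRCL": crcl, "PT": pt, "BILI": bili,
                "AST": ast, "ALT": alt,
            })
    return pd.DataFrame(rows).set_index("ID")


_GROUP_EDGES = (60.0, 120.0, 180.0)   # <60 / 60-120 / >120-180 / >180


def _dose_group(daily: float) -> int:
    if daily < _GROUP_EDGES[0]:
        return 1
    if daily <= _GROUP_EDGES[1]:
        return 2
    if daily <= _GROUP_EDGES[2]:
        return 3
    return 4


def generate_regimen(design: StudyDesign, group: int, seed) -> Regimen:
    """Draw a subject's regimen: daily dose (10-mg units), intakes/day, and an
    evenly spread daily schedule with >= 4 h gaps, repeated over run-in + D1.

    Intake counts whose even 24-h spread cannot respect the 4-h gap are
    redrawn (so realised counts top out at 24/min_gap = 6 per day).
    """
    g = design.groups[group - 1]
    rng = np.random.default_rng(seed)
    max_feasible = int(24.0 // design.min_gap_h)
    while True:
        daily = float(np.round(_truncnorm(rng, g.dose_mean, g.dose_sd, g.dose_min, g.dose_max) / 10.0) * 10.0)
        daily = float(np.clip(daily, max(g.dose_min, 10.0), g.dose_max))
        if _dose_group(daily) == group:
            break
    while True:
        n = int(np.round(_truncnorm(rng, g.intakes_mean, g.intakes_sd,
                                    g.intakes_min - 0.49, g.intakes_max + 0.49)))
        n = int(np.clip(n, g.intakes_min, g.intakes_max))
        if n <= max_feasible and daily / n >= 10.0:   # keep 10-mg units per intake
            break
    base = np.floor(daily / n / 10.0) * 10.0
    amounts = np.full(n, base)
    amounts[0] += daily - base * n
    gap = 24.0 / n
    offsets = np.arange(n) * gap
    n_days = int(design.run_in_h / 24.0) + 1          # run-in days + D1
    dose_times = (np.arange(n_days)[:, None] * 24.0 + offsets[None, :]).ravel()
    return Regimen(group=group, daily_dose=daily, n_intakes=n,
                   amounts=tuple(amounts), offsets=tuple(offsets),
                   dose_times=dose_times, gap_h=gap)


#: nominal windows (h after the reference intake) by tag
SAMPLING_TAGS = ("preN", "N+0-1", "N+1-2", "N+2-3", "N+3+", "N+3+b",
                 "pren", "n+0-1", "n+1-2", "D2-trough")


def sampling_times(regimen: Regimen, seed, run_in_h: float = 72.0) -> list[tuple[float, str]]:
    """9-10 timed sample slots with window tags for one subject.

    Primary intake N is the first D1 intake; secondary intake n is the next
    one.  The late window (3 h after N up to n) yields two samples when it is
    at least 2 h wide, one otherwise — hence 9 or 10 samples in total.
    """
    rng = np.random.default_rng(seed)
    t_n_primary = run_in_h                          # first intake of D1
    t_n_secondary = run_in_h + regimen.gap_h
    t_d2 = run_in_h + 24.0                          # first intake of D2 (not dosed)
    u = lambda lo, hi: float(rng.uniform(lo, hi))
    out = [
        (t_n_primary - u(0.05, 0.5), "preN"),
        (t_n_primary + u(0.0, 1.0), "N+0-1"),
        (t_n_primary + u(1.0, 2.0), "N+1-2"),
        (t_n_primary + u(2.0, 3.0), "N+2-3"),
    ]
    late_lo, late_hi = t_n_primary + 3.0, t_n_secondary
    if late_hi - late_lo >= 2.0:
        mid = 0.5 * (late_lo + late_hi)
        out.append((u(late_lo, mid), "N+3+"))
        out.append((u(mid, late_hi), "N+3+b"))
    else:
        out.append((u(late_lo, late_hi), "N+3+"))
    out += [
        (t_n_secondary - u(0.02, 0.15), "pren"),
        (t_n_secondary + u(0.0, 1.0), "n+0-1"),
        (t_n_secondary + u(1.0, 2.0), "n+1-2"),
        (t_d2 - u(0.05, 0.5), "D2-trough"),
    ]
    out.sort(key=lambda x: x[0])
    return out


def simulate_study(design: StudyDesign | None = None,
                   theta: ThetaVector | None = None,
                   omega: OmegaMatrix | None = None,
                   sigma: SigmaModel | None = None,
                   seed: int = 0,
                   truth_effects: Sequence = ()) -> GeneratedStudy:
    """Compose subjects, regimens, sampling, PK profiles, noise and censoring.

    ``truth_effects`` — optional (CovariateEffect, coefficients) pairs applied
    to the generating typical values, for covariate-selection power studies
    (the trial itself is generated with none).
    """
    design = design or default_design()
    if theta is None or omega is None or sigma is None:
        t0, o0, s0 = reference_estimates()
        theta = theta or t0
        omega = omega or o0
        sigma = sigma or s0
    ss = np.random.SeedSequence(seed)
    cov_seed, *subj_seeds = ss.spawn(1 + design.n_subjects)
    cov = generate_subjects(design, cov_seed)

    w = omega.sd
    rows = []
    truth_eta = {}
    truth_eps = []
    truth_conc = []
    daily_doses, n_intakes_col = [], []
    for i, sid in enumerate(cov.index):
        group = int(cov.loc[sid, "GROUP"])
        sub_ss = subj_seeds[i]
        reg_seed, samp_seed, eta_seed, eps_seed = sub_ss.spawn(4)
        regimen = generate_regimen(design, group, reg_seed)
        slots = sampling_times(regimen, samp_seed, design.run_in_h)
        rng_eta = np.random.default_rng(eta_seed)
        rng_eps = np.random.default_rng(eps_seed)
        eta = rng_eta.standard_normal(3) * w
        log_tv = np.log([theta.tvcl, theta.tvv, theta.tvka])
        pos = {"CL": 0, "V": 1, "KA": 2}
        for eff, coeffs in truth_effects:
            x = eff.design_row(cov.loc[sid, eff.covariate])
            log_tv[pos[eff.parameter]] += float(np.dot(x, np.asarray(coeffs, float)))
        cl, v, ka = np.exp(log_tv + eta)
        truth_eta[sid] = eta
        daily_doses.append(regimen.daily_dose)
        n_intakes_col.append(regimen.n_intakes)

        amounts = np.tile(regimen.amounts, len(regimen.dose_times) // regimen.n_intakes)
        for t_dose, a in zip(regimen.dose_times, amounts):
            rows.append({"ID": sid, "TIME": t_dose, "AMT": a, "DV": np.nan,
                         "EVID": 1, "MDV": 1, "BLQ": 0, "TAG": ""})
        if design.miss_rate > 0:
            slots = [s for s in slots if rng_eps.random() >= design.miss_rate]
        times = np.array([t for t, _ in slots])
        delta = times[:, None] - regimen.dose_times[None, :]
        active = delta > 0
        amt_m = np.where(active, amounts[None, :], 0.0)
        dt_m = np.where(active, delta, 0.0)
        c_mgL = concentration_mgL(amt_m, dt_m,
                                  np.full(len(times), cl),
                                  np.full(len(times), v),
                                  np.full(len(times), ka))
        c_ng = c_mgL * NG_PER_MG_L
        eps = rng_eps.standard_normal(len(times)) * sigma.sigma
        y_ng = c_ng * np.exp(eps)
        for (t_s, tag), c_true, e, y in zip(slots, c_ng, eps, y_ng):
            blq = y < design.lloq_ng_ml
            rows.append({"ID": sid, "TIME": t_s,
                         "AMT": np.nan, "DV": (np.nan if blq else y),
                         "EVID": 0, "MDV": int(blq), "BLQ": int(blq), "TAG": tag})
            truth_eps.append(e)
            truth_conc.append(c_true)

    events = pd.DataFrame(rows).sort_values(["ID", "TIME", "EVID"],
                                            kind="stable").reset_index(drop=True)
    cov = cov.copy()
    cov["DOSE"] = daily_doses
    cov["NINTAKES"] = n_intakes_col
    dataset = StudyDataset(events, cov)
    truth = {
        "theta": {"tvcl": theta.tvcl, "tvv": theta.tvv, "tvka": theta.tvka},
        "omega_sd": {"CL": w[0], "V": w[1], "KA": w[2]},
        "sigma": sigma.sigma,
        "eta": {int(k): list(map(float, v)) for k, v in truth_eta.items()},
        "eps": [float(x) for x in truth_eps],
        "conc_true_ng": [float(x) for x in truth_conc],
    }
    return GeneratedStudy(dataset=dataset, covariates=cov, truth=truth,
                          design=design, seed=int(seed) if np.isscalar(seed) else 0)
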