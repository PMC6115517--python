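"""Covariate effects, derived clinical covariates, and stepwise covariate search.

Continuous covariates act as power functions of the median-centred value,
``P = TVP * (x / median)**theta``; categorical covariates as multipliers,
``P = TVP * m**I(level)`` with m > 0 (optimised as beta = log m); a
multilevel covariate gets one multiplier per non-reference level.

Selection follows forward inclusion / backward elimination on the objective
function: a candidate enters when the OFV drops by at least the chi-squared
critical value for its degrees of freedom at P = 0.05 (3.84 for 1 df), and is
retained only if its removal raises the OFV by more than the P = 0.001
critical value (10.8 for 1 df, 16.3 for 3 df).  Categorical levels below 10%
prevalence are pooled before testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import StudyDataset
from .engine import FitResult, FitSettings, fit as engine_fit
from .model import ThetaVector


@dataclass(frozen=True)
class CovariateEffect:
    """One parameter-covariate link.

    form:
        "power"       continuous, coefficient = exponent theta
        "categorical" 0/1 indicator, coefficient = log multiplier
        "multilevel"  one log multiplier per non-reference level
    reference:
        median for "power"; the reference level for "multilevel"
        (for "categorical" the reference is the 0 coding).
    levels:
        non-reference levels, in coefficient order (multilevel only).
    """

    parameter: str
    covariate: str
    form: str
    reference: float = 1.0
    levels: tuple = ()

    def __post_init__(self):
        if self.parameter not in ("CL", "V", "KA"):
            raise ValueError("parameter must be CL, V or KA")
        if self.form not in ("power", "categorical", "multilevel"):
            raise ValueError(f"unknown form {self.form!r}")
        if self.form == "power" and not self.reference > 0:
            raise ValueError("power reference (median) must be positive")

    @property
    def df(self) -> int:
        if self.form == "multilevel":
            return len(self.levels)
        return 1

    def design_row(self, value) -> np.ndarray:
        return self.design_matrix(np.asarray([value]))[0]

    def design_matrix(self, values: np.ndarray) -> np.ndarray:
        """(n, df) matrix X such that log-factor = X @ coefficients."""
        if self.form == "power":
            v = np.asarray(values, float)
            if np.any(v <= 0):
                raise ValueError(f"nonpositive value for covariate {self.covariate}")
            return np.log(v / self.reference)[:, None]
        if self.form == "categorical":
            return np.asarray(values, float)[:, None]
        cols = [np.asarray(values == lev, float) for lev in self.levels]
        return np.stack(cols, axis=1)

    def label(self) -> str:
        return f"{self.covariate}~{self.parameter}"


# ---------------------------------------------------------------------------
# derived clinical covariates
# ---------------------------------------------------------------------------

def cockcroft_gault(age: float, weight: float, scr: float, sex) -> float:
    """Creatinine clearance (mL/min): (140 - age) * weight / (72 * SCr), x0.85 if female.

    ``sex`` is 0/'M' for male, 1/'F' for female; serum creatinine in mg/dL.
    """
    female = sex in (1, "F", "f", "female")
    if scr <= 0:
        raise ValueError("serum creatinine must be positive")
    if weight <= 0 or age < 0 or age >= 140:
        if age == 140:
            return 0.0
        if not (0 <= age <= 140):
            raise ValueError("age out of range")
        raise ValueError("weight must be positive")
    crcl = (140.0 - age) * weight / (72.0 * scr)
    return crcl * 0.85 if female else crcl


def bmi(weight_kg: float, height_m: float) -> float:
    """Body mass index, kg/m^2."""
    if height_m <= 0:
        raise ValueError("height must be positive")
    return weight_kg / height_m ** 2


def lbm_james(weight_kg: float, height_cm: float, sex) -> float:
    """Lean body mass by the James equations (height in cm)."""
    if height_cm <= 0:
        raise ValueError("height must be positive")
    female = sex in (1, "F", "f", "female")
    r = weight_kg / height_cm
    if female:
        return 1.07 * weight_kg - 148.0 * r ** 2
    return 1.10 * weight_kg - 128.0 * r ** 2


def derived_covariates(weight_kg: float, height_m: float, sex) -> dict:
    """BMI (kg/m^2) and James LBM (kg) with the formula choice recorded."""
    return {
        "BMI": bmi(weight_kg, height_m),
        "LBM": lbm_james(weight_kg, height_m * 100.0, sex),
        "lbm_formula": "james",
    }


def lrt_threshold(df: int, alpha: float, rounded: bool = True) -> float:
    """Critical OFV drop: upper-alpha chi-squared quantile with ``df`` degrees.

    Rounded to three significant figures for reporting (3.84, 10.8, 16.3);
    pass ``rounded=False`` for the raw quantile.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    q = float(stats.chi2.ppf(1.0 - alpha, df))
    return float(f"{q:.3g}") if rounded else q


# ---------------------------------------------------------------------------
# pooling rule
# ---------------------------------------------------------------------------

def pool_rare_levels(values: np.ndarray, min_frac: float = 0.10):
    """Pool categorical levels under ``min_frac`` prevalence into their neighbour.

    Levels are assumed ordinal (pooling merges a rare level with the adjacent
    retained level).  Returns (pooled values, mapping) or (None, mapping) when
    pooling collapses everything to a single level (covariate dropped).
    """
    values = np.asarray(values)
    n = len(values)
    levels = sorted(pd.unique(values).tolist())
    mapping = {lev: lev for lev in levels}
    changed = True
    while changed:
        changed = False
        counts = pd.Series([mapping[v] for v in values]).value_counts()
        kept = sorted(counts.index.tolist())
        for lev in kept:
            if counts[lev] / n < min_frac and len(kept) > 1:
                pos = kept.index(lev)
                target = kept[pos - 1] if pos > 0 else kept[pos + 1]
                for k, v in mapping.items():
                    if v == lev:
                        mapping[k] = target
                changed = True
                break
    pooled = np.asarray([mapping[v] for v in values])
    if len(pd.unique(pooled)) < 2:
        return None, mapping
    return pooled, mapping


# ---------------------------------------------------------------------------
# candidate construction
# ---------------------------------------------------------------------------

#: covariate -> PK parameters screened, on physiological-plausibility grounds
DEFAULT_SEARCH_SPACE = {
    "CL": ["DOSE", "GROUP", "NINTAKES", "SEX", "WT", "AGE", "BMI", "LBM",
           "CRCL", "CREA", "PT", "BILI", "AST", "ALT"],
    "V": ["WT", "BMI", "LBM", "SEX"],
    "KA": ["NINTAKES", "DOSE"],
}

_CATEGORICAL = {"SEX"}
_MULTILEVEL = {"GROUP"}


def make_candidate(parameter: str, covariate: str, cov_table: pd.DataFrame,
                   min_frac: float = 0.10):
    """Build a pooled, median-centred candidate effect; None if degenerate."""
    values = cov_table[covariate].to_numpy()
    if covariate in _MULTILEVEL:
        pooled, _ = pool_rare_levels(values, min_frac)
        if pooled is None:
            return None
        counts = pd.Series(pooled).value_counts()
        top = counts.max()
        ref = min(lev for lev in counts.index if counts[lev] == top)
        levels = tuple(lev for lev in sorted(counts.index) if lev != ref)
        return CovariateEffect(parameter, covariate, "multilevel",
                               reference=float(ref), levels=levels)
    if covariate in _CATEGORICAL:
        frac = np.mean(values == 1)
        if min(frac, 1 - frac) < min_frac:
            return None
        return CovariateEffect(parameter, covariate, "categorical")
    med = float(np.median(values))
    if med <= 0:
        return None
    return CovariateEffect(parameter, covariate, "power", reference=med)


def default_candidates(cov_table: pd.DataFrame,
                       search_space: dict | None = None) -> list[CovariateEffect]:
    space = search_space or DEFAULT_SEARCH_SPACE
    out = []
    for param, covs in space.items():
        for cov in covs:
            if cov not in cov_table.columns:
                continue
            cand = make_candidate(param, cov, cov_table)
            if cand is not None:
                out.append(cand)
    return out


# ---------------------------------------------------------------------------
# stepwise search
# ---------------------------------------------------------------------------

@dataclass
class SearchRecord:
    step: str
    effect: str
    delta_ofv: float
    threshold: float
    accepted: bool
    note: str = ""


@dataclass
class SearchResult:
    fit: FitResult
    effects: tuple
    records: list


def _refit(dataset, base: FitResult, effects, settings) -> FitResult:
    theta0 = _dc_replace(base.theta, cov_coeffs=())
    return engine_fit(dataset, theta0, base.omega, base.sigma,
                      effects=effects, settings=settings)


def forward_step(dataset: StudyDataset, base_fit: FitResult,
                 candidates: Sequence[CovariateEffect], alpha: float = 0.05,
                 settings: FitSettings | None = None) -> SearchResult:
    """Greedy best-first forward inclusion on OFV drop.

    Each remaining candidate is tested against the current model; the largest
    significant drop (>= chi2 critical value at ``alpha`` for the candidate's
    df) is added, and the scan repeats until nothing passes.
    """
    current = base_fit
    included: list[CovariateEffect] = []
    remaining = list(candidates)
    records: list[SearchRecord] = []
    while remaining:
        best = None
        best_fit = None
        best_drop = -np.inf
        for cand in remaining:
            thr = lrt_threshold(cand.df, alpha)
            try:
                cfit = _refit(dataset, current, tuple(included + [cand]), settings)
            except Exception as exc:  # candidate fit failed outright
                records.append(SearchRecord("forward", cand.label(), np.nan, thr,
                                            False, f"fit error: {exc}"))
                continue
            if not cfit.converged:
                records.append(SearchRecord("forward", cand.label(), np.nan, thr,
                                            False, "non-convergence, skipped"))
                continue
            drop = current.ofv - cfit.ofv
            passed = drop >= thr
            records.append(SearchRecord("forward", cand.label(), float(drop), thr, passed))
            if passed and drop > best_drop:
                best, best_fit, best_drop = cand, cfit, drop
        if best is None:
            break
        included.append(best)
        remaining = [c for c in remaining if c is not best]
        current = best_fit
        records.append(SearchRecord("forward-accept", best.label(), float(best_drop),
                                    lrt_threshold(best.df, alpha), True))
    return SearchResult(current, tuple(included), records)


def backward_step(dataset: StudyDataset, full: SearchResult, alpha: float = 0.001,
                  settings: FitSettings | None = None) -> SearchResult:
    """Backward elimination: drop, one at a time, every effect whose removal
    raises the OFV by no more than the chi-squared critical value at ``alpha``."""
    current = full.fit
    effects = list(full.effects)
    records = list(full.records)
    while effects:
        worst = None
        worst_fit = None
        worst_rise = np.inf
        for eff in effects:
            thr = lrt_threshold(eff.df, alpha)
            reduced = [e for e in effects if e is not eff]
            try:
                rfit = _refit(dataset, current, tuple(reduced), settings)
            except Exception as exc:
                records.append(SearchRecord("backward", eff.label(), np.nan, thr,
                                            True, f"fit error: {exc}; retained"))
                continue
            rise = rfit.ofv - current.ofv
            retained = rise > thr
            records.append(SearchRecord("backward", eff.label(), float(rise), thr, retained))
            if not retained and rise < worst_rise:
                worst, worst_fit, worst_rise = eff, rfit, rise
        if worst is None:
            break
        effects = [e for e in effects if e is not worst]
        current = worst_fit
        records.append(SearchRecord("backward-remove", worst.label(), float(worst_rise),
                                    lrt_threshold(worst.df, alpha), False))
    return SearchResult(current, tuple(effects), records)


def covariate_search(dataset: StudyDataset, base_fit: FitResult,
                     candidates: Sequence[CovariateEffect],
                     forward_alpha: float = 0.05, backward_alpha: float = 0.001,
                     settings: FitSettings | None = None) -> SearchResult:
    """Full forward-inclusion / backward-elimination procedure."""
    fwd = forward_step(dataset, base_fit, candidates, forward_alpha, settings)
    return backward_step(dataset, fwd, backward_alpha, settings)
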