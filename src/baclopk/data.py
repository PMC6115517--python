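"""Study dataset container: dosing events, timed concentration observations, covariates.

The on-disk dialect is a NONMEM-style event table (one CSV row per dose or
observation; see :mod:`baclopk.dataio`).  In memory a :class:`StudyDataset`
holds two pandas frames — the event table and a per-subject covariate table —
plus a cached "compiled" numeric view used by the estimation engine.

Unit convention: files and the public API carry concentrations in ng/mL (assay
units); all likelihood computation is done in mg and L, i.e. mg/L, with the
fixed conversion 1 mg/L = 1000 ng/mL.  Times are hours from each subject's
first recorded dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NG_PER_MG_L = 1000.0
LLOQ_NG_ML = 5.0

EVENT_COLUMNS = ["ID", "TIME", "AMT", "DV", "EVID", "MDV", "BLQ"]


@dataclass
class CompiledData:
    """Flat numeric view of a dataset for vectorised likelihood evaluation.

    Observation rows are stacked across subjects; each row carries the padded
    history of doses preceding it (``amt`` is zero for padding and for doses
    administered after the observation, so superposition is a plain sum over
    the dose axis).
    """

    subject_ids: np.ndarray          # unique IDs in order of appearance
    sub_idx: np.ndarray              # (n_obs,) index into subject_ids
    times: np.ndarray                # (n_obs,) h
    dv_ng: np.ndarray                # (n_obs,) ng/mL, NaN when BLQ/missing
    blq: np.ndarray                  # (n_obs,) bool
    dt: np.ndarray                   # (n_obs, Dmax) h since each dose, >= 0
    amt: np.ndarray                  # (n_obs, Dmax) mg, 0 for inactive doses
    tad: np.ndarray                  # (n_obs,) h since most recent dose

    @property
    def n_sub(self) -> int:
        return len(self.subject_ids)

    @property
    def n_obs(self) -> int:
        return len(self.times)

    @property
    def log_y(self) -> np.ndarray:
        """log observed concentration in mg/L (NaN for BLQ rows)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.log(self.dv_ng / NG_PER_MG_L)

    def fit_mask(self) -> np.ndarray:
        """Rows entering the likelihood: quantifiable (non-BLQ) observations."""
        return ~self.blq & np.isfinite(self.dv_ng)


class StudyDataset:
    """Dosing events + concentration observations + per-subject covariates."""

    def __init__(self, events: pd.DataFrame, covariates: pd.DataFrame | None = None):
        missing = [c for c in EVENT_COLUMNS if c not in events.columns]
        if missing:
            raise ValueError(f"event table missing columns: {missing}")
        self.events = events.reset_index(drop=True)
        if covariates is not None:
            if "ID" in covariates.columns:
                covariates = covariates.set_index("ID")
            covariates = covariates.loc[self.subject_ids()]
        self.covariates = covariates
        self._compiled: CompiledData | None = None
        self._validate()

    # -- basic accessors ---------------------------------------------------
    def subject_ids(self) -> list:
        seen: dict = {}
        for i in self.events["ID"]:
            seen.setdefault(i, None)
        return list(seen)

    @property
    def n_subjects(self) -> int:
        return self.events["ID"].nunique()

    def doses(self) -> pd.DataFrame:
        return self.events[self.events["EVID"] == 1]

    def observations(self) -> pd.DataFrame:
        return self.events[self.events["EVID"] == 0]

    @property
    def n_observations(self) -> int:
        return int((self.events["EVID"] == 0).sum())

    @property
    def n_blq(self) -> int:
        obs = self.observations()
        return int((obs["BLQ"] == 1).sum())

    def _validate(self) -> None:
        ev = self.events
        for sid, g in ev.groupby("ID", sort=False):
            t = g["TIME"].to_numpy(float)
            if np.any(np.diff(t) < -1e-9):
                raise ValueError(f"TIME not non-decreasing within subject {sid}")
            if not (g["EVID"] == 1).any():
                raise ValueError(f"subject {sid} has no dose records")
        obs = self.observations()
        bad = obs[(obs["BLQ"] == 1) & obs["DV"].notna()]
        if len(bad):
            raise ValueError(f"BLQ observation with DV present at rows {list(bad.index)}")
        doses = self.doses()
        if (doses["AMT"] <= 0).any():
            raise ValueError("nonpositive dose amount")

    # -- compiled view -----------------------------------------------------
    def compile(self) -> CompiledData:
        """Flatten into contiguous per-subject numeric arrays (cached)."""
        if self._compiled is not None:
            return self._compiled
        ev = self.events
        ids_arr = ev["ID"].to_numpy()
        times_all = ev["TIME"].to_numpy(float)
        evid = ev["EVID"].to_numpy()
        dv_all = pd.to_numeric(ev["DV"], errors="coerce").to_numpy(float)
        blq_all = pd.to_numeric(ev["BLQ"], errors="coerce").to_numpy(float) == 1
        amt_all = pd.to_numeric(ev["AMT"], errors="coerce").to_numpy(float)
        sub_ids = list(dict.fromkeys(ids_arr.tolist()))

        per_sub = []
        dmax = 1
        for sid in sub_ids:
            m = ids_arr == sid
            md = m & (evid == 1)
            mo = m & (evid == 0)
            t_dose = times_all[md]
            a_dose = amt_all[md]
            t_obs = times_all[mo]
            delta = t_obs[:, None] - t_dose[None, :]
            active = delta > 0
            per_sub.append((t_obs, dv_all[mo], blq_all[mo],
                            np.where(active, delta, 0.0),
                            np.where(active, a_dose[None, :], 0.0)))
            dmax = max(dmax, len(t_dose))

        n_obs = sum(len(p[0]) for p in per_sub)
        dt = np.zeros((n_obs, dmax))
        amt = np.zeros((n_obs, dmax))
        times = np.empty(n_obs)
        dv = np.empty(n_obs)
        blq = np.empty(n_obs, bool)
        sub_idx = np.empty(n_obs, np.intp)
        tad = np.full(n_obs, np.nan)
        at = 0
        for i, (t_obs, dv_o, blq_o, d_m, a_m) in enumerate(per_sub):
            n = len(t_obs)
            sl = slice(at, at + n)
            times[sl] = t_obs
            dv[sl] = dv_o
            blq[sl] = blq_o
            sub_idx[sl] = i
            dt[sl, :d_m.shape[1]] = d_m
            amt[sl, :a_m.shape[1]] = a_m
            with np.errstate(invalid="ignore"):
                pos = np.where(d_m > 0, d_m, np.inf)
                row_tad = pos.min(axis=1) if d_m.shape[1] else np.full(n, np.inf)
            tad[sl] = np.where(np.isfinite(row_tad), row_tad, np.nan)
            at += n

        self._compiled = CompiledData(
            subject_ids=np.asarray(sub_ids),
            sub_idx=sub_idx,
            times=times,
            dv_ng=dv,
            blq=blq,
            dt=dt,
            amt=amt,
            tad=tad,
        )
        return self._compiled

    def subset_subjects(self, ids: list, new_ids: list | None = None) -> "StudyDataset":
        """Dataset restricted to ``ids`` (with repetition allowed, for bootstrap).

        ``new_ids`` relabels the selected subjects so that a subject drawn
        twice becomes two distinct individuals.
        """
        if new_ids is None:
            new_ids = list(range(1, len(ids) + 1))
        parts = []
        covs = []
        grouped = dict(tuple(self.events.groupby("ID", sort=False)))
        for sid, nid in zip(ids, new_ids):
            g = grouped[sid].copy()
            g["ID"] = nid
            parts.append(g)
            if self.covariates is not None:
                row = self.covariates.loc[[sid]].copy()
                row.index = [nid]
                covs.append(row)
        events = pd.concat(parts, ignore_index=True)
        cov = pd.concat(covs) if covs else None
        if cov is not None:
            cov.index.name = "ID"
        return StudyDataset(events, cov)
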