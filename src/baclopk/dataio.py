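"""Readers/writers for the NONMEM-style event-table CSV dialect.

Columns: ID, TIME (h from the subject's first recorded dose), AMT (mg, empty
for observations), DV (ng/mL, empty for doses and BLQ rows), EVID (1 dose /
0 observation), MDV (1 when DV missing), BLQ (0/1), TAG (sampling-window
label, optional), plus per-subject covariate columns repeated on every row.

Formatting is canonical (%.10g, empty for missing), so a generated dataset
round-trips byte-for-byte through write -> read -> write.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .data import EVENT_COLUMNS, StudyDataset
from .engine import FitResult, OmegaMatrix, SigmaModel
from .model import ThetaVector


class DatasetError(ValueError):
    pass


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return ""
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    if isinstance(x, (float, np.floating)):
        return f"{float(x):.10g}"
    return str(x)


def dataset_to_frame(ds: StudyDataset) -> pd.DataFrame:
    """Merge the per-subject covariates into the event table."""
    df = ds.events.copy()
    if ds.covariates is not None:
        cov = ds.covariates
        for col in cov.columns:
            df[col] = df["ID"].map(cov[col])
    return df


def write_dataset(ds: StudyDataset, path) -> None:
    df = dataset_to_frame(ds)
    cols = list(df.columns)
    with open(path, "w", newline="") as fh:
        fh.write(",".join(cols) + "\n")
        for _, row in df.iterrows():
            fh.write(",".join(_fmt(row[c]) for c in cols) + "\n")


#: integer-typed columns in the dialect (and integer-valued covariates)
_INT_COLS = {"ID", "EVID", "MDV", "BLQ", "SEX", "GROUP", "NINTAKES"}


def read_dataset(path) -> StudyDataset:
    """Parse, validate (with row numbers) and split events from covariates."""
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"missing required columns: {missing}")
    for c in _INT_COLS & set(df.columns):
        df[c] = df[c].astype("int64", errors="ignore")

    for i, row in df.iterrows():
        line = i + 2   # header is line 1
        evid = row["EVID"]
        if evid not in (0, 1):
            raise DatasetError(f"row {line}: EVID must be 0 or 1")
        if evid == 1:
            if pd.isna(row["AMT"]) or row["AMT"] <= 0:
                raise DatasetError(f"row {line}: dose row needs AMT > 0")
            if pd.notna(row["DV"]):
                raise DatasetError(f"row {line}: dose row must not carry DV")
        else:
            if pd.notna(row["AMT"]):
                raise DatasetError(f"row {line}: observation row must not carry AMT")
            if row["BLQ"] == 1 and pd.notna(row["DV"]):
                raise DatasetError(f"row {line}: BLQ = 1 with DV present")
            if row["BLQ"] == 1 and row["MDV"] != 1:
                raise DatasetError(f"row {line}: BLQ = 1 requires MDV = 1")
            if row["MDV"] == 0 and pd.isna(row["DV"]):
                raise DatasetError(f"row {line}: MDV = 0 with DV missing")

    # per-subject monotone time and no observation before the first dose
    for sid, g in df.groupby("ID", sort=False):
        t = g["TIME"].to_numpy(float)
        if np.any(np.diff(t) < -1e-9):
            bad = g.index[np.where(np.diff(t) < -1e-9)[0][0] + 1] + 2
            raise DatasetError(f"row {bad}: TIME decreases within subject {sid}")
        doses = g[g["EVID"] == 1]
        if len(doses) == 0:
            raise DatasetError(f"subject {sid}: no dose records")
        first_dose = doses["TIME"].min()
        orphan = g[(g["EVID"] == 0) & (g["TIME"] < first_dose)]
        if len(orphan):
            raise DatasetError(
                f"row {orphan.index[0] + 2}: observation before first dose of subject {sid}")

    extra = [c for c in df.columns if c not in EVENT_COLUMNS + ["TAG"]]
    cov = None
    if extra:
        cov = df.groupby("ID", sort=False)[extra].first()
        # covariates must be constant within subject
        nun = df.groupby("ID", sort=False)[extra].nunique(dropna=False)
        if (nun > 1).any().any():
            col = nun.columns[(nun > 1).any()][0]
            raise DatasetError(f"covariate column {col} varies within a subject")
    events = df[[c for c in EVENT_COLUMNS + ["TAG"] if c in df.columns]].copy()
    return StudyDataset(events, cov)


# ---------------------------------------------------------------------------
# results serialisation
# ---------------------------------------------------------------------------

def fit_to_dict(fr: FitResult) -> dict:
    return {
        "theta": {"tvcl": fr.theta.tvcl, "tvv": fr.theta.tvv, "tvka": fr.theta.tvka,
                  "cov_coeffs": list(fr.theta.cov_coeffs)},
        "omega_sd": {"CL": fr.omega.sd[0], "V": fr.omega.sd[1], "KA": fr.omega.sd[2]},
        "sigma": fr.sigma.sigma,
        "ofv": fr.ofv,
        "shrinkage": fr.shrinkage,
        "rse": fr.rse,
        "converged": fr.converged,
        "message": fr.message,
        "n_obs": fr.n_obs,
        "n_subjects": fr.n_subjects,
        "n_blq_excluded": fr.n_blq_excluded,
        "effects": [e.label() for e in fr.effects],
    }


def write_fit(fr: FitResult, path) -> None:
    with open(path, "w") as fh:
        json.dump(fit_to_dict(fr), fh, indent=2)


def read_fit(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def fit_from_dict(d: dict) -> FitResult:
    theta = ThetaVector(d["theta"]["tvcl"], d["theta"]["tvv"], d["theta"]["tvka"],
                        tuple(d["theta"].get("cov_coeffs", ())))
    omega = OmegaMatrix.from_sd(d["omega_sd"]["CL"], d["omega_sd"]["V"], d["omega_sd"]["KA"])
    sigma = SigmaModel(d["sigma"])
    return FitResult(theta=theta, omega=omega, sigma=sigma, ofv=d["ofv"],
                     ebes=np.zeros((0, 3)), shrinkage=d.get("shrinkage", {}),
                     converged=d.get("converged", True), message=d.get("message", ""),
                     n_obs=d.get("n_obs", 0), n_subjects=d.get("n_subjects", 0),
                     n_blq_excluded=d.get("n_blq_excluded", 0),
                     rse=d.get("rse"))
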