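"""Helpers for constructing purpose-built synthetic datasets in tests."""

import numpy as np
import pandas as pd

import baclopk as b
from conftest import small_design


def noise_free_study(seed=7):
    """Study generated with zero between-subject and (essentially) zero
    residual variability: observed = typical prediction."""
    return b.simulate_study(design=small_design(), seed=seed,
                            omega=b.OmegaMatrix(0.0, 0.0, 0.0),
                            sigma=b.SigmaModel(1e-6))


def densify_observations(study, n_times=30, seed=0):
    """Same subjects, same true etas, but a dense observation grid on the
    sampling day — the 'rich sampling' counterpart of the sparse design."""
    rng = np.random.default_rng(seed)
    theta, _, sigma = b.reference_estimates()
    tvl = np.log([theta.tvcl, theta.tvv, theta.tvka])
    rows = []
    for sid, g in study.dataset.events.groupby("ID", sort=False):
        doses = g[g["EVID"] == 1]
        eta = np.asarray(study.truth["eta"][int(sid)])
        cl, v, ka = np.exp(tvl + eta)
        p = b.IndividualParams(cl=cl, v=v, ka=ka)
        devents = [b.DoseEvent(sid, t, a)
                   for t, a in zip(doses["TIME"], doses["AMT"])]
        times = np.linspace(72.2, 95.8, n_times)
        conc = b.conc_profile(p, devents, times)
        dv = conc * np.exp(rng.normal(0, sigma.sigma, n_times))
        for _, r in doses.iterrows():
            rows.append({"ID": sid, "TIME": r["TIME"], "AMT": r["AMT"],
                         "DV": np.nan, "EVID": 1, "MDV": 1, "BLQ": 0})
        for t, y in zip(times, dv):
            rows.append({"ID": sid, "TIME": t, "AMT": np.nan, "DV": y,
                         "EVID": 0, "MDV": 0, "BLQ": 0})
    events = pd.DataFrame(rows).sort_values(["ID", "TIME", "EVID"],
                                            kind="stable").reset_index(drop=True)
    return b.StudyDataset(events, study.dataset.covariates.copy())


def shared_schedule_dataset(n_sub=8, seed=3):
    """All subjects share one regimen, covariates and observation grid, so the
    population prediction is constant within any time bin."""
    rng = np.random.default_rng(seed)
    theta, omega, sigma = b.reference_estimates()
    doses = [b.DoseEvent(0, 8.0 * i, 60.0) for i in range(12)]
    times = np.array([72.5, 73.5, 74.5, 76.0, 78.5, 93.0])
    rows, cov_rows = [], []
    for sid in range(1, n_sub + 1):
        eta = rng.standard_normal(3) * omega.sd
        p = b.individual_from_typical(theta, eta=eta)
        conc = b.conc_profile(p, doses, times)
        dv = conc * np.exp(rng.normal(0, sigma.sigma, len(times)))
        for d in doses:
            rows.append({"ID": sid, "TIME": d.time, "AMT": d.amount,
                         "DV": np.nan, "EVID": 1, "MDV": 1, "BLQ": 0})
        for t, y in zip(times, dv):
            rows.append({"ID": sid, "TIME": t, "AMT": np.nan, "DV": y,
                         "EVID": 0, "MDV": 0, "BLQ": 0})
        cov_rows.append({"ID": sid, "GROUP": 2, "SEX": 0, "AGE": 46.0,
                         "WT": 75.0})
    events = pd.DataFrame(rows).sort_values(["ID", "TIME", "EVID"],
                                            kind="stable").reset_index(drop=True)
    cov = pd.DataFrame(cov_rows).set_index("ID")
    return b.StudyDataset(events, cov)
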