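"""Simulation-based model qualification.

* NPDE — normalized prediction distribution errors: each subject's observed
  vector and its K simulated counterparts are decorrelated with the inverse
  Cholesky factor of the empirical simulated covariance; the rank (mid-rank
  for ties) of each decorrelated observation among its simulations, clipped
  away from 0 and 1 by 1/(2K), is mapped through the standard-normal
  quantile.  Under the true model NPDE ~ N(0, 1).
* pcVPC — prediction-corrected visual predictive check: observations and
  simulations are rescaled by the bin-median population prediction before
  5/50/95th-percentile comparison, with simulation-based 95% bands.
* Nonparametric bootstrap — subjects resampled with replacement, stratified
  by dose group, refit per replicate; percentile confidence intervals.
* CPRED/IPRED tables — population (eta = 0) and individual (eta = eta_hat)
  predictions per observation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import NG_PER_MG_L, StudyDataset
from .engine import (FitResult, FitSettings, OmegaMatrix, PKAdapter, SigmaModel,
                     fit as engine_fit, map_etas)
from .model import ThetaVector

#: default pcVPC bin edges on time-after-dose (h), matching the sampling windows
DEFAULT_VPC_BINS = (0.0, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0)


@dataclass
class SimulationEnsemble:
    """K replicate concentration sets simulated at the design's observation rows."""

    sims_ng: np.ndarray          # (K, n_obs_rows) ng/mL
    cpred_ng: np.ndarray         # (n_obs_rows,) population prediction, ng/mL
    seed: int
    obs_mask: np.ndarray         # rows with a quantifiable observed value

    @property
    def K(self) -> int:
        return self.sims_ng.shape[0]


@dataclass
class NpdeResult:
    npde: np.ndarray             # per used observation
    pd_values: np.ndarray        # in (0, 1)
    subject_ids: np.ndarray
    times: np.ndarray
    marginal_fallback: bool = False


@dataclass
class VpcResult:
    table: pd.DataFrame          # per bin: observed & simulated percentile bands
    bins: tuple
    merged_bins: list


@dataclass
class BootstrapResult:
    estimates: pd.DataFrame      # one row per converged replicate
    ci: pd.DataFrame             # 2.5/97.5 percentile bounds per parameter
    n_requested: int
    n_converged: int
    unreliable: bool
    seed: int


def simulate_ensemble(fit_result: FitResult, dataset: StudyDataset, K: int,
                      seed: int) -> SimulationEnsemble:
    """Monte-Carlo replicates under the fitted model and the original design.

    For each replicate and subject: eta ~ N(0, Omega_hat), then the profile at
    the subject's own doses/times/covariates, then log-scale residuals
    eps ~ N(0, sigma_hat^2).
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    ad = PKAdapter(dataset, fit_result.effects)
    comp = ad.comp
    rng = np.random.default_rng(seed)
    w = fit_result.omega.sd
    predict_full = ad.predictor(fit_result.theta, full_rows=True)
    cpred_log = predict_full(np.zeros((ad.n_sub, 3)))
    sims = np.empty((K, comp.n_obs))
    for r in range(K):
        eta = rng.standard_normal((ad.n_sub, 3)) * w[None, :]
        logf = predict_full(eta)
        eps = rng.standard_normal(comp.n_obs) * fit_result.sigma.sigma
        sims[r] = np.exp(logf + eps) * NG_PER_MG_L
    return SimulationEnsemble(sims_ng=sims, cpred_ng=np.exp(cpred_log) * NG_PER_MG_L,
                              seed=int(seed), obs_mask=comp.fit_mask())


def npde(dataset: StudyDataset, ensemble: SimulationEnsemble) -> NpdeResult:
    """Decorrelated normalized prediction distribution errors."""
    comp = dataset.compile()
    mask = ensemble.obs_mask
    K = ensemble.K
    y = comp.dv_ng
    npde_vals = np.full(mask.sum(), np.nan)
    pd_vals = np.full(mask.sum(), np.nan)
    fallback = False
    out_pos = np.cumsum(mask) - 1     # position of each masked row in output
    for s in range(comp.n_sub):
        rows = np.where((comp.sub_idx == s) & mask)[0]
        if len(rows) == 0:
            continue
        obs = y[rows]
        sims = ensemble.sims_ng[:, rows]                  # (K, n_i)
        mu = sims.mean(axis=0)
        if len(rows) > 1:
            cov = np.cov(sims, rowvar=False)
            try:
                L = np.linalg.cholesky(cov)
                obs_d = np.linalg.solve(L, obs - mu)
                sims_d = np.linalg.solve(L, (sims - mu).T).T
            except np.linalg.LinAlgError:
                fallback = True
                sd = sims.std(axis=0, ddof=1)
                sd = np.where(sd > 0, sd, 1.0)
                obs_d = (obs - mu) / sd
                sims_d = (sims - mu) / sd
        else:
            sd = sims.std(axis=0, ddof=1)
            sd = np.where(sd > 0, sd, 1.0)
            obs_d = (obs - mu) / sd
            sims_d = (sims - mu) / sd
        # mid-rank of each decorrelated observation among its simulations
        below = (sims_d < obs_d[None, :]).sum(axis=0)
        ties = (sims_d == obs_d[None, :]).sum(axis=0)
        pd_i = (below + 0.5 * ties) / K
        pd_i = np.clip(pd_i, 1.0 / (2 * K), 1.0 - 1.0 / (2 * K))
        npde_vals[out_pos[rows]] = stats.norm.ppf(pd_i)
        pd_vals[out_pos[rows]] = pd_i
    return NpdeResult(
        npde=npde_vals, pd_values=pd_vals,
        subject_ids=comp.subject_ids[comp.sub_idx[mask]],
        times=comp.times[mask], marginal_fallback=fallback,
    )


def _assign_bins(tad: np.ndarray, edges: tuple, min_per_bin: int):
    """Bin indices on time-after-dose with small bins merged into neighbours."""
    edges = list(edges)
    if tad.max() > edges[-1]:
        edges[-1] = float(tad.max()) + 1e-9
    idx = np.clip(np.searchsorted(edges, tad, side="right") - 1, 0, len(edges) - 2)
    merged = []
    changed = True
    while changed and len(edges) > 2:
        changed = False
        counts = np.array([(idx == b).sum() for b in range(len(edges) - 1)])
        for b in np.argsort(counts):
            if counts[b] < min_per_bin:
                drop = b + 1 if b + 1 < len(edges) - 1 else b
                merged.append((edges[drop], counts[b]))
                del edges[drop]
                idx = np.clip(np.searchsorted(edges, tad, side="right") - 1,
                              0, len(edges) - 2)
                changed = True
                break
    return idx, tuple(edges), merged


def pc_vpc(dataset: StudyDataset, ensemble: SimulationEnsemble,
           bins: tuple = DEFAULT_VPC_BINS, min_per_bin: int = 5,
           prediction_corrected: bool = True) -> VpcResult:
    """Prediction-corrected VPC percentiles and simulation bands per time bin."""
    comp = dataset.compile()
    mask = ensemble.obs_mask
    tad = comp.tad[mask]
    obs = comp.dv_ng[mask]
    sims = ensemble.sims_ng[:, mask]
    pred = ensemble.cpred_ng[mask]
    idx, edges, merged = _assign_bins(tad, bins, min_per_bin)
    pct = (5.0, 50.0, 95.0)
    rows = []
    for b in range(len(edges) - 1):
        in_bin = idx == b
        if not in_bin.any():
            continue
        if prediction_corrected:
            corr = np.median(pred[in_bin]) / pred[in_bin]
        else:
            corr = np.ones(in_bin.sum())
        obs_b = obs[in_bin] * corr
        sims_b = sims[:, in_bin] * corr[None, :]
        obs_pct = np.percentile(obs_b, pct)
        sim_pct = np.percentile(sims_b, pct, axis=1)          # (3, K)
        lo = np.percentile(sim_pct, 2.5, axis=1)
        hi = np.percentile(sim_pct, 97.5, axis=1)
        med = np.percentile(sim_pct, 50.0, axis=1)
        rows.append({
            "bin_lo": edges[b], "bin_hi": edges[b + 1], "n": int(in_bin.sum()),
            "obs_p5": obs_pct[0], "obs_p50": obs_pct[1], "obs_p95": obs_pct[2],
            "sim_p5_lo": lo[0], "sim_p5_med": med[0], "sim_p5_hi": hi[0],
            "sim_p50_lo": lo[1], "sim_p50_med": med[1], "sim_p50_hi": hi[1],
            "sim_p95_lo": lo[2], "sim_p95_med": med[2], "sim_p95_hi": hi[2],
        })
    return VpcResult(table=pd.DataFrame(rows), bins=edges, merged_bins=merged)


def stratified_resample_ids(ids: np.ndarray, strata: np.ndarray,
                            rng: np.random.Generator) -> list:
    """One bootstrap draw of subject ids: with replacement, per stratum,
    preserving each stratum's size."""
    pick = []
    for s in np.unique(strata):
        pool = ids[strata == s]
        pick.extend(rng.choice(pool, size=len(pool), replace=True))
    return pick


def bootstrap_ci(dataset: StudyDataset, init_theta: ThetaVector,
                 init_omega: OmegaMatrix, init_sigma: SigmaModel,
                 B: int = 200, seed: int = 0, effects=(),
                 settings: FitSettings | None = None,
                 stratify_by: str = "GROUP") -> BootstrapResult:
    """Subject-level nonparametric bootstrap, stratified by dose group.

    Each replicate redraws subjects with replacement within each stratum
    (preserving the group sizes), refits, and contributes one estimate row;
    percentile CIs use converged replicates only.  More than 20%
    non-convergence flags the result unreliable.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed)
    ids = np.asarray(dataset.subject_ids())
    if dataset.covariates is not None and stratify_by in dataset.covariates.columns:
        strata = dataset.covariates.loc[ids, stratify_by].to_numpy()
    else:
        strata = np.zeros(len(ids))
    rows = []
    n_conv = 0
    for b in range(B):
        pick = stratified_resample_ids(ids, strata, rng)
        ds_b = dataset.subset_subjects(pick)
        try:
            fr = engine_fit(ds_b, init_theta, init_omega, init_sigma,
                            effects=effects, settings=settings)
        except Exception:
            continue
        if not fr.converged:
            continue
        n_conv += 1
        rows.append({
            "replicate": b,
            "tvcl": fr.theta.tvcl, "tvv": fr.theta.tvv, "tvka": fr.theta.tvka,
            "w_cl": fr.omega.sd[0], "w_v": fr.omega.sd[1], "w_ka": fr.omega.sd[2],
            "sigma": fr.sigma.sigma, "ofv": fr.ofv,
        })
    est = pd.DataFrame(rows)
    params = ["tvcl", "tvv", "tvka", "w_cl", "w_v", "w_ka", "sigma"]
    ci_rows = []
    for p in params:
        if len(est):
            lo, hi = np.percentile(est[p], [2.5, 97.5])
        else:
            lo = hi = np.nan
        ci_rows.append({"parameter": p, "lo": lo, "hi": hi})
    return BootstrapResult(
        estimates=est, ci=pd.DataFrame(ci_rows).set_index("parameter"),
        n_requested=B, n_converged=n_conv,
        unreliable=(n_conv < 0.8 * B), seed=int(seed),
    )


def prediction_tables(fit_result: FitResult, dataset: StudyDataset) -> pd.DataFrame:
    """Tidy per-observation table with DV, CPRED (eta = 0) and IPRED (eta = eta_hat)."""
    ad = PKAdapter(dataset, fit_result.effects)
    comp = ad.comp
    predict_full = ad.predictor(fit_result.theta, full_rows=True)
    cpred = np.exp(predict_full(np.zeros((ad.n_sub, 3)))) * NG_PER_MG_L
    ebes = fit_result.ebes
    if ebes is None or len(ebes) != ad.n_sub:
        ebes = map_etas(dataset, fit_result.theta, fit_result.omega,
                        fit_result.sigma, fit_result.effects)
    ipred = np.exp(predict_full(ebes)) * NG_PER_MG_L
    return pd.DataFrame({
        "ID": comp.subject_ids[comp.sub_idx],
        "TIME": comp.times,
        "TAD": comp.tad,
        "DV": comp.dv_ng,
        "BLQ": comp.blq.astype(int),
        "CPRED": cpred,
        "IPRED": ipred,
    })


# ---------------------------------------------------------------------------
# optional plots
# ---------------------------------------------------------------------------

def plot_vpc(vpc: VpcResult, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = vpc.table
    mid = 0.5 * (t["bin_lo"] + t["bin_hi"])
    fig, ax = plt.subplots(figsize=(7, 5))
    for p, c in (("p5", "tab:blue"), ("p50", "tab:red"), ("p95", "tab:blue")):
        ax.fill_between(mid, t[f"sim_{p}_lo"], t[f"sim_{p}_hi"], alpha=0.25, color=c)
        ax.plot(mid, t[f"obs_{p}"], "o-", color=c, label=f"observed {p}")
    ax.set_xlabel("time after dose (h)")
    ax.set_ylabel("prediction-corrected concentration (ng/mL)")
    ax.legend()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_npde(res: NpdeResult, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    axes[0].scatter(res.times, res.npde, s=10)
    axes[0].axhline(0.0, color="k", lw=0.8)
    axes[0].set_xlabel("time (h)")
    axes[0].set_ylabel("NPDE")
    axes[1].hist(res.npde[np.isfinite(res.npde)], bins=20, density=True)
    x = np.linspace(-4, 4, 200)
    axes[1].plot(x, stats.norm.pdf(x), "r-")
    axes[1].set_xlabel("NPDE")
    fig.savefig(path, dpi=120)
    plt.close(fig)
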