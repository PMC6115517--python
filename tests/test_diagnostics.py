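"""Simulation diagnostics: NPDE, pcVPC, bootstrap, prediction tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import baclopk as b
from baclopk.diagnostics import (bootstrap_ci, npde, pc_vpc, prediction_tables,
                                 simulate_ensemble, stratified_resample_ids)
from baclopk.engine import FitResult, OmegaMatrix, SigmaModel
from baclopk.model import ThetaVector


def truth_fit(dataset, omega=None, sigma=None):
    """FitResult carrying the generating parameters (self-simulation oracle)."""
    theta, om, sg = b.reference_estimates()
    om = omega or om
    sg = sigma or sg
    n = dataset.n_subjects
    return FitResult(theta=theta, omega=om, sigma=sg, ofv=0.0,
                     ebes=np.zeros((n, 3)), shrinkage={}, converged=True,
                     message="", n_obs=dataset.n_observations, n_subjects=n,
                     n_blq_excluded=0)


class TestEnsemble:
    def test_degenerate_variances_reproduce_population_prediction(self, small_study):
        fr = truth_fit(small_study.dataset, omega=OmegaMatrix(0.0, 0.0, 0.0),
                       sigma=SigmaModel(1e-12))
        ens = simulate_ensemble(fr, small_study.dataset, K=3, seed=0)
        for r in range(3):
            np.testing.assert_allclose(ens.sims_ng[r], ens.cpred_ng, rtol=1e-6)

    def test_same_seed_bitwise_identical(self, small_study):
        fr = truth_fit(small_study.dataset)
        e1 = simulate_ensemble(fr, small_study.dataset, K=20, seed=5)
        e2 = simulate_ensemble(fr, small_study.dataset, K=20, seed=5)
        assert np.array_equal(e1.sims_ng, e2.sims_ng)

    def test_k_below_two_rejected(self, small_study):
        with pytest.raises(ValueError):
            simulate_ensemble(truth_fit(small_study.dataset),
                              small_study.dataset, K=1, seed=0)

    def test_log_variance_matches_delta_method(self, small_study):
        """Empirical variance of simulated log-concentrations at each row
        approximates J Omega J' + sigma^2 (first-order propagation)."""
        from baclopk.engine import PKAdapter
        fr = truth_fit(small_study.dataset)
        ens = simulate_ensemble(fr, small_study.dataset, K=1000, seed=2)
        ad = PKAdapter(small_study.dataset)
        _, J = ad.predictor_with_jac(fr.theta)(np.zeros((ad.n_sub, 3)))
        w2 = fr.omega.diag
        pred_var = (J ** 2 @ w2) + fr.sigma.sigma ** 2
        emp_var = np.log(ens.sims_ng[:, ens.obs_mask]).var(axis=0, ddof=1)
        # median ratio over rows: Monte-Carlo + linearisation tolerance
        ratio = np.median(emp_var / pred_var[: len(emp_var)])
        assert 0.85 < ratio < 1.15


class TestNpde:
    def test_marginal_rank_oracle_single_obs_subjects(self):
        """With one observation per subject the decorrelation is a plain
        standardisation, so NPDE must equal the brute-force rank construction."""
        rng = np.random.default_rng(3)
        n, K = 12, 40
        rows = []
        for sid in range(1, n + 1):
            rows.append({"ID": sid, "TIME": 0.0, "AMT": 100.0, "DV": np.nan,
                         "EVID": 1, "MDV": 1, "BLQ": 0})
            rows.append({"ID": sid, "TIME": 2.0, "AMT": np.nan,
                         "DV": float(rng.uniform(50, 150)), "EVID": 0,
                         "MDV": 0, "BLQ": 0})
        ds = b.StudyDataset(pd.DataFrame(rows))
        comp = ds.compile()
        sims = rng.uniform(40, 160, size=(K, comp.n_obs))
        from baclopk.diagnostics import SimulationEnsemble
        ens = SimulationEnsemble(sims_ng=sims, cpred_ng=np.full(comp.n_obs, 100.0),
                                 seed=0, obs_mask=comp.fit_mask())
        res = npde(ds, ens)
        obs = comp.dv_ng
        for i in range(comp.n_obs):
            mu, sd = sims[:, i].mean(), sims[:, i].std(ddof=1)
            z_obs = (obs[i] - mu) / sd
            z_sim = (sims[:, i] - mu) / sd
            pd_i = ((z_sim < z_obs).sum() + 0.5 * (z_sim == z_obs).sum()) / K
            pd_i = np.clip(pd_i, 1 / (2 * K), 1 - 1 / (2 * K))
            assert res.npde[i] == pytest.approx(stats.norm.ppf(pd_i), abs=1e-10)

    def test_observation_at_simulated_median_maps_near_zero(self):
        rows = [{"ID": 1, "TIME": 0.0, "AMT": 100.0, "DV": np.nan,
                 "EVID": 1, "MDV": 1, "BLQ": 0},
                {"ID": 1, "TIME": 2.0, "AMT": np.nan, "DV": 100.0,
                 "EVID": 0, "MDV": 0, "BLQ": 0}]
        ds = b.StudyDataset(pd.DataFrame(rows))
        comp = ds.compile()
        K = 101
        sims = np.linspace(50.0, 150.0, K)[:, None]   # median exactly 100
        from baclopk.diagnostics import SimulationEnsemble
        ens = SimulationEnsemble(sims_ng=sims, cpred_ng=np.array([100.0]),
                                 seed=0, obs_mask=comp.fit_mask())
        res = npde(ds, ens)
        assert abs(res.npde[0]) < 0.05

    def test_self_simulated_study_close_to_standard_normal(self, small_study):
        fr = truth_fit(small_study.dataset)
        ens = simulate_ensemble(fr, small_study.dataset, K=300, seed=8)
        res = npde(small_study.dataset, ens)
        vals = res.npde[np.isfinite(res.npde)]
        assert stats.kstest(vals, "norm").pvalue > 0.01
        assert abs(vals.mean()) < 0.2
        assert 0.7 < vals.var(ddof=1) < 1.3


class TestPcVpc:
    def test_percentile_ordering_in_every_bin(self, study1):
        fr = truth_fit(study1.dataset)
        ens = simulate_ensemble(fr, study1.dataset, K=100, seed=4)
        res = pc_vpc(study1.dataset, ens)
        t = res.table
        assert (t["obs_p5"] <= t["obs_p50"]).all()
        assert (t["obs_p50"] <= t["obs_p95"]).all()
        assert (t["sim_p5_med"] <= t["sim_p50_med"]).all()
        assert (t["sim_p50_med"] <= t["sim_p95_med"]).all()

    def test_bins_below_minimum_are_merged(self, study1):
        fr = truth_fit(study1.dataset)
        ens = simulate_ensemble(fr, study1.dataset, K=50, seed=4)
        res = pc_vpc(study1.dataset, ens, min_per_bin=5)
        assert (res.table["n"] >= 5).all()

    def test_correction_is_identity_under_shared_schedule(self):
        """All subjects on one regimen and one observation grid: the bin
        population prediction is constant, so prediction correction must not
        change the percentiles."""
        from tests_support import shared_schedule_dataset
        ds = shared_schedule_dataset()
        fr = truth_fit(ds)
        ens = simulate_ensemble(fr, ds, K=60, seed=6)
        # one shared time-after-dose per bin, so PRED is constant within bins
        bins = (0.0, 1.0, 2.0, 3.0, 4.5, 5.5, 24.0)
        on = pc_vpc(ds, ens, bins=bins, prediction_corrected=True)
        off = pc_vpc(ds, ens, bins=bins, prediction_corrected=False)
        pd.testing.assert_frame_equal(on.table, off.table)

    def test_self_simulated_percentiles_inside_bands(self, study1):
        fr = truth_fit(study1.dataset)
        ens = simulate_ensemble(fr, study1.dataset, K=200, seed=12)
        res = pc_vpc(study1.dataset, ens)
        t = res.table
        inside = 0
        for p in ("p5", "p50", "p95"):
            inside += (t[f"obs_{p}"].between(t[f"sim_{p}_lo"], t[f"sim_{p}_hi"])).sum()
        assert inside >= 0.9 * 3 * len(t)


class TestBootstrap:
    def test_resampling_preserves_stratum_sizes(self):
        ids = np.arange(1, 58)
        strata = np.repeat([1, 2, 3, 4], [10, 15, 16, 16])
        rng = np.random.default_rng(0)
        pick = stratified_resample_ids(ids, strata, rng)
        assert len(pick) == 57
        drawn_groups = pd.Series([strata[list(ids).index(p)] for p in pick])
        assert drawn_groups.value_counts().sort_index().tolist() == [10, 15, 16, 16]

    def test_percentile_ci_of_mean_matches_normal_theory(self):
        """Resampling machinery against the analytic CI for a sample mean
        (single stratum, B = 1000)."""
        rng = np.random.default_rng(1)
        x = rng.normal(10.0, 2.0, 80)
        ids = np.arange(80)
        strata = np.zeros(80)
        boots = []
        rng2 = np.random.default_rng(2)
        for _ in range(1000):
            pick = stratified_resample_ids(ids, strata, rng2)
            boots.append(x[pick].mean())
        lo, hi = np.percentile(boots, [2.5, 97.5])
        se = x.std(ddof=1) / np.sqrt(len(x))
        assert lo == pytest.approx(x.mean() - 1.96 * se, abs=0.25 * se)
        assert hi == pytest.approx(x.mean() + 1.96 * se, abs=0.25 * se)

    def test_cloned_subject_collapses_ci(self, fast_settings):
        """57 copies of one subject leave nothing to resample: every replicate
        refits identical data, so the CI width is zero."""
        study = b.simulate_study(seed=3)
        ds = study.dataset
        first = ds.subject_ids()[0]
        clones = ds.subset_subjects([first] * 8)
        theta, omega, sigma = b.reference_estimates()
        res = bootstrap_ci(clones, theta, omega, sigma, B=4, seed=0,
                           settings=fast_settings)
        width = res.ci.loc["tvcl", "hi"] - res.ci.loc["tvcl", "lo"]
        assert width == pytest.approx(0.0, abs=1e-9)

    def test_fixed_seed_reproduces_estimates(self, small_study, small_fit,
                                             fast_settings):
        r1 = bootstrap_ci(small_study.dataset, small_fit.theta, small_fit.omega,
                          small_fit.sigma, B=3, seed=11, settings=fast_settings)
        r2 = bootstrap_ci(small_study.dataset, small_fit.theta, small_fit.omega,
                          small_fit.sigma, B=3, seed=11, settings=fast_settings)
        pd.testing.assert_frame_equal(r1.estimates, r2.estimates)


class TestPredictionTables:
    def test_zero_omega_equates_cpred_ipred(self, small_study):
        fr = truth_fit(small_study.dataset, omega=OmegaMatrix(0.0, 0.0, 0.0))
        t = prediction_tables(fr, small_study.dataset)
        np.testing.assert_allclose(t["CPRED"], t["IPRED"], rtol=1e-9)

    def test_ipred_residuals_smaller_than_cpred(self, study1, fit1):
        t = prediction_tables(fit1, study1.dataset)
        ok = t["DV"].notna()
        r_ip = np.log(t.loc[ok, "DV"]) - np.log(t.loc[ok, "IPRED"])
        r_cp = np.log(t.loc[ok, "DV"]) - np.log(t.loc[ok, "CPRED"])
        assert r_ip.var() < r_cp.var()

    def test_log_log_calibration_slope(self, study1, fit1):
        t = prediction_tables(fit1, study1.dataset)
        ok = t["DV"].notna()
        x = np.log(t.loc[ok, "IPRED"])
        y = np.log(t.loc[ok, "DV"])
        slope = np.polyfit(x, y, 1)[0]
        assert 0.95 <= slope <= 1.05
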