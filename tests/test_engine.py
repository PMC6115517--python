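"""Estimation engine: exact Gaussian oracles, recovery, shrinkage, SEs.

The Laplace/FOCE objective is exact for any model linear in eta with additive
Gaussian error, so closed-form marginal likelihoods provide independent
oracles for both the conditional modes and the OFV.
"""

import numpy as np
import pytest

import baclopk as b
from baclopk.engine import (FitSettings, OmegaMatrix, SigmaModel, eta_shrinkage,
                            map_etas_generic, ofv_generic, standard_errors)
from baclopk.model import ThetaVector


def linear_problem(n_sub=6, n_per=4, omega2=0.09, sigma=0.3, seed=0):
    """y_ij = eta_i + eps_ij: the simplest eta-linear Gaussian model."""
    rng = np.random.default_rng(seed)
    sub_idx = np.repeat(np.arange(n_sub), n_per)
    eta_true = rng.normal(0, np.sqrt(omega2), n_sub)
    y = eta_true[sub_idx] + rng.normal(0, sigma, n_sub * n_per)

    def predict(eta):
        return eta[..., sub_idx, 0]

    return y, sub_idx, predict, n_sub


def exact_neg2_loglik(y, sub_idx, n_sub, omega2, sigma):
    """-2 log of the exact marginal Gaussian likelihood, per-subject compound
    symmetry covariance sigma^2 I + omega^2 J."""
    total = 0.0
    for s in range(n_sub):
        yi = y[sub_idx == s]
        n = len(yi)
        cov = sigma ** 2 * np.eye(n) + omega2 * np.ones((n, n))
        sign, logdet = np.linalg.slogdet(cov)
        total += n * np.log(2 * np.pi) + logdet + yi @ np.linalg.solve(cov, yi)
    return total


class TestGenericOracles:
    def test_ofv_matches_exact_gaussian_marginal(self):
        y, sub_idx, predict, n_sub = linear_problem()
        got = ofv_generic(predict, y, sub_idx, n_sub, np.array([0.09]), 0.3)
        want = exact_neg2_loglik(y, sub_idx, n_sub, 0.09, 0.3)
        assert got == pytest.approx(want, rel=1e-6)

    def test_map_eta_matches_ridge_posterior_mode(self):
        """For y = eta + eps the conditional mode has the conjugate closed
        form n*ybar*omega^2 / (sigma^2 + n*omega^2)."""
        y, sub_idx, predict, n_sub = linear_problem(omega2=0.25, sigma=0.4)
        eta, _, _, _ = map_etas_generic(predict, y, sub_idx, n_sub,
                                        np.array([0.25]), 0.4)
        for s in range(n_sub):
            yi = y[sub_idx == s]
            want = len(yi) * yi.mean() * 0.25 / (0.4 ** 2 + len(yi) * 0.25)
            assert eta[s, 0] == pytest.approx(want, abs=1e-8)

    def test_zero_omega_pins_etas_at_zero(self):
        y, sub_idx, predict, n_sub = linear_problem()
        eta, _, _, _ = map_etas_generic(predict, y, sub_idx, n_sub,
                                        np.array([0.0]), 0.3)
        assert np.all(np.abs(eta) < 1e-6)

    def test_ofv_additive_over_subjects(self):
        y, sub_idx, predict, n_sub = linear_problem()
        single = ofv_generic(predict, y, sub_idx, n_sub, np.array([0.09]), 0.3)
        y2 = np.concatenate([y, y])
        sub2 = np.concatenate([sub_idx, sub_idx + n_sub])

        def predict2(eta):
            return eta[..., sub2, 0]

        double = ofv_generic(predict2, y2, sub2, 2 * n_sub, np.array([0.09]), 0.3)
        assert double == pytest.approx(2 * single, rel=1e-12)


class TestPKEtas:
    def test_rich_data_recovers_simulated_eta(self):
        """50 samples and tiny residual noise pin the conditional mode to the
        eta used to simulate the subject."""
        import pandas as pd
        rng = np.random.default_rng(5)
        theta, omega, _ = b.reference_estimates()
        eta_true = np.array([0.25, -0.15, 0.30])
        p = b.individual_from_typical(theta, eta=eta_true)
        doses = [b.DoseEvent(1, 8.0 * i, 60.0) for i in range(12)]
        times = np.linspace(72.5, 96.0, 50)
        conc = b.conc_profile(p, doses, times)
        sigma = 0.001
        dv = conc * np.exp(rng.normal(0, sigma, len(times)))
        rows = [{"ID": 1, "TIME": d.time, "AMT": d.amount, "DV": np.nan,
                 "EVID": 1, "MDV": 1, "BLQ": 0} for d in doses]
        rows += [{"ID": 1, "TIME": t, "AMT": np.nan, "DV": y, "EVID": 0,
                  "MDV": 0, "BLQ": 0} for t, y in zip(times, dv)]
        frame = pd.DataFrame(rows).sort_values(["ID", "TIME"], kind="stable")
        ds = b.StudyDataset(frame.reset_index(drop=True))
        eta = b.map_etas(ds, theta, omega, b.SigmaModel(sigma))
        np.testing.assert_allclose(eta[0], eta_true, rtol=0.01)


class TestFit:
    def test_degenerate_noise_recovers_theta(self, fast_settings):
        """With no between-subject or residual variability the fixed effects
        are recovered essentially exactly."""
        from tests_support import noise_free_study
        study = noise_free_study()
        theta_t, _, _ = b.reference_estimates()
        fr = b.fit(study.dataset, b.ThetaVector(9.0, 60.0, 1.2),
                   OmegaMatrix(0.0, 0.0, 0.0), SigmaModel(1e-6),
                   fix_omega=True, fix_sigma=True, settings=fast_settings)
        assert fr.theta.tvcl == pytest.approx(theta_t.tvcl, rel=1e-3)
        assert fr.theta.tvv == pytest.approx(theta_t.tvv, rel=1e-3)
        assert fr.theta.tvka == pytest.approx(theta_t.tvka, rel=1e-3)

    def test_fit_is_deterministic(self, small_study, init_model, fast_settings):
        f1 = b.fit(small_study.dataset, *init_model, settings=fast_settings)
        f2 = b.fit(small_study.dataset, *init_model, settings=fast_settings)
        assert f1.ofv == f2.ofv
        assert f1.theta == f2.theta

    def test_trace_is_monotone_nonincreasing(self, fit1):
        trace = np.asarray(fit1.trace)
        runs = np.split(trace, np.where(np.diff(trace) > 1e-6)[0] + 1)
        # within each L-BFGS-B run the accepted iterates decrease
        for run in runs:
            if len(run) > 1:
                assert np.all(np.diff(run) <= 1e-6)

    def test_invariant_to_subject_relabeling(self, small_study, init_model,
                                             fast_settings):
        ds = small_study.dataset
        ids = ds.subject_ids()
        shuffled = list(reversed(ids))
        ds2 = ds.subset_subjects(shuffled, new_ids=list(range(101, 101 + len(ids))))
        f1 = b.fit(ds, *init_model, settings=fast_settings)
        f2 = b.fit(ds2, *init_model, settings=fast_settings)
        assert f2.theta.tvcl == pytest.approx(f1.theta.tvcl, rel=1e-4)
        assert f2.ofv == pytest.approx(f1.ofv, abs=1e-3)


class TestShrinkage:
    def test_all_zero_ebes_give_total_shrinkage(self):
        fr = _dummy_fit(ebes=np.zeros((10, 3)))
        s = eta_shrinkage(fr)
        assert all(v == 1.0 for v in s.values())

    def test_rich_sampling_shrinks_less_than_sparse(self):
        """Same subjects, same true etas: denser sampling carries more
        individual information, hence smaller eta-shrinkage for every random
        effect (averaged over paired replicate studies; unclipped values so
        near-zero shrinkage still compares strictly)."""
        from tests_support import densify_observations
        theta, omega, sigma = b.reference_estimates()
        sparse, rich = [], []
        for seed in range(1, 7):
            study = b.simulate_study(seed=seed)
            sparse.append(_raw_shrinkage(study.dataset, theta, omega, sigma))
            rich.append(_raw_shrinkage(densify_observations(study, 30, 9),
                                       theta, omega, sigma))
        assert np.all(np.mean(rich, axis=0) < np.mean(sparse, axis=0))

    def test_variance_form_is_larger(self):
        rng = np.random.default_rng(0)
        fr = _dummy_fit(ebes=rng.normal(0, 0.1, (30, 3)))
        sd = eta_shrinkage(fr, "sd")
        var = eta_shrinkage(fr, "var")
        for k in sd:
            assert var[k] > sd[k]


class TestStandardErrors:
    def test_rse_reasonable_at_study_scale(self, fit1, study1):
        """The sparse 57-subject design supports a low-single-digit RSE for
        typical clearance (the study reports 3%)."""
        res = standard_errors(fit1, study1.dataset)
        assert res.positive_definite
        assert 0.5 < res.rse["tvcl"] < 8.0
        assert res.rse["tvka"] > res.rse["tvcl"]

    def test_rse_invariant_to_concentration_units(self, small_study, init_model,
                                                  fast_settings):
        """Rescaling DV (assay unit change) shifts V and CL estimates but
        leaves every relative standard error unchanged."""
        ds = small_study.dataset
        ev2 = ds.events.copy()
        ev2["DV"] = ev2["DV"] * 10.0
        ds2 = b.StudyDataset(ev2, ds.covariates.copy())
        f1 = b.fit(ds, *init_model, settings=fast_settings)
        f2 = b.fit(ds2, *init_model, settings=fast_settings)
        r1 = standard_errors(f1, ds, settings=fast_settings)
        r2 = standard_errors(f2, ds2, settings=fast_settings)
        for k in ("tvcl", "tvv", "tvka", "sigma"):
            assert r2.rse[k] == pytest.approx(r1.rse[k], rel=0.05)


def _raw_shrinkage(dataset, theta, omega, sigma):
    ebes = b.map_etas(dataset, theta, omega, sigma)
    return 1.0 - np.std(ebes, axis=0, ddof=1) / omega.sd


def _dummy_fit(ebes, omega=None):
    from baclopk.engine import FitResult
    return FitResult(
        theta=ThetaVector(11.6, 72.8, 1.64),
        omega=omega or OmegaMatrix.from_sd(0.21, 0.22, 0.44),
        sigma=SigmaModel(0.24), ofv=0.0, ebes=ebes, shrinkage={},
        converged=True, message="", n_obs=len(ebes), n_subjects=len(ebes),
        n_blq_excluded=0)
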