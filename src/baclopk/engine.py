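"""Nonlinear mixed-effects estimation for the one-compartment oral model.

The residual model is "exponential": y = f(eta) * exp(eps).  On the log scale
this is additive Gaussian with a variance that no longer depends on eta, so
the FOCE "interaction" term is handled exactly rather than by linearisation.
The marginal likelihood per subject is approximated by a Laplace expansion
around the conditional mode (empirical Bayes estimate) of eta, with a
Gauss-Newton Hessian — the classical FOCE-I objective for this error model:

    OFV_i = n_i log(2 pi sigma^2) + SSR_i / sigma^2
            + eta_i' Omega^-1 eta_i + log det(I + Omega J_i'J_i / sigma^2)

where J_i is the Jacobian of the log-predictions with respect to eta at the
mode.  The additive constant convention (the ``n log 2 pi`` term is included)
is fixed so that OFV *differences* are implementation-independent; the
absolute OFV differs from NONMEM's by a data-dependent constant (the Jacobian
of the log transform), which cancels in every likelihood-ratio comparison.

BLQ observations are excluded from the likelihood (M1) and counted in the
result.  Omega is diagonal (no CL-V correlation).  Outer optimisation is
quasi-Newton (L-BFGS-B) on log-transformed parameters; inner eta optimisation
is damped Gauss-Newton started at eta = 0 (or the previous outer iterate's
mode, which changes nothing at convergence).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import optimize

from .data import StudyDataset
from .model import ThetaVector, concentration_and_k_gradients, concentration_mgL

_LOG2PI = np.log(2.0 * np.pi)
_ZERO_OMEGA_PREC = 1e12   # penalty precision standing in for omega^2 = 0


@dataclass(frozen=True)
class OmegaMatrix:
    """Diagonal between-subject variances on the log scale (CL, V, Ka order)."""

    w2_cl: float
    w2_v: float
    w2_ka: float

    def __post_init__(self):
        if min(self.w2_cl, self.w2_v, self.w2_ka) < 0:
            raise ValueError("omega^2 must be non-negative")

    @property
    def diag(self) -> np.ndarray:
        return np.array([self.w2_cl, self.w2_v, self.w2_ka])

    @property
    def sd(self) -> np.ndarray:
        """Reported omega values (SD scale, e.g. 0.21)."""
        return np.sqrt(self.diag)

    @staticmethod
    def from_sd(w_cl: float, w_v: float, w_ka: float) -> "OmegaMatrix":
        return OmegaMatrix(w_cl ** 2, w_v ** 2, w_ka ** 2)


@dataclass(frozen=True)
class SigmaModel:
    """Residual SD on the log-concentration scale (approximate CV)."""

    sigma: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class FitSettings:
    outer_tol: float = 1e-9        # L-BFGS-B ftol (relative objective change)
    outer_gtol: float = 1e-6
    outer_maxiter: int = 300
    outer_eps: float = 1e-6        # finite-difference step of the outer gradient
    outer_restarts: int = 1        # polishing restarts (reset Hessian approx.)
    inner_tol: float = 1e-11       # absolute change of the per-subject objective
    inner_gtol: float = 1e-7       # sup-norm of the per-subject eta gradient
    inner_maxiter: int = 100
    fd_step: float = 1e-5          # central-difference step for d(log f)/d(eta)


@dataclass
class FitResult:
    theta: ThetaVector
    omega: OmegaMatrix
    sigma: SigmaModel
    ofv: float
    ebes: np.ndarray                  # (n_sub, 3) conditional modes
    shrinkage: dict
    converged: bool
    message: str
    n_obs: int
    n_subjects: int
    n_blq_excluded: int
    effects: tuple = ()
    rse: dict | None = None
    n_ofv_evals: int = 0
    trace: list = field(default_factory=list)   # accepted outer OFV values


# ---------------------------------------------------------------------------
# generic Laplace core (model-agnostic; the PK model is one adapter)
# ---------------------------------------------------------------------------

def map_etas_generic(predict_log: Callable[[np.ndarray], np.ndarray],
                     log_y: np.ndarray, sub_idx: np.ndarray, n_sub: int,
                     w2: np.ndarray, sigma: float,
                     eta0: np.ndarray | None = None,
                     settings: FitSettings | None = None,
                     predict_log_jac: Callable | None = None):
    """Batched damped Gauss-Newton for the conditional modes of eta.

    ``predict_log`` maps eta (n_sub, q) to per-observation log predictions;
    ``predict_log_jac``, when available, returns (log predictions, analytic
    (n_obs, q) Jacobian) in one call — otherwise a central-difference
    Jacobian is used.  Returns (eta_hat, per-subject SSR, per-subject J'J,
    per-subject objective values).
    """
    st = settings or FitSettings()
    q = len(w2)
    prec = np.where(w2 > 0, 1.0 / np.where(w2 > 0, w2, 1.0), _ZERO_OMEGA_PREC)
    eta = np.zeros((n_sub, q)) if eta0 is None else np.array(eta0, float)
    inv_s2 = 1.0 / sigma ** 2
    h = st.fd_step
    shifts = np.concatenate([np.eye(q) * h, -np.eye(q) * h])   # (2q, q)

    def g_from_logf(e, logf):
        r = log_y - logf
        ssr = np.bincount(sub_idx, weights=r * r, minlength=n_sub)
        return ssr * inv_s2 + (e * e * prec).sum(axis=1), r, ssr

    def eval_with_jac(e):
        if predict_log_jac is not None:
            logf, J = predict_log_jac(e)
        else:
            logf = predict_log(e)
            stacked = e[None, :, :] + shifts[:, None, :]       # (2q, n_sub, q)
            out = predict_log(stacked)                         # (2q, n_obs)
            J = (out[:q] - out[q:]).T / (2 * h)
        g, r, ssr = g_from_logf(e, logf)
        return g, r, ssr, J

    def jtj_of(J):
        JtJ = np.empty((n_sub, q, q))
        for a in range(q):
            for b in range(a, q):
                val = np.bincount(sub_idx, weights=J[:, a] * J[:, b], minlength=n_sub)
                JtJ[:, a, b] = val
                JtJ[:, b, a] = val
        return JtJ

    g, r, ssr, J = eval_with_jac(eta)
    active = np.ones(n_sub, bool)
    for _ in range(st.inner_maxiter):
        JtJ = jtj_of(J)
        A = JtJ * inv_s2 + np.eye(q)[None, :, :] * prec[None, :]
        Jtr = np.stack(
            [np.bincount(sub_idx, weights=J[:, k] * r, minlength=n_sub) for k in range(q)],
            axis=1,
        )
        grad = -Jtr * inv_s2 + eta * prec        # gradient of g/2
        gnorm = np.abs(grad).max(axis=1)
        active &= gnorm > st.inner_gtol
        if not active.any():
            break
        step = np.linalg.solve(A, grad[..., None])[..., 0]
        # damped per-subject line search; a non-worsening trial is accepted
        alpha = np.ones(n_sub)
        new_eta = eta.copy()
        new_g = g.copy()
        trying = active.copy()
        slack = 1e-12 * (1.0 + np.abs(g))
        for _half in range(12):
            trial = eta - (alpha * trying)[:, None] * step
            logf_t = predict_log(trial)
            g_t, _, _ = g_from_logf(trial, logf_t)
            accept = trying & (g_t <= g + slack)
            new_eta[accept] = trial[accept]
            new_g[accept] = g_t[accept]
            trying &= ~accept
            if not trying.any():
                break
            alpha = np.where(trying, alpha * 0.5, alpha)
        active &= ~trying          # line search exhausted: no further progress
        eta = new_eta
        g, r, ssr, J = eval_with_jac(eta)
        if not active.any():
            break
    return eta, ssr, jtj_of(J), g


def _assemble_ofv(eta, ssr, JtJ, n_i, w2, sigma):
    """OFV from the inner-loop pieces (shared by the numpy and compiled paths)."""
    q = len(w2)
    inv_s2 = 1.0 / sigma ** 2
    prec = np.where(w2 > 0, 1.0 / np.where(w2 > 0, w2, 1.0), _ZERO_OMEGA_PREC)
    # log det(I + Omega J'J / sigma^2): rows with omega^2 = 0 contribute 0
    with np.errstate(invalid="ignore", over="ignore"):
        M = np.eye(q)[None, :, :] + (w2[None, :, None] * JtJ) * inv_s2
        sign, logdet = np.linalg.slogdet(M)
    if not np.all(sign > 0):
        raise np.linalg.LinAlgError("non-positive Laplace determinant")
    pen = (eta * eta * prec).sum(axis=1)
    ofv_i = n_i * (_LOG2PI + 2.0 * np.log(sigma)) + ssr * inv_s2 + pen + logdet
    return float(ofv_i.sum())


def ofv_generic(predict_log, log_y, sub_idx, n_sub, w2, sigma,
                eta0=None, settings=None, return_etas=False,
                predict_log_jac=None):
    """Laplace/FOCE-I approximate -2 log marginal likelihood (model-agnostic)."""
    eta, ssr, JtJ, _ = map_etas_generic(
        predict_log, log_y, sub_idx, n_sub, w2, sigma, eta0, settings,
        predict_log_jac=predict_log_jac)
    n_i = np.bincount(sub_idx, minlength=n_sub).astype(float)
    total = _assemble_ofv(eta, ssr, JtJ, n_i, w2, sigma)
    if return_etas:
        return total, eta
    return total


def _pk_inner(ad: "PKAdapter", theta: ThetaVector, w2: np.ndarray, sigma: float,
              eta0, st: FitSettings):
    """Inner modes via the compiled per-subject loop (numpy fallback if
    numba is unavailable)."""
    from ._speedups import HAVE_NUMBA, pk_inner_gn
    if not HAVE_NUMBA:
        return map_etas_generic(ad.predictor(theta), ad.log_y, ad.sub_idx,
                                ad.n_sub, w2, sigma, eta0, st,
                                predict_log_jac=ad.predictor_with_jac(theta))
    e0 = np.zeros((ad.n_sub, 3)) if eta0 is None else np.array(eta0, float)
    return pk_inner_gn(ad.amt, ad.dt, ad.log_y, ad.obs_ptr,
                       ad.log_params(theta), np.asarray(w2, float),
                       float(sigma), e0, st.inner_gtol, st.inner_maxiter)


def _pk_ofv(ad: "PKAdapter", theta: ThetaVector, w2: np.ndarray, sigma: float,
            eta0, st: FitSettings, return_etas: bool = False):
    eta, ssr, JtJ, _ = _pk_inner(ad, theta, w2, sigma, eta0, st)
    n_i = np.diff(ad.obs_ptr).astype(float)
    total = _assemble_ofv(eta, ssr, JtJ, n_i, w2, sigma)
    if return_etas:
        return total, eta
    return total


# ---------------------------------------------------------------------------
# PK adapter
# ---------------------------------------------------------------------------

class PKAdapter:
    """Vectorised log-prediction function for a compiled dataset + covariate effects."""

    def __init__(self, dataset: StudyDataset, effects: Sequence = ()):
        comp = dataset.compile()
        mask = comp.fit_mask()
        if not mask.any():
            raise ValueError("dataset has no quantifiable observations")
        self.comp = comp
        self.mask = mask
        self.sub_idx = comp.sub_idx[mask]
        self.log_y = comp.log_y[mask]
        self.dt = comp.dt[mask]
        self.amt = comp.amt[mask]
        self.n_sub = comp.n_sub
        self.n_blq = int(comp.blq.sum())
        # compile() emits observations contiguously per subject, which the
        # compiled inner loop relies on
        if np.any(np.diff(self.sub_idx) < 0):
            raise AssertionError("observation rows not grouped by subject")
        counts = np.bincount(self.sub_idx, minlength=self.n_sub)
        self.obs_ptr = np.zeros(self.n_sub + 1, dtype=np.int64)
        self.obs_ptr[1:] = np.cumsum(counts)
        self.effects = tuple(effects)
        # per-effect design matrices (n_sub, df) against the covariate table
        self.designs = []
        pos = {"CL": 0, "V": 1, "KA": 2}
        for eff in self.effects:
            if dataset.covariates is None or eff.covariate not in dataset.covariates.columns:
                raise ValueError(f"missing covariate '{eff.covariate}' for effect on {eff.parameter}")
            X = eff.design_matrix(dataset.covariates[eff.covariate].to_numpy())
            self.designs.append((pos[eff.parameter], X))
        self.n_coeffs = sum(eff.df for eff in self.effects)

    def log_params(self, theta: ThetaVector) -> np.ndarray:
        """(n_sub, 3) typical log parameters after covariate effects."""
        lp = np.tile(np.log([theta.tvcl, theta.tvv, theta.tvka]), (self.n_sub, 1))
        i = 0
        for (pidx, X), eff in zip(self.designs, self.effects):
            beta = np.asarray(theta.cov_coeffs[i:i + eff.df], float)
            i += eff.df
            lp[:, pidx] += X @ beta
        return lp

    def predictor(self, theta: ThetaVector,
                  full_rows: bool = False) -> Callable[[np.ndarray], np.ndarray]:
        lp0 = self.log_params(theta)
        if full_rows:
            sub_idx, dt, amt = self.comp.sub_idx, self.comp.dt, self.comp.amt
        else:
            sub_idx, dt, amt = self.sub_idx, self.dt, self.amt

        def predict_log(eta: np.ndarray) -> np.ndarray:
            # eta: (n_sub, 3) or batched (..., n_sub, 3)
            p = np.exp(lp0 + eta)[..., sub_idx, :]
            c = concentration_mgL(amt, dt, p[..., 0], p[..., 1], p[..., 2])
            return np.log(np.maximum(c, 1e-300))

        return predict_log

    def predictor_with_jac(self, theta: ThetaVector) -> Callable:
        """Log predictions plus analytic d(log f)/d(eta) in one call."""
        lp0 = self.log_params(theta)
        sub_idx, dt, amt = self.sub_idx, self.dt, self.amt

        def predict(eta: np.ndarray):
            p = np.exp(lp0 + eta)[sub_idx]
            cl, v, ka = p[:, 0], p[:, 1], p[:, 2]
            C, dCdk, dCdka = concentration_and_k_gradients(amt, dt, cl, v, ka)
            C = np.maximum(C, 1e-300)
            k = cl / v
            j_cl = k * dCdk / C
            J = np.stack([j_cl, -1.0 - j_cl, ka * dCdka / C], axis=1)
            return np.log(C), J

        return predict


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def map_etas(dataset: StudyDataset, theta: ThetaVector, omega: OmegaMatrix,
             sigma: SigmaModel, effects: Sequence = (),
             settings: FitSettings | None = None) -> np.ndarray:
    """Empirical Bayes estimates (conditional modes) of eta, (n_sub, 3)."""
    ad = PKAdapter(dataset, effects)
    eta, _, _, _ = _pk_inner(ad, theta, omega.diag, sigma.sigma, None,
                             settings or FitSettings())
    return eta


def ofv(dataset: StudyDataset, theta: ThetaVector, omega: OmegaMatrix,
        sigma: SigmaModel, effects: Sequence = (),
        settings: FitSettings | None = None) -> float:
    """FOCE-I objective function value for the dataset under the model."""
    ad = PKAdapter(dataset, effects)
    return _pk_ofv(ad, theta, omega.diag, sigma.sigma, None,
                   settings or FitSettings())


def _pack(theta: ThetaVector, omega: OmegaMatrix, sigma: SigmaModel,
          fix_omega: bool, fix_sigma: bool) -> np.ndarray:
    parts = [np.log([theta.tvcl, theta.tvv, theta.tvka]),
             np.asarray(theta.cov_coeffs, float)]
    if not fix_omega:
        parts.append(np.log(np.maximum(omega.diag, 1e-12)))
    if not fix_sigma:
        parts.append(np.log([sigma.sigma ** 2]))
    return np.concatenate(parts)


def _unpack(psi: np.ndarray, n_coeffs: int, omega0: OmegaMatrix, sigma0: SigmaModel,
            fix_omega: bool, fix_sigma: bool):
    # clip to keep extreme line-search probes finite (objective guards on 1e12)
    psi = np.clip(psi, -300.0, 300.0)
    tv = np.exp(psi[:3])
    coeffs = tuple(psi[3:3 + n_coeffs])
    i = 3 + n_coeffs
    if fix_omega:
        omega = omega0
    else:
        w2 = np.exp(psi[i:i + 3]); i += 3
        omega = OmegaMatrix(*w2)
    sigma = sigma0 if fix_sigma else SigmaModel(float(np.sqrt(np.exp(psi[i]))))
    theta = ThetaVector(tv[0], tv[1], tv[2], coeffs)
    return theta, omega, sigma


def fit(dataset: StudyDataset, init_theta: ThetaVector, init_omega: OmegaMatrix,
        init_sigma: SigmaModel, effects: Sequence = (),
        settings: FitSettings | None = None,
        fix_omega: bool = False, fix_sigma: bool = False) -> FitResult:
    """Maximum (approximate) marginal likelihood fit.

    Positivity of tvcl/tvv/tvka, omega^2 and sigma^2 is enforced by
    log-parameterisation; covariate coefficients are unconstrained.
    Deterministic given dataset + init + settings.
    """
    st = settings or FitSettings()
    ad = PKAdapter(dataset, effects)
    if len(init_theta.cov_coeffs) != ad.n_coeffs:
        init_theta = replace(init_theta, cov_coeffs=tuple(
            list(init_theta.cov_coeffs) + [0.0] * (ad.n_coeffs - len(init_theta.cov_coeffs))))
    psi0 = _pack(init_theta, init_omega, init_sigma, fix_omega, fix_sigma)
    n_eval = [0]
    # warm-start cache for the inner modes; safe because the inner solver
    # iterates to a gradient tolerance, making the mode start-independent
    eta_cache = {"eta": None}

    def objective(psi):
        n_eval[0] += 1
        theta, omega, sigma = _unpack(psi, ad.n_coeffs, init_omega, init_sigma,
                                      fix_omega, fix_sigma)
        try:
            val, eta = _pk_ofv(ad, theta, omega.diag, sigma.sigma,
                               eta_cache["eta"], st, return_etas=True)
        except (np.linalg.LinAlgError, FloatingPointError, OverflowError):
            return 1e12
        if not np.isfinite(val):
            return 1e12
        eta_cache["eta"] = eta
        return val

    trace: list[float] = []

    def cb(psi):
        trace.append(objective(psi))

    # quasi-Newton with a polishing restart: restarting resets the Hessian
    # approximation, which reliably escapes the flat ridges of the Laplace
    # objective near convergence.  The finite-difference step is kept well
    # above the (tiny) numerical noise of the inner optimisation.
    opts = {"ftol": st.outer_tol, "gtol": st.outer_gtol,
            "maxiter": st.outer_maxiter, "eps": st.outer_eps}
    res = optimize.minimize(objective, psi0, method="L-BFGS-B",
                            options=opts, callback=cb)
    success = bool(res.success)
    for _restart in range(st.outer_restarts):
        r = optimize.minimize(objective, res.x, method="L-BFGS-B",
                              options=opts, callback=cb)
        success = success or bool(r.success)
        if r.fun <= res.fun:
            res = r
    theta, omega, sigma = _unpack(res.x, ad.n_coeffs, init_omega, init_sigma,
                                  fix_omega, fix_sigma)
    final_ofv, ebes = _pk_ofv(ad, theta, omega.diag, sigma.sigma, None, st,
                              return_etas=True)
    fr = FitResult(
        theta=theta, omega=omega, sigma=sigma, ofv=float(final_ofv),
        ebes=ebes, shrinkage={}, converged=success,
        message=str(res.message), n_obs=len(ad.log_y), n_subjects=ad.n_sub,
        n_blq_excluded=ad.n_blq, effects=tuple(effects),
        n_ofv_evals=n_eval[0], trace=trace,
    )
    fr.shrinkage = eta_shrinkage(fr)
    return fr


def eta_shrinkage(fit_result: FitResult, method: str = "sd") -> dict:
    """Eta-shrinkage per random effect: 1 - SD(eta_hat)/omega (clipped to [0,1]).

    ``method='var'`` uses the variance-ratio form 1 - Var(eta_hat)/omega^2.
    Undefined effects (omega = 0) are reported as NaN.
    """
    names = ["CL", "V", "KA"]
    w = fit_result.omega.sd
    out = {}
    for k, name in enumerate(names):
        if w[k] <= 0:
            out[name] = float("nan")
            continue
        s = np.std(fit_result.ebes[:, k], ddof=1)
        if method == "sd":
            val = 1.0 - s / w[k]
        elif method == "var":
            val = 1.0 - (s / w[k]) ** 2
        else:
            raise ValueError("method must be 'sd' or 'var'")
        out[name] = float(np.clip(val, 0.0, 1.0))
    return out


@dataclass
class StandardErrorResult:
    rse: dict | None           # RSE% per reported parameter
    se_psi: np.ndarray | None  # SE on the internal log scale
    cov: np.ndarray | None
    positive_definite: bool
    eigenvalues: np.ndarray
    condition_number: float
    param_names: list


def standard_errors(fit_result: FitResult, dataset: StudyDataset,
                    settings: FitSettings | None = None,
                    rel_step: float = 1e-3) -> StandardErrorResult:
    """RSE% from the inverse finite-difference Hessian of OFV/2 at the optimum.

    The Hessian is taken with respect to the log-transformed parameters, so
    sqrt of the covariance diagonal is directly the relative SE of each
    natural parameter (delta method); for omega and sigma (reported on the SD
    scale) the log-variance SE is halved.  A non-positive-definite Hessian is
    reported via per-parameter eigen-diagnostics rather than silent output.
    """
    st = settings or FitSettings()
    ad = PKAdapter(dataset, fit_result.effects)
    psi = _pack(fit_result.theta, fit_result.omega, fit_result.sigma, False, False)
    names = (["tvcl", "tvv", "tvka"]
             + [f"beta{j}" for j in range(ad.n_coeffs)]
             + ["w2_cl", "w2_v", "w2_ka", "s2"])

    def f(p):
        theta, omega, sigma = _unpack(p, ad.n_coeffs, fit_result.omega,
                                      fit_result.sigma, False, False)
        return 0.5 * _pk_ofv(ad, theta, omega.diag, sigma.sigma, None, st)

    n = len(psi)
    h = rel_step * (1.0 + np.abs(psi))
    H = np.empty((n, n))
    f0 = f(psi)
    for i in range(n):
        ei = np.zeros(n); ei[i] = h[i]
        H[i, i] = (f(psi + ei) - 2 * f0 + f(psi - ei)) / h[i] ** 2
    for i in range(n):
        for j in range(i + 1, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(psi + ei + ej) - f(psi + ei - ej)
                - f(psi - ei + ej) + f(psi - ei - ej)
            ) / (4 * h[i] * h[j])
    H = 0.5 * (H + H.T)
    eig = np.linalg.eigvalsh(H)
    pd_ok = bool(eig.min() > 0)
    if not pd_ok:
        return StandardErrorResult(None, None, None, False, eig,
                                   float(np.abs(eig).max() / max(np.abs(eig).min(), 1e-300)),
                                   names)
    cov = np.linalg.inv(H)
    se_psi = np.sqrt(np.diag(cov))
    rse = {"tvcl": 100.0 * se_psi[0], "tvv": 100.0 * se_psi[1], "tvka": 100.0 * se_psi[2]}
    i = 3
    for j, beta in enumerate(fit_result.theta.cov_coeffs):
        rse[f"beta{j}"] = float(100.0 * se_psi[i + j] / abs(beta)) if beta != 0 else float("inf")
    i += ad.n_coeffs
    for k, nm in enumerate(["w_cl", "w_v", "w_ka"]):
        rse[nm] = 100.0 * se_psi[i + k] / 2.0
    rse["sigma"] = 100.0 * se_psi[i + 3] / 2.0
    return StandardErrorResult(rse, se_psi, cov, True, eig,
                               float(eig.max() / eig.min()), names)
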