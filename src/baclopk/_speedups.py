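"""Numba-compiled inner loop for the PK likelihood.

Same algorithm as the generic numpy path in :mod:`baclopk.engine`
(damped Gauss-Newton to the conditional mode with the analytic Jacobian of
log-concentration); specialised to the one-compartment model so the whole
per-subject iteration runs without interpreter overhead.  The numpy path
remains the reference; equivalence is asserted in the test suite.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
    HAVE_NUMBA = True
except ImportError:          # pragma: no cover - numba is a hard speedup dep
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco(a[0]) if a and callable(a[0]) else deco


_KA_K_TOL = 1e-8
_ZERO_OMEGA_PREC = 1e12


@njit(cache=True)
def _conc_grad_subject(amt, dt, lo, hi, cl, v, ka, C, dCdk, dCdka):
    """Concentration + dC/dk + dC/dKa for one subject's observation rows."""
    k = cl / v
    for r in range(lo, hi):
        c = 0.0
        gk = 0.0
        gka = 0.0
        for d in range(amt.shape[1]):
            a = amt[r, d]
            t = dt[r, d]
            if a <= 0.0 or t <= 0.0:
                continue
            B = a / v
            D = ka - k
            E1 = np.exp(-k * t)
            if abs(D) <= _KA_K_TOL * k:
                c += B * k * t * E1
                gk += -0.5 * B * k * t * t * E1
                gka += B * t * E1 * (1.0 - 0.5 * k * t)
            else:
                E2 = np.exp(-ka * t)
                dE = E1 - E2
                c += B * ka * dE / D
                gk += B * ka / D * (dE / D - t * E1)
                gka += B / D * (dE * (1.0 - ka / D) + ka * t * E2)
        C[r] = c if c > 1e-300 else 1e-300
        dCdk[r] = gk
        dCdka[r] = gka


@njit(cache=True)
def _conc_subject(amt, dt, lo, hi, cl, v, ka, C):
    k = cl / v
    for r in range(lo, hi):
        c = 0.0
        for d in range(amt.shape[1]):
            a = amt[r, d]
            t = dt[r, d]
            if a <= 0.0 or t <= 0.0:
                continue
            D = ka - k
            E1 = np.exp(-k * t)
            if abs(D) <= _KA_K_TOL * k:
                c += a / v * k * t * E1
            else:
                c += a / v * ka * (E1 - np.exp(-ka * t)) / D
        C[r] = c if c > 1e-300 else 1e-300


@njit(cache=True)
def _solve3(A, b, out):
    """3x3 linear solve by Gaussian elimination with partial pivoting."""
    M = np.empty((3, 4))
    for i in range(3):
        for j in range(3):
            M[i, j] = A[i, j]
        M[i, 3] = b[i]
    for col in range(3):
        piv = col
        best = abs(M[col, col])
        for i in range(col + 1, 3):
            if abs(M[i, col]) > best:
                best = abs(M[i, col])
                piv = i
        if piv != col:
            for j in range(4):
                tmp = M[col, j]
                M[col, j] = M[piv, j]
                M[piv, j] = tmp
        p = M[col, col]
        if p == 0.0:
            p = 1e-300
        for i in range(col + 1, 3):
            f = M[i, col] / p
            for j in range(col, 4):
                M[i, j] -= f * M[col, j]
    for i in range(2, -1, -1):
        s = M[i, 3]
        for j in range(i + 1, 3):
            s -= M[i, j] * out[j]
        out[i] = s / (M[i, i] if M[i, i] != 0.0 else 1e-300)


@njit(cache=True)
def pk_inner_gn(amt, dt, log_y, obs_ptr, lp0, w2, sigma, eta0,
                gtol, maxiter):
    """Per-subject damped Gauss-Newton to the conditional mode of eta.

    Returns (eta, ssr, JtJ, g): the modes, residual sums of squares, J'J at
    the mode and the penalised objective values, per subject.
    """
    n_sub = lp0.shape[0]
    n_obs = log_y.shape[0]
    inv_s2 = 1.0 / (sigma * sigma)
    prec = np.empty(3)
    for kk in range(3):
        prec[kk] = 1.0 / w2[kk] if w2[kk] > 0.0 else _ZERO_OMEGA_PREC

    eta = eta0.copy()
    ssr_out = np.zeros(n_sub)
    jtj_out = np.zeros((n_sub, 3, 3))
    g_out = np.zeros(n_sub)

    C = np.empty(n_obs)
    dCdk = np.empty(n_obs)
    dCdka = np.empty(n_obs)
    J = np.empty((n_obs, 3))
    grad = np.empty(3)
    step = np.empty(3)
    A = np.empty((3, 3))
    e_try = np.empty(3)

    for s in range(n_sub):
        lo = obs_ptr[s]
        hi = obs_ptr[s + 1]
        e = eta[s]

        # current objective
        cl = np.exp(lp0[s, 0] + e[0])
        v = np.exp(lp0[s, 1] + e[1])
        ka = np.exp(lp0[s, 2] + e[2])
        _conc_subject(amt, dt, lo, hi, cl, v, ka, C)
        g_cur = 0.0
        for r in range(lo, hi):
            res = log_y[r] - np.log(C[r])
            g_cur += res * res
        g_cur = g_cur * inv_s2 + (e[0] * e[0] * prec[0]
                                  + e[1] * e[1] * prec[1]
                                  + e[2] * e[2] * prec[2])

        for _it in range(maxiter):
            cl = np.exp(lp0[s, 0] + e[0])
            v = np.exp(lp0[s, 1] + e[1])
            ka = np.exp(lp0[s, 2] + e[2])
            k = cl / v
            _conc_grad_subject(amt, dt, lo, hi, cl, v, ka, C, dCdk, dCdka)
            for i in range(3):
                grad[i] = e[i] * prec[i]
                for j in range(3):
                    A[i, j] = prec[i] if i == j else 0.0
            ssr = 0.0
            for r in range(lo, hi):
                jcl = k * dCdk[r] / C[r]
                J[r, 0] = jcl
                J[r, 1] = -1.0 - jcl
                J[r, 2] = ka * dCdka[r] / C[r]
                res = log_y[r] - np.log(C[r])
                ssr += res * res
                for i in range(3):
                    grad[i] -= J[r, i] * res * inv_s2
                    for j in range(3):
                        A[i, j] += J[r, i] * J[r, j] * inv_s2
            gmax = max(abs(grad[0]), abs(grad[1]), abs(grad[2]))
            if gmax <= gtol:
                break
            _solve3(A, grad, step)
            # backtracking line search accepting any non-worsening trial
            alpha = 1.0
            accepted = False
            slack = 1e-12 * (1.0 + abs(g_cur))
            for _h in range(12):
                for i in range(3):
                    e_try[i] = e[i] - alpha * step[i]
                cl_t = np.exp(lp0[s, 0] + e_try[0])
                v_t = np.exp(lp0[s, 1] + e_try[1])
                ka_t = np.exp(lp0[s, 2] + e_try[2])
                _conc_subject(amt, dt, lo, hi, cl_t, v_t, ka_t, C)
                g_t = 0.0
                for r in range(lo, hi):
                    res = log_y[r] - np.log(C[r])
                    g_t += res * res
                g_t = g_t * inv_s2 + (e_try[0] * e_try[0] * prec[0]
                                      + e_try[1] * e_try[1] * prec[1]
                                      + e_try[2] * e_try[2] * prec[2])
                if g_t <= g_cur + slack:
                    for i in range(3):
                        e[i] = e_try[i]
                    g_cur = g_t
                    accepted = True
                    break
                alpha *= 0.5
            if not accepted:
                break

        # final Jacobian pieces at the mode
        cl = np.exp(lp0[s, 0] + e[0])
        v = np.exp(lp0[s, 1] + e[1])
        ka = np.exp(lp0[s, 2] + e[2])
        k = cl / v
        _conc_grad_subject(amt, dt, lo, hi, cl, v, ka, C, dCdk, dCdka)
        ssr = 0.0
        for i in range(3):
            for j in range(3):
                jtj_out[s, i, j] = 0.0
        for r in range(lo, hi):
            jcl = k * dCdk[r] / C[r]
            J[r, 0] = jcl
            J[r, 1] = -1.0 - jcl
            J[r, 2] = ka * dCdka[r] / C[r]
            res = log_y[r] - np.log(C[r])
            ssr += res * res
            for i in range(3):
                for j in range(3):
                    jtj_out[s, i, j] += J[r, i] * J[r, j]
        ssr_out[s] = ssr
        g_out[s] = ssr * inv_s2 + (e[0] * e[0] * prec[0]
                                   + e[1] * e[1] * prec[1]
                                   + e[2] * e[2] * prec[2])

    return eta, ssr_out, jtj_out, g_out
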