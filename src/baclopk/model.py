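"""One-compartment oral-absorption structural model.

Concentration after a single oral dose D with first-order absorption (Ka) and
first-order elimination (k = CL/V):

    C(t) = D*Ka / (V*(Ka - k)) * (exp(-k*t) - exp(-Ka*t)),   t >= 0

with the removable singularity at Ka = k handled by the limit
C(t) = D*k*t/V * exp(-k*t).  Multiple-dose profiles are plain superposition
(linear kinetics).  Parameters are apparent oral quantities (CL/F, Vd/F);
bioavailability never appears explicitly.

Individual parameters follow the usual log-normal random-effect model
``p_i = typical(covariates) * exp(eta)`` with covariate effects applied
multiplicatively to the typical value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .data import NG_PER_MG_L

#: relative |Ka - k| band within which the limiting form is used
_KA_K_TOL = 1e-8


@dataclass(frozen=True)
class ThetaVector:
    """Fixed effects: typical CL/F (L/h), Vd/F (L), Ka (1/h) + covariate coefficients.

    ``cov_coeffs`` holds the coefficients of the active covariate effects in
    declaration order (power exponents, or log category multipliers — see
    :mod:`baclopk.covariates`).
    """

    tvcl: float
    tvv: float
    tvka: float
    cov_coeffs: tuple = ()

    def __post_init__(self):
        if not (self.tvcl > 0 and self.tvv > 0 and self.tvka > 0):
            raise ValueError("typical parameters must be positive")


@dataclass(frozen=True)
class IndividualParams:
    """Per-subject parameters with the random effects that produced them."""

    cl: float
    v: float
    ka: float
    eta: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if not (self.cl > 0 and self.v > 0 and self.ka > 0):
            raise ValueError("individual parameters must be positive")


@dataclass(frozen=True)
class DoseEvent:
    subject_id: object
    time: float
    amount: float

    def __post_init__(self):
        if self.amount <= 0:
            raise ValueError("dose amount must be positive")
        if self.time < 0:
            raise ValueError("dose time must be non-negative")


@dataclass(frozen=True)
class Observation:
    subject_id: object
    time: float
    conc: float | None          # ng/mL; None when BLQ
    blq_flag: bool = False
    window_tag: str = ""


def concentration_mgL(amt, dt, cl, v, ka):
    """Vectorised superposition core, in mg and L.

    ``amt``/``dt`` have a trailing dose axis; ``cl``/``v``/``ka`` broadcast
    against the leading axes.  Padding and not-yet-given doses are encoded as
    ``amt == 0``.
    """
    amt = np.asarray(amt, float)
    dt = np.asarray(dt, float)
    cl = np.asarray(cl, float)[..., None]
    v = np.asarray(v, float)[..., None]
    ka = np.asarray(ka, float)[..., None]
    k = cl / v
    active = (amt > 0) & (dt > 0)
    dtc = np.where(active, dt, 0.0)
    diff = ka - k
    near = np.abs(diff) <= _KA_K_TOL * k
    safe = np.where(near, 1.0, diff)
    with np.errstate(over="ignore", invalid="ignore"):
        ek = np.exp(-k * dtc)
        general = amt * ka / (v * safe) * (ek - np.exp(-ka * dtc))
        limit = amt * k * dtc * ek / v
    terms = np.where(near, limit, general)
    terms = np.where(active, terms, 0.0)
    return terms.sum(axis=-1)


def concentration_and_k_gradients(amt, dt, cl, v, ka):
    """Superposition sum C plus its summed partials dC/dk and dC/dKa.

    Used for the analytic Jacobian of log C with respect to the random
    effects: with k = CL/V one has

        dlogC/d(eta_CL) =  k * (dC/dk) / C
        dlogC/d(eta_V)  = -1 - k * (dC/dk) / C      (exact for the sum)
        dlogC/d(eta_Ka) = ka * (dC/dKa) / C

    The removable Ka = k singularity uses the series-expansion limits.
    """
    amt = np.asarray(amt, float)
    dt = np.asarray(dt, float)
    cl = np.asarray(cl, float)[..., None]
    v = np.asarray(v, float)[..., None]
    ka = np.asarray(ka, float)[..., None]
    k = cl / v
    active = (amt > 0) & (dt > 0)
    t = np.where(active, dt, 0.0)
    B = amt / v
    D = ka - k
    near = np.abs(D) <= _KA_K_TOL * k
    safe = np.where(near, 1.0, D)
    E1 = np.exp(-k * t)
    E2 = np.exp(-ka * t)
    dE = E1 - E2
    T_g = B * ka * dE / safe
    dTdk_g = B * ka / safe * (dE / safe - t * E1)
    dTdka_g = B / safe * (dE * (1.0 - ka / safe) + ka * t * E2)
    T_n = B * k * t * E1
    dTdk_n = -0.5 * B * k * t * t * E1
    dTdka_n = B * t * E1 * (1.0 - 0.5 * k * t)
    T = np.where(near, T_n, T_g)
    dTdk = np.where(near, dTdk_n, dTdk_g)
    dTdka = np.where(near, dTdka_n, dTdka_g)
    T = np.where(active, T, 0.0)
    dTdk = np.where(active, dTdk, 0.0)
    dTdka = np.where(active, dTdka, 0.0)
    return T.sum(axis=-1), dTdk.sum(axis=-1), dTdka.sum(axis=-1)


def conc_single_dose(p: IndividualParams, dose: float, t) -> np.ndarray | float:
    """Concentration (ng/mL) at time(s) ``t`` hours after a single oral dose (mg)."""
    if dose <= 0:
        raise ValueError("dose must be positive")
    t_arr = np.asarray(t, float)
    if np.any(t_arr < 0):
        raise ValueError("time after dose must be non-negative")
    c = concentration_mgL(
        np.full(t_arr.shape + (1,), float(dose)),
        t_arr[..., None],
        np.broadcast_to(p.cl, t_arr.shape),
        np.broadcast_to(p.v, t_arr.shape),
        np.broadcast_to(p.ka, t_arr.shape),
    )
    out = c * NG_PER_MG_L
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def conc_profile(p: IndividualParams, doses: Sequence[DoseEvent], times) -> np.ndarray:
    """Concentration (ng/mL) at each time under a multiple-dose history."""
    times = np.asarray(times, float)
    if len(doses) == 0:
        warnings.warn("empty dose list: returning an all-zero profile")
        return np.zeros_like(times)
    dtimes = np.asarray([d.time for d in doses], float)
    if np.any(np.diff(dtimes) < 0):
        raise ValueError("doses must be sorted by time")
    damts = np.asarray([d.amount for d in doses], float)
    delta = times[:, None] - dtimes[None, :]
    active = delta > 0
    amt = np.where(active, damts[None, :], 0.0)
    dt = np.where(active, delta, 0.0)
    c = concentration_mgL(
        amt, dt,
        np.broadcast_to(p.cl, times.shape),
        np.broadcast_to(p.v, times.shape),
        np.broadcast_to(p.ka, times.shape),
    )
    return c * NG_PER_MG_L


def individual_from_typical(theta: ThetaVector, covariates: Mapping | None = None,
                            eta=(0.0, 0.0, 0.0), effects: Iterable = ()) -> IndividualParams:
    """Apply covariate effects multiplicatively, then the random effects.

    ``effects`` is an iterable of :class:`baclopk.covariates.CovariateEffect`;
    their coefficients are consumed from ``theta.cov_coeffs`` in order.
    """
    log_tv = np.log([theta.tvcl, theta.tvv, theta.tvka])
    pos = {"CL": 0, "V": 1, "KA": 2}
    i = 0
    for eff in effects:
        coeffs = np.asarray(theta.cov_coeffs[i:i + eff.df], float)
        i += eff.df
        if covariates is None or eff.covariate not in covariates:
            raise ValueError(f"missing covariate '{eff.covariate}' for effect on {eff.parameter}")
        x = eff.design_row(covariates[eff.covariate])
        log_tv[pos[eff.parameter]] += float(np.dot(x, coeffs))
    eta = np.asarray(eta, float)
    p = np.exp(log_tv + eta)
    return IndividualParams(cl=p[0], v=p[1], ka=p[2], eta=tuple(eta))


def half_life(cl: float, v: float) -> float:
    """Elimination half-life (h) = ln2 * V / CL."""
    if cl <= 0 or v <= 0:
        raise ValueError("cl and v must be positive")
    return math.log(2.0) * v / cl
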