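"""Two-slope spline submodel for eGFR trajectories.

The mean eGFR of subject *i* at year *t* is a linear spline with a single
change-point ``t*`` separating an acute from a chronic phase,

    mu(t) = (alpha0(x) + a_i) + (beta0(x) + b_i) * A(t) + (gamma0(x) + g_i) * C(t)
            + tau0(x) * trt * C(t) / (1 - w) + zeta0(x) * trt * (t - C(t) / (1 - w)),

where ``A(t) = t - d(t) * (t - t*)`` and ``C(t) = d(t) * (t - t*)`` are the
acute and chronic time bases (``d = 1(t > t*)``), ``w = t*/T*``, and
``tau0 = w * zeta0 + (1 - w) * nu0`` is the total treatment effect over the
horizon ``T*`` (a weighted average of the acute effect ``zeta0`` and the
chronic effect ``nu0``).  Random effects ``(a_i, b_i, g_i) ~ N(0, sigma2 * Sigma)``
and residuals ``N(0, sigma2)``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TimeBasis",
    "EffectWeights",
    "time_basis",
    "effect_weight",
    "nu_from_tau",
    "tau_from_nu",
    "mean_trajectory",
    "longitudinal_loglik",
    "marginal_subject_loglik",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class TimeBasis:
    """Acute/chronic decomposition of visit times: ``acute + chronic = yrs``."""

    acute: np.ndarray
    chronic: np.ndarray
    d: np.ndarray


@dataclass(frozen=True)
class EffectWeights:
    t_star: float
    T_star: float

    @property
    def w(self) -> float:
        return self.t_star / self.T_star


def time_basis(yrs, t_star: float) -> TimeBasis:
    """Split visit times into the acute and chronic spline bases.

    The chronic indicator uses the strict convention ``d = 1(yrs > t*)``;
    at ``yrs == t*`` both conventions give identical bases.
    """
    yrs = np.asarray(yrs, dtype=float)
    if np.any(yrs < 0):
        raise ValueError("visit times must be non-negative")
    d = (yrs > t_star).astype(float)
    chronic = d * (yrs - t_star)
    acute = yrs - chronic
    return TimeBasis(acute=acute, chronic=chronic, d=d)


def effect_weight(t_star: float, T_star: float) -> EffectWeights:
    if not 0 < t_star < T_star:
        raise ValueError("need 0 < t_star < T_star")
    return EffectWeights(t_star=t_star, T_star=T_star)


def nu_from_tau(tau0, zeta0, w):
    """Chronic treatment effect implied by a total effect: ``nu0 = (tau0 - w*zeta0)/(1-w)``."""
    if np.any(np.asarray(w) >= 1) or np.any(np.asarray(w) <= 0):
        raise ValueError("w must lie in (0, 1)")
    return (tau0 - w * zeta0) / (1.0 - w)


def tau_from_nu(nu0, zeta0, w):
    """Total treatment effect from acute/chronic effects: ``tau0 = w*zeta0 + (1-w)*nu0``."""
    return w * zeta0 + (1.0 - w) * nu0


def mean_trajectory(yrs, trt, *, alpha0, beta0, gamma0, tau0, zeta0,
                    weights: EffectWeights, re=(0.0, 0.0, 0.0)):
    """Expected eGFR at the given times, in the total-effect parameterization.

    ``alpha0 ... zeta0`` are scalars (already evaluated at the subject's
    covariates); ``re`` is the subject's random-effect triple.
    """
    tb = time_basis(yrs, weights.t_star)
    w = weights.w
    a_i, b_i, g_i = re
    cshare = tb.chronic / (1.0 - w)
    return (
        (alpha0 + a_i)
        + (beta0 + b_i) * tb.acute
        + (gamma0 + g_i) * tb.chronic
        + tau0 * trt * cshare
        + zeta0 * trt * (np.asarray(yrs, dtype=float) - cshare)
    )


def longitudinal_loglik(y, mu, re, sigma2: float, Sigma: np.ndarray) -> float:
    """Gaussian log-density of the visits plus the random-effect log-prior.

    ``y``/``mu`` are flat arrays over all visits, ``re`` the (n, 3) matrix of
    random effects; the random-effect covariance is ``sigma2 * Sigma``.
    """
    y = np.asarray(y, float)
    mu = np.asarray(mu, float)
    re = np.atleast_2d(np.asarray(re, float))
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    resid = y - mu
    ll = -0.5 * (len(y) * (_LOG2PI + np.log(sigma2)) + resid @ resid / sigma2)
    cov = sigma2 * np.asarray(Sigma, float)
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise np.linalg.LinAlgError("random-effect covariance is not positive definite")
    sol = np.linalg.solve(cov, re.T)
    ll += -0.5 * (re.shape[0] * (3 * _LOG2PI + logdet) + np.sum(re.T * sol))
    return float(ll)


def re_design(yrs, t_star: float) -> np.ndarray:
    """Random-effect design Z = [1, A, C] at the given visit times."""
    tb = time_basis(yrs, t_star)
    return np.column_stack([np.ones_like(tb.acute), tb.acute, tb.chronic])


def marginal_subject_loglik(y, yrs, mu_fixed, sigma2: float, Sigma: np.ndarray,
                            t_star: float) -> float:
    """Closed-form Gaussian marginal of one subject's visits.

    Integrates the random effects analytically:
    ``y ~ N(mu_fixed, sigma2 * (I + Z Sigma Z^T))`` with ``Z`` the
    random-effect design at the subject's visit times.
    """
    y = np.asarray(y, float)
    Z = re_design(yrs, t_star)
    V = sigma2 * (np.eye(len(y)) + Z @ np.asarray(Sigma, float) @ Z.T)
    resid = y - np.asarray(mu_fixed, float)
    sign, logdet = np.linalg.slogdet(V)
    if sign <= 0:
        raise np.linalg.LinAlgError("marginal covariance is not positive definite")
    sol = np.linalg.solve(V, resid)
    return float(-0.5 * (len(y) * _LOG2PI + logdet + resid @ sol))
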