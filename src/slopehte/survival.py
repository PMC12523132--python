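"""Piecewise-exponential dropout submodel with shared random effects.

The hazard of the composite event (death / ESKD) for subject *i* is

    h_i(s) = z_i * exp(lambda_k)   for s in [t_k, t_{k+1}),
    z_i    = exp(lambda0 * trt_i + eta1 * a_i + eta2 * g_i),

where ``(a_i, g_i)`` are the subject's baseline and chronic-slope random
effects from the longitudinal model — the "shared parameters" that make
dropout informative when ``eta1, eta2 != 0``.  The acute random effect is
deliberately excluded: with so few acute-phase visits it carries almost no
information about the event time.  No covariates enter ``z_i``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PiecewiseHazard",
    "place_knots",
    "frailty",
    "cumulative_hazard",
    "survival_prob",
    "survival_loglik",
    "sample_event_time",
]


@dataclass
class PiecewiseHazard:
    """Step baseline hazard plus frailty coefficients.

    ``knots`` has length K+1 starting at 0; the final interval extends to
    infinity (times past the last knot keep the last hazard level).
    ``log_levels`` are the per-interval log baseline hazards.
    """

    knots: np.ndarray
    log_levels: np.ndarray
    lambda0: float = 0.0
    eta1: float = 0.0
    eta2: float = 0.0

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        self.log_levels = np.asarray(self.log_levels, dtype=float)
        if self.knots[0] != 0.0:
            raise ValueError("first knot must be 0")
        if np.any(np.diff(self.knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        if len(self.log_levels) != len(self.knots):
            raise ValueError("need one log level per interval (K = len(knots))")

    @property
    def K(self) -> int:
        return len(self.log_levels)

    def interval_of(self, t) -> np.ndarray:
        """Index k with t in [t_k, t_{k+1}); the last interval is half-open to inf."""
        idx = np.searchsorted(self.knots, np.asarray(t, dtype=float), side="right") - 1
        return np.clip(idx, 0, self.K - 1)


def place_knots(event_times, K: int) -> np.ndarray:
    """Interior knots at the k/K quantiles of the observed (uncensored) event times.

    Uses linear-interpolation sample quantiles.  Returns the K knots
    ``[0, q_{1/K}, ..., q_{(K-1)/K}]``; the final interval is unbounded.
    """
    times = np.asarray(event_times, dtype=float)
    times = times[np.isfinite(times)]
    if times.size == 0:
        raise ValueError("no observed events: supply a fixed knot grid instead")
    if K < 1:
        raise ValueError("K must be >= 1")
    if K == 1:
        return np.array([0.0])
    qs = np.quantile(times, np.arange(1, K) / K, method="linear")
    knots = np.concatenate([[0.0], qs])
    if np.any(np.diff(knots) <= 0):
        raise ValueError("degenerate knots: event times have too few distinct values")
    return knots


def frailty(trt, alpha_i, gamma_i, hz: PiecewiseHazard):
    """Multiplicative hazard factor z_i = exp(lambda0*trt + eta1*a_i + eta2*g_i)."""
    return np.exp(hz.lambda0 * np.asarray(trt, float)
                  + hz.eta1 * np.asarray(alpha_i, float)
                  + hz.eta2 * np.asarray(gamma_i, float))


def exposure_matrix(t, knots: np.ndarray) -> np.ndarray:
    """Per-interval exposure: E[i, k] = length of [t_k, t_{k+1}) spent before t_i."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    upper = np.concatenate([knots[1:], [np.inf]])
    lo = np.minimum(np.maximum(t[:, None] - knots[None, :], 0.0),
                    (upper - knots)[None, :])
    return lo


def cumulative_hazard(t, hz: PiecewiseHazard):
    """Baseline cumulative hazard Lambda0(t) (piecewise linear)."""
    E = exposure_matrix(t, hz.knots)
    out = E @ np.exp(hz.log_levels)
    return out if np.ndim(t) else float(out[0])


def survival_prob(t, z, hz: PiecewiseHazard):
    """S(t) = exp(-z * Lambda0(t)); S(0) = 1, nonincreasing in t."""
    if np.any(np.asarray(t) < 0):
        raise ValueError("time must be non-negative")
    return np.exp(-np.asarray(z, float) * cumulative_hazard(t, hz))


def survival_loglik(time, event, z, hz: PiecewiseHazard):
    """Log-likelihood of (time, event): event adds log(z*h(time)) to log S(time)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    z = np.asarray(z, dtype=float)
    ll = -z * cumulative_hazard(time, hz)
    loghaz = np.log(z) + hz.log_levels[hz.interval_of(time)]
    ll = ll + event * loghaz
    return float(np.sum(ll))


def sample_event_time(z, hz: PiecewiseHazard, rng: np.random.Generator):
    """Inverse-CDF draw of event times: Lambda0^{-1}(-log U / z).

    Vectorizes over ``z``; the distribution matches ``survival_prob`` exactly
    because Lambda0 is piecewise linear and strictly increasing.
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    if np.any(z <= 0):
        raise ValueError("frailty must be positive")
    target = -np.log(rng.uniform(size=z.shape)) / z
    levels = np.exp(hz.log_levels)
    widths = np.diff(hz.knots)
    cum = np.concatenate([[0.0], np.cumsum(levels[:-1] * widths)])  # Lambda0 at knots
    k = np.clip(np.searchsorted(cum, target, side="right") - 1, 0, hz.K - 1)
    t = hz.knots[k] + (target - cum[k]) / levels[k]
    return t if t.size > 1 else float(t[0])
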