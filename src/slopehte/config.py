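"""Run configuration.

All tunable quantities of the model live in :class:`ModelConfig` and
:class:`SamplerConfig`; both can be populated from a plain YAML file with
``load_config``.  Every key has a default, so an empty file is a valid
configuration.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import yaml


@dataclass
class ModelConfig:
    """Structural and prior settings of the joint model.

    Parameters
    ----------
    t_star
        Change-point between the acute and chronic eGFR phases, in years.
    T_star
        Horizon defining the total slope, in years.
    prior_scale
        Standard deviation of the vague Gaussian priors placed on all
        regression-type coefficients and on the log-hazard levels.
    a0, b0
        Gamma hyper-parameters of the residual precision prior; ``a0`` also
        enters the Wishart degrees of freedom of the random-effect precision.
    c0, d0
        Base and power parameters of the tree-depth prior: a node at depth
        ``D`` splits with probability ``c0 * (1 + D) ** -d0``.
    K
        Number of steps of the piecewise-exponential baseline hazard.
    n_cuts
        Number of interior quantile cutpoints per continuous split variable.
    min_leaf
        Minimum subjects per leaf on the discovery set; ``None`` means
        ``max(25, 0.02 * n)``.
    max_depth
        Optional hard cap on tree depth (mainly for enumerable test spaces).
    """

    t_star: float = 1.0 / 3.0
    T_star: float = 3.0
    prior_scale: float = 1000.0
    a0: float = 0.01
    b0: float = 0.01
    c0: float = 0.95
    d0: float = 2.0
    K: int = 5
    n_cuts: int = 9
    min_leaf: int | None = None
    max_depth: int | None = None
    horizon_years: float = 3.0
    newton_tol: float = 1e-8
    newton_maxit: int = 50

    @property
    def w(self) -> float:
        return self.t_star / self.T_star

    def resolve_min_leaf(self, n: int) -> int:
        if self.min_leaf is not None:
            return int(self.min_leaf)
        return max(25, int(round(0.02 * n)))


@dataclass
class SamplerConfig:
    """Gibbs round-trip schedule.

    ``b1`` is the inner-chain length of each conditional step (only the last
    state is kept; the first half of the parameter step counts as warmup),
    ``b2`` the number of round-trips, i.e. retained posterior draws.
    """

    b1: int = 100
    b2: int = 100
    keep_inner: bool = False  # retain every post-warmup inner draw (frozen-tree runs)


@dataclass
class HonestConfig:
    """Honest subgroup-estimation schedule: ``b3`` repeated 60/40 splits."""

    b3: int = 100
    frac_discovery: float = 0.6
    refit_all: bool = False
    refit: SamplerConfig | None = None  # defaults to the discovery schedule


def load_config(path: str) -> dict:
    """Read a YAML config file.

    Returns ``{"model": ModelConfig, "sampler": SamplerConfig,
    "honest": HonestConfig, "covariates": CovariateSpec | None}``; the
    optional ``covariates`` section carries the columns, transforms and
    design roles (see :class:`slopehte.data_model.CovariateSpec`).
    """
    from .data_model import CovariateSpec

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = {}
    for key, cls in (("model", ModelConfig), ("sampler", SamplerConfig),
                     ("honest", HonestConfig)):
        sect = raw.get(key, {}) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(sect) - known
        if unknown:
            raise KeyError(f"unknown {key} config keys: {sorted(unknown)}")
        out[key] = cls(**sect)
    if out["honest"].refit is None:
        out["honest"] = replace(out["honest"], refit=out["sampler"])
    cov = raw.get("covariates")
    out["covariates"] = CovariateSpec(**cov) if cov else None
    return out
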