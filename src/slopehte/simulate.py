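"""Synthetic CKD-trial generator.

Emulates the package's standard simulation design: six baseline
covariates (five Unif(-2,2), one Bernoulli(0.5)), treatment-effect /
intercept / chronic-slope surfaces from one of three families — step (ST),
continuous (CON) or constant (CST), the heterogeneous ones depending only on
the first (continuous) and sixth (binary) covariate — and a
piecewise-exponential dropout process whose frailty optionally shares the
baseline and chronic-slope random effects (informative censoring,
``eta1 = eta2 = -0.5``).

Default magnitudes (documented in the methods note) are chosen to resemble
CKD trials: residual SD ``sigma = 3`` eGFR units, slope random-effect SD 1.5
units/yr, visits every 4 months to 3 years, and a baseline hazard giving
roughly 30% control-arm events by year 3 absent informative censoring.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import CovariateSpec, TrialDataset
from .survival import PiecewiseHazard, frailty, sample_event_time
from .two_slope import effect_weight, mean_trajectory

__all__ = [
    "ScenarioConfig",
    "scenario_catalog",
    "gen_covariates",
    "gen_subject",
    "gen_trial",
    "mdrd_like_fixture",
]

_COV_NAMES = [f"x{i}" for i in range(1, 7)]


def _surface(family: str, kind: str, params: dict):
    """Return f(x1, x6) for one of the ST / CON / CST families."""
    lo, hi = params["low"], params["high"]
    bump = params.get("x6", 0.0)
    if family == "CST":
        return lambda x1, x6: np.full_like(np.asarray(x1, float), hi)
    if family == "ST":
        return lambda x1, x6: np.where(np.asarray(x1) > 0.0, hi + bump * x6, lo)
    if family == "CON":
        slope = (hi - lo) / 4.0
        mid = (hi + lo) / 2.0
        return lambda x1, x6: mid + slope * np.asarray(x1, float) + bump * x6
    raise ValueError(f"unknown surface family {family!r}")


@dataclass
class ScenarioConfig:
    """One data-generating process.

    ``tau/alpha/gamma`` families are ST, CON or CST; the acute slope and the
    acute treatment effect are always constant.  ``eta`` switches informative
    censoring (0 or -0.5 on both connecting parameters).
    """

    n: int = 800
    tau_family: str = "CST"
    alpha_family: str = "CST"
    gamma_family: str = "CST"
    tau_params: dict = field(default_factory=lambda: {"low": -0.85, "high": 0.9, "x6": 0.2})
    alpha_params: dict = field(default_factory=lambda: {"low": 40.0, "high": 45.0, "x6": 3.0})
    gamma_params: dict = field(default_factory=lambda: {"low": -4.0, "high": -2.5, "x6": 0.5})
    beta0: float = -2.0
    zeta0: float = 0.0
    eta: tuple = (0.0, 0.0)
    lambda0: float = 0.0
    log_hazard: float = float(np.log(-np.log(0.7) / 3.0))  # ~30% events by year 3
    sigma: float = 3.0
    re_sd: tuple = (2.0, 1.5, 1.5)  # SDs of (alpha_i, beta_i, gamma_i)
    visit_schedule: tuple = tuple(np.round(np.arange(0, 10) / 3.0, 6))
    horizon: float = 3.0
    t_star: float = 1.0 / 3.0
    T_star: float = 3.0

    def surfaces(self):
        return {
            "tau0": _surface(self.tau_family, "tau", self.tau_params),
            "alpha0": _surface(self.alpha_family, "alpha", self.alpha_params),
            "gamma0": _surface(self.gamma_family, "gamma", self.gamma_params),
        }

    @property
    def Sigma(self) -> np.ndarray:
        """Standardized random-effect covariance (RE covariance = sigma^2 * Sigma)."""
        return np.diag(np.asarray(self.re_sd, float) ** 2 / self.sigma ** 2)


def scenario_catalog() -> dict[str, ScenarioConfig]:
    """Named scenarios mirroring the 16-setting simulation layout.

    Settings 1-8: strong heterogeneity with a harmed subgroup; 9-12: subtle
    heterogeneity (effect gap 0.4 with a harmed subgroup); 13/15: constant
    positive effect 0.1 (no heterogeneity); 14/16: all-positive but
    extremely subtle gap 0.2.  Even-numbered members of each block use the
    continuous family; the trailing YES variants add informative censoring.
    """
    strong = {"low": -0.85, "high": 0.9, "x6": 0.2}
    subtle = {"low": -0.2, "high": 0.2, "x6": 0.0}
    tiny = {"low": 0.05, "high": 0.25, "x6": 0.0}
    null = {"low": 0.1, "high": 0.1, "x6": 0.0}
    ic = (-0.5, -0.5)
    cat = {
        "setting1": ScenarioConfig(tau_family="ST", alpha_family="ST", gamma_family="ST",
                                   tau_params=strong),
        "setting2": ScenarioConfig(tau_family="ST", alpha_family="CON", gamma_family="CON",
                                   tau_params=strong),
        "setting3": ScenarioConfig(tau_family="ST", alpha_family="ST", gamma_family="ST",
                                   tau_params=strong, eta=ic),
        "setting4": ScenarioConfig(tau_family="ST", alpha_family="CON", gamma_family="CON",
                                   tau_params=strong, eta=ic),
        "setting5": ScenarioConfig(tau_family="CON", alpha_family="ST", gamma_family="ST",
                                   tau_params=strong),
        "setting6": ScenarioConfig(tau_family="CON", alpha_family="CON", gamma_family="CON",
                                   tau_params=strong),
        "setting7": ScenarioConfig(tau_family="CON", alpha_family="ST", gamma_family="ST",
                                   tau_params=strong, eta=ic),
        "setting8": ScenarioConfig(tau_family="CON", alpha_family="CON", gamma_family="CON",
                                   tau_params=strong, eta=ic),
        "setting9": ScenarioConfig(tau_family="ST", tau_params=subtle),
        "setting10": ScenarioConfig(tau_family="CON", tau_params=subtle),
        "setting11": ScenarioConfig(tau_family="ST", tau_params=subtle, eta=ic),
        "setting12": ScenarioConfig(tau_family="CON", tau_params=subtle, eta=ic),
        "setting13": ScenarioConfig(tau_family="CST", tau_params=null),
        "setting14": ScenarioConfig(tau_family="CON", tau_params=tiny),
        "setting15": ScenarioConfig(tau_family="CST", tau_params=null, eta=ic),
        "setting16": ScenarioConfig(tau_family="CON", tau_params=tiny, eta=ic),
    }
    return cat


def sim_covariate_spec() -> CovariateSpec:
    # simulated covariates are already light-tailed and centred: no transform
    return CovariateSpec(names=list(_COV_NAMES), log1p=[], standardize=False)


def gen_covariates(n: int, rng: np.random.Generator) -> np.ndarray:
    """n x 6 covariate matrix: columns 1-5 Unif(-2,2), column 6 Bernoulli(0.5)."""
    if n < 1:
        raise ValueError("n must be positive")
    X = np.empty((n, 6))
    X[:, :5] = rng.uniform(-2.0, 2.0, size=(n, 5))
    X[:, 5] = rng.integers(0, 2, size=n)
    return X


def gen_subject(x: np.ndarray, trt: int, scenario: ScenarioConfig,
                rng: np.random.Generator):
    """Simulate one subject: visits on the two-slope mean, dropout by frailty.

    Returns ``(visit_times, egfr_values, time, event, re, true_tau0)``;
    visits are truncated at ``min(event time, horizon)``.
    """
    sf = scenario.surfaces()
    x1, x6 = x[0], x[5]
    tau0 = float(np.asarray(sf["tau0"](x1, x6)))
    alpha0 = float(np.asarray(sf["alpha0"](x1, x6)))
    gamma0 = float(np.asarray(sf["gamma0"](x1, x6)))
    weights = effect_weight(scenario.t_star, scenario.T_star)

    sd = np.asarray(scenario.re_sd, float)
    re = rng.standard_normal(3) * sd
    hz = PiecewiseHazard(knots=np.array([0.0]),
                         log_levels=np.array([scenario.log_hazard]),
                         lambda0=scenario.lambda0,
                         eta1=scenario.eta[0], eta2=scenario.eta[1])
    z = frailty(trt, re[0], re[2], hz)
    t_ev = float(np.atleast_1d(sample_event_time(z, hz, rng))[0])
    event = int(t_ev < scenario.horizon)
    time = min(t_ev, scenario.horizon)

    sched = np.asarray(scenario.visit_schedule, float)
    keep = sched <= time + 1e-12
    yrs = sched[keep]
    mu = mean_trajectory(yrs, trt, alpha0=alpha0, beta0=scenario.beta0,
                         gamma0=gamma0, tau0=tau0, zeta0=scenario.zeta0,
                         weights=weights, re=tuple(re))
    egfr = mu + scenario.sigma * rng.standard_normal(len(yrs))
    return yrs, egfr, time, event, re, tau0


def gen_trial(scenario: ScenarioConfig, seed: int | np.random.Generator) -> TrialDataset:
    """Simulate a full 1:1 randomized trial as a validated TrialDataset.

    The per-subject true conditional average treatment effect is recorded in
    ``dataset.truth`` for evaluation.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = scenario.n
    X = gen_covariates(n, rng)
    trt = rng.permutation(np.arange(n) % 2)
    rows_long, rows_surv, taus = [], [], []
    for i in range(n):
        yrs, egfr, time, event, _, tau0 = gen_subject(X[i], int(trt[i]), scenario, rng)
        rows_long.append(pd.DataFrame({"subject_id": i, "yrs": yrs, "egfr": egfr}))
        rows_surv.append((i, time, event))
        taus.append(tau0)
    long = pd.concat(rows_long, ignore_index=True)
    surv = pd.DataFrame(rows_surv, columns=["subject_id", "time", "event"])
    cov = pd.DataFrame(X, columns=_COV_NAMES)
    cov.insert(0, "subject_id", np.arange(n))
    cov["trt"] = trt.astype(int)
    ds = TrialDataset(long=long, surv=surv, cov=cov, spec=sim_covariate_spec(),
                      truth=pd.DataFrame({"subject_id": np.arange(n), "true_cate": taus}))
    ds.validate()
    return ds


# ---------------------------------------------------------------------------
# MDRD-like fixture


_MDRD_CONTINUOUS = ["eGFR", "AGE", "UACR", "PHOS", "ALB", "BICARB", "BMI", "CAL",
                    "DBP_sit", "SBP_sit", "LDL", "HDL", "TG"]


def mdrd_like_fixture(seed: int, n: int = 800, split_egfr: float = 34.32,
                      tau_low: float = 0.2, tau_high: float = 2.0) -> TrialDataset:
    """Synthetic stand-in resembling the MDRD covariate table (no real data).

    ~n subjects with the standard CKD covariate names, heavy-tailed UACR/TG
    (log-normal), visits every other month to 3 years, composite events, and
    a planted treatment-effect split on baseline eGFR.  Entirely simulated;
    used only for end-to-end smoke tests of the pipeline.
    """
    rng = np.random.default_rng(seed)
    egfr = rng.uniform(14.0, 55.0, n)
    cov = pd.DataFrame({
        "subject_id": np.arange(n),
        "eGFR": egfr,
        "AGE": rng.normal(52.0, 12.0, n).clip(18, 75),
        "UACR": rng.lognormal(4.5, 1.3, n),
        "PHOS": rng.normal(3.8, 0.7, n).clip(2, 8),
        "ALB": rng.normal(4.0, 0.35, n).clip(2.5, 5.5),
        "BICARB": rng.normal(23.0, 3.0, n).clip(12, 35),
        "BMI": rng.normal(26.7, 4.5, n).clip(16, 45),
        "CAL": rng.normal(9.1, 0.5, n).clip(7, 12),
        "DBP_sit": rng.normal(81.0, 9.0, n).clip(50, 120),
        "SBP_sit": rng.normal(130.0, 16.0, n).clip(90, 200),
        "LDL": rng.normal(144.0, 40.0, n).clip(40, 300),
        "HDL": rng.normal(38.0, 12.0, n).clip(15, 100),
        "TG": rng.lognormal(4.95, 0.55, n),
        "Sex": rng.integers(0, 2, n),
        "Smoke": rng.integers(0, 2, n),
    })
    cov["trt"] = rng.permutation(np.arange(n) % 2).astype(int)

    scenario = ScenarioConfig(sigma=3.0, re_sd=(2.0, 1.5, 1.0), eta=(-0.3, -0.3),
                              visit_schedule=tuple(np.round(np.arange(0, 19) / 6.0, 6)))
    weights = effect_weight(scenario.t_star, scenario.T_star)
    hz = PiecewiseHazard(knots=np.array([0.0]), log_levels=np.array([scenario.log_hazard]),
                         lambda0=0.0, eta1=scenario.eta[0], eta2=scenario.eta[1])
    rows_long, rows_surv, taus = [], [], []
    for i in range(n):
        tau0 = tau_high if egfr[i] > split_egfr else tau_low
        alpha0 = 0.95 * egfr[i]
        gamma0 = -4.5 + 0.04 * egfr[i]
        re = rng.standard_normal(3) * np.asarray(scenario.re_sd)
        z = frailty(int(cov.loc[i, "trt"]), re[0], re[2], hz)
        t_ev = float(np.atleast_1d(sample_event_time(z, hz, rng))[0])
        event = int(t_ev < scenario.horizon)
        time = min(t_ev, scenario.horizon)
        sched = np.asarray(scenario.visit_schedule)
        yrs = sched[sched <= time + 1e-12]
        mu = mean_trajectory(yrs, int(cov.loc[i, "trt"]), alpha0=alpha0,
                             beta0=-2.0, gamma0=gamma0, tau0=tau0, zeta0=0.0,
                             weights=weights, re=tuple(re))
        rows_long.append(pd.DataFrame({"subject_id": i, "yrs": yrs,
                                       "egfr": mu + scenario.sigma * rng.standard_normal(len(yrs))}))
        rows_surv.append((i, time, event))
        taus.append(tau0)

    spec = CovariateSpec(
        names=_MDRD_CONTINUOUS + ["Sex", "Smoke"],
        log1p=["UACR", "TG"],
        standardize=False,
        roles={
            "alpha": ["AGE", "UACR", "PHOS"],
            "gamma": ["eGFR", "AGE", "UACR", "PHOS"],
            "beta": ["eGFR", "AGE", "UACR", "PHOS"],
            "zeta": ["eGFR", "AGE", "UACR", "PHOS"],
            "split": ["eGFR", "AGE", "UACR", "PHOS"],
        },
    )
    cov2 = cov.copy()
    for c in spec.log1p:
        cov2[c] = np.log1p(cov2[c])
    ds = TrialDataset(long=pd.concat(rows_long, ignore_index=True),
                      surv=pd.DataFrame(rows_surv, columns=["subject_id", "time", "event"]),
                      cov=cov2, spec=spec,
                      truth=pd.DataFrame({"subject_id": np.arange(n), "true_cate": taus}))
    ds.validate()
    return ds
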