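import numpy as np
import pandas as pd
import pytest

from slopehte.config import ModelConfig, SamplerConfig
from slopehte.data_model import CovariateSpec, TrialDataset
from slopehte.simulate import ScenarioConfig, gen_trial


def make_dataset(y_per_subject, yrs_per_subject, times, events, X, trt,
                 names=None) -> TrialDataset:
    """Assemble a TrialDataset directly from arrays (test fixtures)."""
    names = names or [f"x{i + 1}" for i in range(np.atleast_2d(X).shape[1])]
    X = np.atleast_2d(np.asarray(X, float))
    rows = []
    for i, (y, t) in enumerate(zip(y_per_subject, yrs_per_subject)):
        rows.append(pd.DataFrame({"subject_id": i, "yrs": t, "egfr": y}))
    cov = pd.DataFrame(X, columns=names)
    cov.insert(0, "subject_id", np.arange(len(times)))
    cov["trt"] = np.asarray(trt, int)
    ds = TrialDataset(
        long=pd.concat(rows, ignore_index=True),
        surv=pd.DataFrame({"subject_id": np.arange(len(times)),
                           "time": times, "event": events}),
        cov=cov, spec=CovariateSpec(names=names, standardize=False))
    ds.validate()
    return ds


@pytest.fixture
def rng():
    return np.random.default_rng(20250929)


@pytest.fixture(scope="session")
def small_trial():
    """A quick 120-subject null trial shared across tests."""
    sc = ScenarioConfig(n=120, tau_family="CST", tau_params={"low": 0.1, "high": 0.1})
    return gen_trial(sc, 42)


@pytest.fixture(scope="session")
def ic_trial():
    """A 150-subject trial with informative censoring."""
    sc = ScenarioConfig(n=150, tau_family="CST", tau_params={"low": 0.1, "high": 0.1},
                        eta=(-0.5, -0.5))
    return gen_trial(sc, 43)


def one_subject_dataset(rng, nvis=None):
    """Single-subject fixture with a random visit layout and follow-up."""
    nvis = nvis if nvis is not None else int(rng.integers(1, 10))
    time = float(rng.uniform(0.5, 3.0))
    yrs = np.sort(np.concatenate([[0.0], rng.uniform(0.05, time, nvis - 1)])) \
        if nvis > 1 else np.array([0.0])
    y = 40.0 + rng.normal(0, 3, len(yrs))
    return make_dataset([y], [yrs], [time], [int(rng.uniform() < 0.5)],
                        [[rng.uniform(-2, 2)]], [int(rng.uniform() < 0.5)])


def random_sp_state(cd, cfg, rng, eta_scale=0.5):
    """A model-realistic random parameter configuration on compiled data."""
    from slopehte.sampler import init_state
    st = init_state(cd, cfg)
    st.sigma2 = 9.0
    st.Sigma = np.diag([4 / 9, 0.25, 0.25])
    st.hz.log_levels = rng.normal(-2.1, 0.4, cfg.K)
    st.hz.lambda0 = float(rng.normal(0, 0.3))
    st.hz.eta1 = float(-rng.uniform(0, eta_scale))
    st.hz.eta2 = float(-rng.uniform(0, eta_scale))
    return st


def laplace_quadrature_oracle(cd, st, cfg):
    """Independent check of the subject marginal: exact Gaussian reduction of
    the longitudinal factor plus adaptive quadrature over the 1-D frailty
    exponent u = eta1*a + eta2*g."""
    from scipy.integrate import quad

    from slopehte.sampler import fixed_mean
    from slopehte.two_slope import marginal_subject_loglik
    fit = fixed_mean(cd, st)
    res = cd.y - fit
    V = st.sigma2 * st.Sigma
    C_y = marginal_subject_loglik(cd.y, cd.A + cd.C, fit, st.sigma2, st.Sigma,
                                  cfg.t_star)
    Q = cd.Z3.T @ cd.Z3 / st.sigma2 + np.linalg.inv(V)
    mu_re = np.linalg.solve(Q, cd.Z3.T @ res / st.sigma2)
    eta = np.array([st.hz.eta1, 0.0, st.hz.eta2])
    m_u = float(eta @ mu_re)
    v_u = float(eta @ np.linalg.solve(Q, eta))
    delta = float(cd.delta[0])
    H0 = float(cd.E[0] @ np.exp(st.hz.log_levels))
    c0 = st.hz.lambda0 * cd.trt[0]
    logh = float(st.hz.log_levels[cd.ev_interval[0]])

    def integrand(u):
        return (np.exp(delta * (c0 + u + logh) - np.exp(c0 + u) * H0)
                * np.exp(-(u - m_u) ** 2 / (2 * v_u)) / np.sqrt(2 * np.pi * v_u))

    s = np.sqrt(v_u)
    I, _ = quad(integrand, m_u - 12 * s, m_u + 12 * s, limit=200)
    return C_y + np.log(I)


@pytest.fixture
def fast_cfg():
    return ModelConfig()


@pytest.fixture
def fast_scfg():
    return SamplerConfig(b1=15, b2=15)
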