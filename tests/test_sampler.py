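import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import chisquare

from conftest import (laplace_quadrature_oracle, make_dataset,
                      one_subject_dataset, random_sp_state)
from slopehte.config import ModelConfig, SamplerConfig
from slopehte.sampler import (CompiledData, SPState, fixed_mean, init_state,
                              laplace_subject_marginal, make_tree_prior,
                              run_chain, update_trees, _laplace_stats)
from slopehte.simulate import ScenarioConfig, gen_trial
from slopehte.survival import survival_loglik
from slopehte.trees import DecisionTree, Node
from slopehte.two_slope import marginal_subject_loglik


class TestLaplaceMarginal:
    def test_exact_when_connections_zero(self, rng):
        ds = one_subject_dataset(rng, nvis=4)
        cfg = ModelConfig(K=1)
        cd = CompiledData(ds, cfg)
        st = random_sp_state(cd, cfg, rng, eta_scale=0.0)
        st.hz.eta1 = st.hz.eta2 = 0.0
        got = laplace_subject_marginal(cd, st, 0)
        fit = fixed_mean(cd, st)
        z = np.exp(st.hz.lambda0 * cd.trt[0])
        expected = (marginal_subject_loglik(cd.y, cd.A + cd.C, fit, st.sigma2,
                                            st.Sigma, cfg.t_star)
                    + survival_loglik(cd.time[0], cd.delta[0], z, st.hz))
        assert np.isclose(got, expected, atol=1e-10)

    def test_matches_quadrature_on_one_visit_toy(self, rng):
        ds = one_subject_dataset(rng, nvis=1)
        cfg = ModelConfig(K=1)
        cd = CompiledData(ds, cfg)
        st = random_sp_state(cd, cfg, rng)
        got = laplace_subject_marginal(cd, st, 0)
        assert abs(got - laplace_quadrature_oracle(cd, st, cfg)) < 1e-3

    def test_perturbing_data_from_mean_lowers_marginal(self, rng):
        ds = one_subject_dataset(rng, nvis=6)
        cfg = ModelConfig(K=1)
        cd = CompiledData(ds, cfg)
        st = random_sp_state(cd, cfg, rng)
        fit = fixed_mean(cd, st)
        cd.y = fit.copy()
        at_mean = laplace_subject_marginal(cd, st, 0)
        cd.y = fit + 25.0
        assert laplace_subject_marginal(cd, st, 0) < at_mean

    def test_permutation_invariance(self, small_trial, fast_cfg, rng):
        cd = CompiledData(small_trial, fast_cfg)
        st = random_sp_state(cd, fast_cfg, rng)
        total = sum(laplace_subject_marginal(cd, st, i) for i in range(0, cd.n, 10))
        from dataclasses import replace
        perm = replace(small_trial,
                       cov=small_trial.cov.iloc[::-1].reset_index(drop=True))
        cdp = CompiledData(perm, fast_cfg)
        stp = random_sp_state(cdp, fast_cfg, np.random.default_rng(20250929))
        # same parameter values, reversed subject order
        for attr in ("sigma2", "Sigma"):
            setattr(stp, attr, getattr(st, attr))
        stp.hz = st.hz
        stp.mu0, stp.mu1, stp.mu3, stp.mu4, stp.theta = \
            st.mu0, st.mu1, st.mu3, st.mu4, st.theta
        total_p = sum(laplace_subject_marginal(cdp, stp, cdp.n - 1 - i)
                      for i in range(0, cd.n, 10))
        assert np.isclose(total, total_p, atol=1e-8)


class TestChainBasics:
    def test_fixed_seed_reproducible(self, small_trial, fast_cfg):
        r1 = run_chain(small_trial, fast_cfg, SamplerConfig(b1=5, b2=5),
                       np.random.default_rng(3))
        r2 = run_chain(small_trial, fast_cfg, SamplerConfig(b1=5, b2=5),
                       np.random.default_rng(3))
        for d1, d2 in zip(r1.draws, r2.draws):
            np.testing.assert_array_equal(d1.theta, d2.theta)
            np.testing.assert_array_equal(d1.re, d2.re)
            assert d1.trees[2].canonical_key() == d2.trees[2].canonical_key()

    def test_single_round_trip(self, small_trial, fast_cfg):
        res = run_chain(small_trial, fast_cfg, SamplerConfig(b1=5, b2=1),
                        np.random.default_rng(0))
        assert len(res.draws) == 1
        assert all(t.n_leaves >= 1 for t in res.draws[0].trees)

    def test_finite_log_marginal_each_draw(self, small_trial, fast_cfg):
        res = run_chain(small_trial, fast_cfg, SamplerConfig(b1=5, b2=5),
                        np.random.default_rng(1))
        assert np.isfinite(res.diagnostics["logmarg"]).all()

    def test_frozen_trees_keep_inner_draws(self, small_trial, fast_cfg):
        scfg = SamplerConfig(b1=10, b2=4, keep_inner=True)
        trees = [DecisionTree() for _ in range(3)]
        res = run_chain(small_trial, fast_cfg, scfg, np.random.default_rng(2),
                        init_trees=trees, update_tree_structure=False)
        assert len(res.inner) == 4 * (10 - 5)
        assert all(d.trees[2].n_leaves == 1 for d in res.draws)


class TestParameterRecovery:
    def test_survival_block_recovers_truth(self):
        """Frozen-root fit on simulated data: hazard and connection parameters."""
        sc = ScenarioConfig(n=400, tau_family="CST",
                            tau_params={"low": 0.1, "high": 0.1},
                            eta=(-0.5, -0.5))
        data = gen_trial(sc, 77)
        cfg = ModelConfig()
        res = run_chain(data, cfg, SamplerConfig(b1=30, b2=30),
                        np.random.default_rng(8),
                        init_trees=[DecisionTree() for _ in range(3)],
                        update_tree_structure=False)
        tail = res.draws[10:]
        lam = np.mean([d.hz.log_levels for d in tail], axis=0)
        # constant true hazard log(-log(0.7)/3) ~ -2.13
        assert np.all(np.abs(lam - sc.log_hazard) < 0.8)
        eta2 = np.mean([d.hz.eta2 for d in tail])
        assert eta2 < 0.0  # informative-censoring direction recovered
        sig = np.mean([d.sigma2 for d in tail])
        assert abs(sig - sc.sigma ** 2) < 1.5


class TestWishartDraws:
    def test_bartlett_matches_scipy_moments(self, rng):
        from scipy.stats import wishart

        from slopehte.sampler import _wishart
        df, scale = 9.5, np.array([[2.0, 0.4, 0.0], [0.4, 1.0, 0.1],
                                   [0.0, 0.1, 0.5]])
        ours = np.mean([_wishart(df, scale, rng) for _ in range(4000)], axis=0)
        ref = wishart(df=df, scale=scale).rvs(size=4000,
                                              random_state=np.random.default_rng(1))
        np.testing.assert_allclose(ours, df * scale, rtol=0.08, atol=0.05)
        np.testing.assert_allclose(ours, ref.mean(axis=0), rtol=0.08, atol=0.05)


class TestTreeKernelPosterior:
    def test_enumerable_posterior_frequencies(self, rng):
        """Tree-kernel occupancy matches brute-force enumeration (eta = 0).

        Binary split variable, all variance/survival parameters held fixed,
        so the exact joint marginal of each of the 8 tree configurations is
        a dense-Gaussian computation independent of the sampler.
        """
        n, nvis = 40, 4
        x = np.repeat([0.0, 1.0], n // 2)
        trt = np.tile([0, 1], n // 2)
        yrs = np.linspace(0.0, 3.0, nvis)
        cfg = ModelConfig(prior_scale=5.0, min_leaf=5, K=1, max_depth=1)
        sigma2, Sigma = 4.0, np.diag([0.5, 0.1, 0.1])
        gen = np.random.default_rng(123)
        ys, ts, evs = [], [], []
        from slopehte.two_slope import re_design
        Z = re_design(yrs, cfg.t_star)
        for i in range(n):
            re = gen.multivariate_normal(np.zeros(3), sigma2 * Sigma)
            mu = 40.0 + 2.0 * x[i] - 2.0 * (yrs - (yrs - 1 / 3).clip(0)) \
                - (3.0 - 1.2 * x[i]) * (yrs - 1 / 3).clip(0) \
                + trt[i] * 0.8 * x[i] * (yrs - 1 / 3).clip(0)
            ys.append(mu + Z @ re + gen.normal(0, np.sqrt(sigma2), nvis))
            ts.append(3.0)
            evs.append(0)
        data = make_dataset(ys, [yrs] * n, ts, evs, x[:, None], trt, names=["x1"])
        cd = CompiledData(data, cfg)
        prior = make_tree_prior(cd, cfg)
        st = init_state(cd, cfg)
        st.sigma2, st.Sigma = sigma2, Sigma
        st.hz.eta1 = st.hz.eta2 = st.hz.lambda0 = 0.0
        st.re[:] = 0.0

        # --- independent enumeration oracle ------------------------------
        from slopehte.trees import log_tree_prior
        root = DecisionTree()
        split = DecisionTree(Node(var=0, cut_idx=0, cut=0.5,
                                  left=Node(depth=1), right=Node(depth=1)))
        tau2 = cfg.prior_scale ** 2
        Xa = cd.Xa

        def flat_block(tree, per_visit, design):
            lab = tree.assign(cd.SX)[cd.subj]
            cols = []
            for j in range(tree.n_leaves):
                m = (lab == j).astype(float)
                cols.append(design[cd.subj] * (per_visit * m)[:, None])
            return np.hstack(cols)

        ones = np.ones(cd.N)
        logmarg = {}
        for k0, t0 in enumerate((root, split)):
            for k1, t1 in enumerate((root, split)):
                for k2, t2 in enumerate((root, split)):
                    F = np.hstack([
                        flat_block(t0, ones, Xa),
                        cd.Xb[cd.subj] * cd.A[:, None],
                        flat_block(t1, cd.C, cd.Xg),
                        flat_block(t2, cd.ftau, np.ones((cd.n, 1))),
                        cd.Xz[cd.subj] * cd.fzeta[:, None],
                    ])
                    cov = sigma2 * np.eye(cd.N) + tau2 * (F @ F.T)
                    for i in range(n):
                        sl = slice(i * nvis, (i + 1) * nvis)
                        cov[sl, sl] += Z @ (sigma2 * Sigma) @ Z.T
                    sign, logdet = np.linalg.slogdet(cov)
                    quadf = cd.y @ np.linalg.solve(cov, cd.y)
                    lm = -0.5 * (cd.N * np.log(2 * np.pi) + logdet + quadf)
                    lm += log_tree_prior(t0, prior) + log_tree_prior(t1, prior) \
                        + log_tree_prior(t2, prior)
                    logmarg[(k0, k1, k2)] = lm
        keys = sorted(logmarg)
        lp = np.array([logmarg[k] for k in keys])
        post = np.exp(lp - lp.max())
        post /= post.sum()

        # --- chain occupancy ---------------------------------------------
        scfg = SamplerConfig(b1=10, b2=1)
        counts = dict.fromkeys(keys, 0)
        for it in range(800):
            update_trees(cd, st, prior, scfg, rng)
            cfgkey = tuple(int(t.n_leaves > 1) for t in st.trees)
            counts[cfgkey] += 1
        observed = np.array([counts[k] for k in keys], float)
        keep = post * 800 >= 5
        obs = np.concatenate([observed[keep], [observed[~keep].sum()]])
        exp = np.concatenate([post[keep] * 800, [post[~keep].sum() * 800]])
        if exp[-1] < 1e-9:
            obs, exp = obs[:-1], exp[:-1]
        exp *= obs.sum() / exp.sum()
        res = chisquare(obs, exp)
        assert res.pvalue > 0.001, (obs, exp)
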