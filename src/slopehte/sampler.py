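"""Round-trip Gibbs sampler for the joint tree / shared-parameter model.

Each round trip alternates two conditional steps:

1. *Parameter step* — an inner chain of ``b1`` Metropolis-within-Gibbs
   iterations over all non-tree parameters (leaf and global coefficients,
   subject random effects, residual variance, random-effect covariance, and
   the survival parameters), keeping only the last state.
2. *Tree step* — for each of the three trees in turn, ``b1`` birth/death
   Metropolis-Hastings iterations whose acceptance ratio uses a marginal
   likelihood in which the subject random effects are integrated out via a
   Gaussian (Laplace) replacement of the survival-likelihood factor, and the
   leaf coefficients are integrated exactly under their conjugate Gaussian
   prior.  Leaf coefficients are then redrawn from their full conditionals.

The Laplace replacement is exact when the connecting parameters
``eta1 = eta2 = 0`` (the survival factor is then constant in the random
effects); otherwise the survival x prior factor is expanded at the mode of
the full per-subject integrand, which is one-dimensional in
``u = eta1 * a_i + eta2 * g_i``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from .config import ModelConfig, SamplerConfig
from .data_model import TrialDataset
from .survival import PiecewiseHazard, exposure_matrix, place_knots
from .trees import (DecisionTree, SplitData, TreePrior, birth_proposal,
                    build_cutpoint_grid, death_proposal, eligible_splits,
                    log_tree_prior)
from .two_slope import time_basis

_LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# compiled data


class CompiledData:
    """Flat, visit-major arrays plus per-subject sufficient statistics.

    Subjects are contiguous in the flat arrays (``starts`` gives offsets);
    ``groups`` batches subjects by visit count for vectorized linear algebra.
    """

    def __init__(self, data: TrialDataset, cfg: ModelConfig,
                 grids=None, grid_names=None):
        self.cfg = cfg
        cov = data.cov
        self.n = len(cov)
        self.subject_ids = cov["subject_id"].to_numpy()
        self.trt = cov["trt"].to_numpy(dtype=float)

        spec = data.spec
        names = spec.encoded_names()

        def design(role: str) -> tuple[np.ndarray, list[str]]:
            cols = spec.role_columns(role)
            mat = np.column_stack([np.ones(self.n)] + [cov[c].to_numpy(dtype=float) for c in cols])
            return mat, ["_intercept"] + cols

        self.Xa, self.names_a = design("alpha")
        self.Xb, self.names_b = design("beta")
        self.Xg, self.names_g = design("gamma")
        self.Xz, self.names_z = design("zeta")
        split_cols = spec.role_columns("split")
        self.SX = np.column_stack([cov[c].to_numpy(dtype=float) for c in split_cols])
        self.split_names = split_cols

        if grids is None:
            grids, grid_names = build_cutpoint_grid(cov, split_cols, cfg.n_cuts)
        self.grids, self.grid_names = grids, list(grid_names)
        if self.grid_names != split_cols:
            raise ValueError("cutpoint grid does not match the split-variable roles")

        # flat longitudinal arrays, subject-major
        order = {sid: k for k, sid in enumerate(self.subject_ids)}
        lng = data.long.copy()
        lng["_k"] = lng["subject_id"].map(order)
        lng = lng.sort_values(["_k", "yrs"], kind="stable")
        self.y = lng["egfr"].to_numpy(dtype=float)
        self.subj = lng["_k"].to_numpy(dtype=np.int64)
        yrs = lng["yrs"].to_numpy(dtype=float)
        tb = time_basis(yrs, cfg.t_star)
        self.A, self.C = tb.acute, tb.chronic
        self.nvis = np.bincount(self.subj, minlength=self.n)
        self.starts = np.concatenate([[0], np.cumsum(self.nvis)])[:-1]
        self.N = len(self.y)

        w = cfg.w
        self.w = w
        self.fz = self.A - self.C * w / (1.0 - w)           # zeta basis (before trt)
        trt_f = self.trt[self.subj]
        self.ftau = trt_f * self.C / (1.0 - w)
        self.fzeta = trt_f * self.fz
        self.Z3 = np.column_stack([np.ones(self.N), self.A, self.C])
        self.ZtZ = np.zeros((self.n, 3, 3))
        np.add.at(self.ZtZ, self.subj, self.Z3[:, :, None] * self.Z3[:, None, :])

        # per-subject static visit sums
        def ssum(v):
            return np.add.reduceat(v, self.starts)
        self.SA2, self.SC2 = ssum(self.A ** 2), ssum(self.C ** 2)
        self.Sfz2 = ssum(self.fz ** 2) * self.trt
        self.Sft2 = ssum(self.C ** 2) * self.trt / (1.0 - w) ** 2

        # visit-count groups (visit-index matrix per group)
        self.groups = []
        for k in np.unique(self.nvis):
            idx = np.flatnonzero(self.nvis == k)
            vidx = self.starts[idx][:, None] + np.arange(k)[None, :]
            self.groups.append((idx, vidx))

        # survival statics
        surv = data.surv.set_index("subject_id").loc[self.subject_ids]
        self.time = surv["time"].to_numpy(dtype=float)
        self.delta = surv["event"].to_numpy(dtype=float)
        ev = self.time[self.delta == 1]
        try:
            self.knots = place_knots(ev, cfg.K)
        except ValueError:
            warnings.warn("too few observed events for quantile knots; using a uniform grid")
            self.knots = np.linspace(0.0, cfg.horizon_years, cfg.K + 1)[:-1]
        self.E = exposure_matrix(self.time, self.knots)
        hz0 = PiecewiseHazard(knots=self.knots, log_levels=np.zeros(cfg.K))
        self.ev_interval = hz0.interval_of(self.time)
        self.d_k = np.bincount(self.ev_interval[self.delta == 1], minlength=cfg.K).astype(float)

    def split_data(self) -> SplitData:
        return SplitData(SX=self.SX, trt=self.trt,
                         min_leaf=self.cfg.resolve_min_leaf(self.n))


def make_tree_prior(cd: CompiledData, cfg: ModelConfig) -> TreePrior:
    return TreePrior(grids=cd.grids, c0=cfg.c0, d0=cfg.d0,
                     min_leaf=cfg.resolve_min_leaf(cd.n),
                     max_depth=cfg.max_depth, var_names=cd.grid_names)


# ---------------------------------------------------------------------------
# state


@dataclass
class SPState:
    """One joint draw: trees, coefficient blocks, survival and variance parameters."""

    trees: list[DecisionTree]
    mu0: np.ndarray
    mu1: np.ndarray
    theta: np.ndarray
    mu3: np.ndarray
    mu4: np.ndarray
    hz: PiecewiseHazard
    sigma2: float
    Sigma: np.ndarray
    re: np.ndarray
    leaf: list[np.ndarray] = field(default_factory=list)  # per-tree subject assignments
    logmarg: float = np.nan

    def tau_at(self, SX: np.ndarray) -> np.ndarray:
        return self.theta[self.trees[2].assign(SX)]

    def light_copy(self) -> "SPState":
        return SPState(trees=[t.copy() for t in self.trees],
                       mu0=self.mu0.copy(), mu1=self.mu1.copy(),
                       theta=self.theta.copy(), mu3=self.mu3.copy(), mu4=self.mu4.copy(),
                       hz=PiecewiseHazard(self.hz.knots.copy(), self.hz.log_levels.copy(),
                                          self.hz.lambda0, self.hz.eta1, self.hz.eta2),
                       sigma2=self.sigma2, Sigma=self.Sigma.copy(), re=self.re.copy(),
                       leaf=[l.copy() for l in self.leaf], logmarg=self.logmarg)


def init_state(cd: CompiledData, cfg: ModelConfig, init_trees=None) -> SPState:
    """Root-only trees; OLS coefficients; moment-based variance components."""
    trees = ([t.copy() for t in init_trees] if init_trees is not None
             else [DecisionTree() for _ in range(3)])
    leaf = [t.assign(cd.SX) for t in trees]
    J = [t.n_leaves for t in trees]
    # OLS on the full two-slope design with leaf indicators
    cols, blocks = [], []
    for j in range(J[0]):
        m = (leaf[0][cd.subj] == j).astype(float)
        cols.append(cd.Xa[cd.subj] * m[:, None])
    blocks.append(("mu0", J[0] * cd.Xa.shape[1]))
    cols.append(cd.Xb[cd.subj] * cd.A[:, None])
    blocks.append(("mu3", cd.Xb.shape[1]))
    for j in range(J[1]):
        m = (leaf[1][cd.subj] == j).astype(float)
        cols.append(cd.Xg[cd.subj] * (cd.C * m)[:, None])
    blocks.append(("mu1", J[1] * cd.Xg.shape[1]))
    for j in range(J[2]):
        m = (leaf[2][cd.subj] == j).astype(float)
        cols.append((cd.ftau * m)[:, None])
    blocks.append(("theta", J[2]))
    cols.append(cd.Xz[cd.subj] * cd.fzeta[:, None])
    blocks.append(("mu4", cd.Xz.shape[1]))
    F = np.hstack(cols)
    beta, *_ = np.linalg.lstsq(F, cd.y, rcond=None)
    resid = cd.y - F @ beta
    sigma2 = max(float(resid @ resid) / max(cd.N - F.shape[1], 1), 1e-3)

    out, pos = {}, 0
    for name, width in blocks:
        out[name] = beta[pos:pos + width]
        pos += width
    mu0 = out["mu0"].reshape(J[0], cd.Xa.shape[1])
    mu1 = out["mu1"].reshape(J[1], cd.Xg.shape[1])

    # constant-hazard start for the survival block
    total_events = cd.delta.sum()
    total_exposure = cd.time.sum()
    lam0 = np.log(max(total_events, 0.5) / total_exposure)
    hz = PiecewiseHazard(knots=cd.knots, log_levels=np.full(cd.cfg.K, lam0))

    Sigma = np.diag([0.5, 0.25, 0.25])
    return SPState(trees=trees, mu0=mu0, mu1=mu1, theta=out["theta"],
                   mu3=out["mu3"], mu4=out["mu4"], hz=hz, sigma2=sigma2,
                   Sigma=Sigma, re=np.zeros((cd.n, 3)), leaf=leaf)


# ---------------------------------------------------------------------------
# flat mean components


def _components(cd: CompiledData, st: SPState):
    """Per-subject surface values and per-visit contribution arrays."""
    a0x = np.einsum("ij,ij->i", cd.Xa, st.mu0[st.leaf[0]])
    g0x = np.einsum("ij,ij->i", cd.Xg, st.mu1[st.leaf[1]])
    b0x = cd.Xb @ st.mu3
    z0x = cd.Xz @ st.mu4
    th = st.theta[st.leaf[2]]
    return a0x, b0x, g0x, th, z0x


def fixed_mean(cd: CompiledData, st: SPState) -> np.ndarray:
    """Per-visit fixed-effect mean (no random effects)."""
    a0x, b0x, g0x, th, z0x = _components(cd, st)
    s = cd.subj
    return (a0x[s] + b0x[s] * cd.A + g0x[s] * cd.C
            + th[s] * cd.ftau + z0x[s] * cd.fzeta)


def re_mean(cd: CompiledData, re: np.ndarray) -> np.ndarray:
    s = cd.subj
    return re[s, 0] + re[s, 1] * cd.A + re[s, 2] * cd.C


# ---------------------------------------------------------------------------
# Laplace marginalization


def _laplace_stats(cd: CompiledData, st: SPState, fit_fixed: np.ndarray):
    """Gaussian replacement of (survival likelihood x random-effect prior).

    Returns ``(m, S, const)``: per subject the replacement is
    ``exp(const_i) * N(re; m_i, S_i)``, so the marginal of the subject's
    visits is ``const_i + log N(y_i; fit_i + Z m_i, sigma2 I + Z S Z^T)``.
    Exact when ``eta1 = eta2 = 0``.
    """
    hz, sigma2 = st.hz, st.sigma2
    V = sigma2 * st.Sigma
    H0 = cd.E @ np.exp(hz.log_levels)
    c0 = hz.lambda0 * cd.trt
    logh_ev = hz.log_levels[cd.ev_interval]
    eta = np.array([hz.eta1, 0.0, hz.eta2])

    if hz.eta1 == 0.0 and hz.eta2 == 0.0:
        m = np.zeros((cd.n, 3))
        S = np.broadcast_to(V, (cd.n, 3, 3)).copy()
        const = cd.delta * (c0 + logh_ev) - np.exp(c0) * H0
        return m, S, const

    Vinv = np.linalg.inv(V)
    # exact longitudinal-conditional Gaussian of the random effects
    res = cd.y - fit_fixed
    Zr = np.add.reduceat(res[:, None] * cd.Z3, cd.starts, axis=0)
    Q = cd.ZtZ / sigma2 + Vinv
    mu_re = np.linalg.solve(Q, (Zr / sigma2)[:, :, None])[:, :, 0]
    Qinv = np.linalg.inv(Q)
    m_u = mu_re @ eta
    v_u = np.einsum("i,nij,j->n", eta, Qinv, eta)
    v_u = np.maximum(v_u, 1e-12)

    # 1-D Newton for the mode of N(u; m_u, v_u) * exp(delta*u - kappa*e^u)
    kap = np.exp(np.clip(c0, -30, 30)) * H0
    u = m_u.copy()
    for _ in range(25):
        eu = kap * np.exp(np.clip(u, -30, 30))
        g1 = cd.delta - eu - (u - m_u) / v_u
        g2 = -eu - 1.0 / v_u
        step = g1 / g2
        u -= step
        if np.max(np.abs(step)) < cd.cfg.newton_tol:
            break
    c = kap * np.exp(np.clip(u, -30, 30))
    f1 = cd.delta - c

    P = Vinv[None, :, :] + c[:, None, None] * np.outer(eta, eta)[None, :, :]
    S = np.linalg.inv(P)
    m = (S @ (eta[None, :] * (f1 + c * u)[:, None])[:, :, None])[:, :, 0]

    ls_mode = cd.delta * (c0 + u + logh_ev) - c  # survival loglik at the mode
    a0 = ls_mode - f1 * u - 0.5 * c * u ** 2
    mPm = np.einsum("ni,nij,nj->n", m, P, m)
    sign, logdetS = np.linalg.slogdet(S)
    _, logdetV = np.linalg.slogdet(V)
    const = a0 + 0.5 * mPm + 0.5 * (logdetS - logdetV)

    # cumulant correction for the Gaussianized survival factor: closed-form
    # Gaussian moments of the residual q = e^D - 1 - D - D^2/2, rho = -c q
    s2 = 1.0 / (c + 1.0 / v_u)
    e_half, e_two = np.exp(0.5 * s2), np.exp(2.0 * s2)
    Eq1 = e_half - 1.0 - 0.5 * s2
    Eq2 = e_two - e_half * (s2 ** 2 + 3.0 * s2 + 2.0) + 0.75 * s2 ** 2 + 2.0 * s2 + 1.0
    Eq3 = (np.exp(4.5 * s2) - e_two * (6.0 * s2 ** 2 + 7.5 * s2 + 3.0)
           + e_half * (0.75 * s2 ** 4 + 7.5 * s2 ** 3 + 17.25 * s2 ** 2
                       + 12.0 * s2 + 3.0)
           - (1.875 * s2 ** 3 + 6.75 * s2 ** 2 + 4.5 * s2 + 1.0))
    Erho, Erho2, Erho3 = -c * Eq1, c ** 2 * Eq2, -c ** 3 * Eq3
    k2 = np.maximum(Erho2 - Erho ** 2, 0.0)
    k3 = Erho3 - 3.0 * Erho2 * Erho + 2.0 * Erho ** 3
    # asymptotic series: keep the third term only while terms keep shrinking
    use3 = np.abs(k3) / 6.0 < 0.5 * np.abs(k2)
    const = const + Erho + 0.5 * k2 + np.where(use3, k3 / 6.0, 0.0)
    return m, S, const


def _marginal_w_stats(cd: CompiledData, sigma2: float, S: np.ndarray):
    """Per-visit rows of W^{-1}1 and W^{-1}C with W = sigma2 I + Z S Z^T.

    Also returns the per-subject scalars 1'W^{-1}1, C'W^{-1}C and log|W|.
    """
    w1f = np.empty(cd.N)
    wCf = np.empty(cd.N)
    s_alpha = np.empty(cd.n)
    s_gamma = np.empty(cd.n)
    logdetW = np.empty(cd.n)
    for idx, vidx in cd.groups:
        Z = cd.Z3[vidx]                       # (g, k, 3)
        W = np.einsum("gki,gij,glj->gkl", Z, S[idx], Z)
        k = Z.shape[1]
        W[:, np.arange(k), np.arange(k)] += sigma2
        Winv = np.linalg.inv(W)
        Cg = cd.C[vidx]
        w1 = Winv.sum(axis=2)
        wC = np.einsum("gkl,gl->gk", Winv, Cg)
        w1f[vidx] = w1
        wCf[vidx] = wC
        s_alpha[idx] = w1.sum(axis=1)
        s_gamma[idx] = np.einsum("gk,gk->g", Cg, wC)
        logdetW[idx] = np.linalg.slogdet(W)[1]
    return w1f, wCf, s_alpha, s_gamma, logdetW


def laplace_subject_marginal(cd: CompiledData, st: SPState, i: int) -> float:
    """Laplace-marginal log-likelihood of subject ``i``'s data.

    Integrates the random effects out of the product of the longitudinal
    likelihood, the survival likelihood and the random-effect prior, using
    the Gaussian survival-factor replacement of :func:`_laplace_stats`.
    """
    fit = fixed_mean(cd, st)
    m, S, const = _laplace_stats(cd, st, fit)
    sl = slice(cd.starts[i], cd.starts[i] + cd.nvis[i])
    Z = cd.Z3[sl]
    r = cd.y[sl] - fit[sl] - Z @ m[i]
    W = st.sigma2 * np.eye(cd.nvis[i]) + Z @ S[i] @ Z.T
    sign, logdet = np.linalg.slogdet(W)
    sol = np.linalg.solve(W, r)
    return float(const[i] - 0.5 * (cd.nvis[i] * _LOG2PI + logdet + r @ sol))


# ---------------------------------------------------------------------------
# tree step


def _psi_vec(X, s, t, idx, tau2):
    Xs = X[idx]
    A = Xs.T @ (s[idx, None] * Xs)
    b = Xs.T @ t[idx]
    p = X.shape[1]
    M = A + np.eye(p) / tau2
    L = np.linalg.cholesky(M)
    u = solve_triangular(L, b, lower=True, check_finite=False)
    return 0.5 * float(u @ u) - 0.5 * (p * np.log(tau2) + 2.0 * np.log(np.diag(L)).sum())


def _psi_scalar(s, t, idx, tau2):
    a = float(s[idx].sum())
    b = float(t[idx].sum())
    return 0.5 * b * b / (a + 1.0 / tau2) - 0.5 * np.log1p(tau2 * a)


def _leaf_draw_vec(X, s, t, idx, tau2, rng):
    Xs = X[idx]
    p = X.shape[1]
    M = Xs.T @ (s[idx, None] * Xs) + np.eye(p) / tau2
    b = Xs.T @ t[idx]
    L = np.linalg.cholesky(M)
    mean = solve_triangular(L.T, solve_triangular(L, b, lower=True, check_finite=False),
                            lower=False, check_finite=False)
    return mean + solve_triangular(L.T, rng.standard_normal(p), lower=False,
                                   check_finite=False)


def _leaf_draw_scalar(s, t, idx, tau2, rng):
    prec = float(s[idx].sum()) + 1.0 / tau2
    mean = float(t[idx].sum()) / prec
    return mean + rng.standard_normal() / np.sqrt(prec)


def update_trees(cd: CompiledData, st: SPState, prior: TreePrior,
                 scfg: SamplerConfig, rng: np.random.Generator) -> dict:
    """One tree step: b1 birth/death moves per tree, then leaf-coefficient redraws.

    Mutates ``st`` in place; returns acceptance diagnostics.  The marginal
    likelihood ratio integrates both the random effects (Laplace) and the
    proposed leaves' coefficients (conjugate Gaussian).
    """
    tau2 = cd.cfg.prior_scale ** 2
    fit = fixed_mean(cd, st)
    m, S, const = _laplace_stats(cd, st, fit)
    w1f, wCf, s_alpha, s_gamma, logdetW = _marginal_w_stats(cd, st.sigma2, S)
    off = m[cd.subj, 0] + m[cd.subj, 1] * cd.A + m[cd.subj, 2] * cd.C
    sdata = cd.split_data()
    a0x, b0x, g0x, th, z0x = _components(cd, st)
    ssub = cd.subj
    accept = np.zeros(3, dtype=int)

    for k in range(3):
        tree = st.trees[k]
        if k == 0:
            c_k = a0x[ssub]
            wflat, svec, X = w1f, s_alpha, cd.Xa
        elif k == 1:
            c_k = g0x[ssub] * cd.C
            wflat, svec, X = wCf, s_gamma, cd.Xg
        else:
            c_k = th[ssub] * cd.ftau
            wflat = wCf
            svec, X = cd.trt * s_gamma / (1.0 - cd.w) ** 2, None
        r = cd.y - fit - off + c_k
        tvec = np.add.reduceat(wflat * r, cd.starts)
        if k == 2:
            tvec = cd.trt * tvec / (1.0 - cd.w)

        def psi(idx):
            if k == 2:
                return _psi_scalar(svec, tvec, idx, tau2)
            return _psi_vec(X, svec, tvec, idx, tau2)

        labels = st.leaf[k]
        membership = [np.flatnonzero(labels == j) for j in range(tree.n_leaves)]
        psis = [psi(idx) for idx in membership]
        logprior = log_tree_prior(tree, prior)
        ecache: list[dict | None] = [None] * tree.n_leaves
        death_cache: dict[int, dict] = {}

        def merged_elig(pick, merged):
            if pick not in death_cache:
                death_cache[pick] = eligible_splits(merged, prior, sdata)
            return death_cache[pick]

        for _ in range(scfg.b1):
            do_birth = tree.n_leaves == 1 or rng.uniform() < 0.5
            if do_birth:
                j0 = int(rng.integers(tree.n_leaves))
                if ecache[j0] is None:
                    ecache[j0] = eligible_splits(membership[j0], prior, sdata)
                prop = birth_proposal(tree, prior, rng, split_data=sdata,
                                      membership=membership, leaf_index=j0,
                                      elig=ecache[j0])
            else:
                prop = death_proposal(tree, prior, rng, split_data=sdata,
                                      membership=membership, elig_fn=merged_elig)
            if prop is None:
                continue
            new_tree, log_q, info = prop
            j = info["leaf"]
            if info["move"] == "birth":
                mem = membership[j]
                go_left = cd.SX[mem, info["var"]] <= info["cut"]
                mem_l, mem_r = mem[go_left], mem[~go_left]
                new_psis_j = [psi(mem_l), psi(mem_r)]
                dloglik = sum(new_psis_j) - psis[j]
            else:
                merged = np.concatenate([membership[j], membership[j + 1]])
                new_psis_j = [psi(merged)]
                dloglik = new_psis_j[0] - psis[j] - psis[j + 1]
            new_logprior = log_tree_prior(new_tree, prior)
            log_acc = dloglik + (new_logprior - logprior) + log_q
            if np.log(rng.uniform()) < log_acc:
                tree = new_tree
                logprior = new_logprior
                if info["move"] == "birth":
                    membership[j:j + 1] = [mem_l, mem_r]
                    psis[j:j + 1] = new_psis_j
                    ecache[j:j + 1] = [None, None]
                else:
                    membership[j:j + 2] = [merged]
                    psis[j:j + 2] = new_psis_j
                    ecache[j:j + 2] = [None]
                death_cache.clear()
                accept[k] += 1

        # conjugate leaf-coefficient redraw under the marginalized covariance
        J = tree.n_leaves
        st.trees[k] = tree
        labels = np.empty(cd.n, dtype=np.int64)
        for j, idx in enumerate(membership):
            labels[idx] = j
        st.leaf[k] = labels
        if k == 2:
            st.theta = np.array([_leaf_draw_scalar(svec, tvec, idx, tau2, rng)
                                 for idx in membership])
            th = st.theta[labels]
            new_c = th[ssub] * cd.ftau
        else:
            draws = np.stack([_leaf_draw_vec(X, svec, tvec, idx, tau2, rng)
                              for idx in membership])
            if k == 0:
                st.mu0 = draws
                a0x = np.einsum("ij,ij->i", cd.Xa, draws[labels])
                new_c = a0x[ssub]
            else:
                st.mu1 = draws
                g0x = np.einsum("ij,ij->i", cd.Xg, draws[labels])
                new_c = g0x[ssub] * cd.C
        fit = fit - c_k + new_c

    # marginal log-likelihood diagnostic at the final state
    r = cd.y - fit - off
    st.logmarg = float(np.sum(const) + _marginal_quad(cd, st.sigma2, S, r, logdetW))
    return {"accept": accept, "leaves": [t.n_leaves for t in st.trees]}


def _marginal_quad(cd: CompiledData, sigma2, S, r, logdetW) -> float:
    """Sum over subjects of log N(r_i; 0, W_i) given precomputed log|W_i|."""
    total = 0.0
    for idx, vidx in cd.groups:
        Z = cd.Z3[vidx]
        W = np.einsum("gki,gij,glj->gkl", Z, S[idx], Z)
        k = Z.shape[1]
        W[:, np.arange(k), np.arange(k)] += sigma2
        rg = r[vidx]
        sol = np.linalg.solve(W, rg[:, :, None])[:, :, 0]
        total += float(np.sum(rg * sol))
    return -0.5 * (cd.N * _LOG2PI + float(logdetW.sum()) + total)


# ---------------------------------------------------------------------------
# parameter (SP) step


def _wishart(df: float, scale: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Bartlett-decomposition Wishart draw."""
    p = scale.shape[0]
    L = np.linalg.cholesky(scale)
    A = np.zeros((p, p))
    for i in range(p):
        A[i, i] = np.sqrt(rng.chisquare(df - i))
        for j in range(i):
            A[i, j] = rng.standard_normal()
    LA = L @ A
    return LA @ LA.T


def update_sp_params(cd: CompiledData, st: SPState, scfg: SamplerConfig,
                     rng: np.random.Generator, collect=None) -> dict:
    """Inner chain of b1 Metropolis-within-Gibbs sweeps over non-tree parameters.

    All coefficient blocks (leaf and global) are drawn jointly from their
    conjugate Gaussian full conditional; random effects use an independence
    proposal from their longitudinal-conditional Gaussian corrected by the
    survival factor; the variance components are conjugate; the hazard
    levels and (lambda0, eta1, eta2) use Laplace independence proposals on
    their log-concave conditionals.  Keeps the final state (the first half
    of the sweeps counts as warmup when collecting inner draws).
    """
    cfg = cd.cfg
    tau2 = cfg.prior_scale ** 2
    ssub = cd.subj
    J0, J1, J2 = (t.n_leaves for t in st.trees)
    mem2 = [np.flatnonzero(st.leaf[2] == j) for j in range(J2)]

    # one flat design for every fixed-effect block (leaf structure is fixed)
    pa, pb, pg, pz = (cd.Xa.shape[1], cd.Xb.shape[1], cd.Xg.shape[1],
                      cd.Xz.shape[1])
    cols = []
    lab0, lab1, lab2 = (st.leaf[k][ssub] for k in range(3))
    for j in range(J0):
        cols.append(cd.Xa[ssub] * (lab0 == j)[:, None])
    cols.append(cd.Xb[ssub] * cd.A[:, None])
    for j in range(J1):
        cols.append(cd.Xg[ssub] * (cd.C * (lab1 == j))[:, None])
    for j in range(J2):
        cols.append((cd.ftau * (lab2 == j))[:, None])
    cols.append(cd.Xz[ssub] * cd.fzeta[:, None])
    F = np.hstack(cols)
    P = F.shape[1]
    FtF = F.T @ F
    eyeP = np.eye(P)

    def unpack(beta):
        pos = 0
        st.mu0 = beta[pos:pos + J0 * pa].reshape(J0, pa); pos += J0 * pa
        st.mu3 = beta[pos:pos + pb]; pos += pb
        st.mu1 = beta[pos:pos + J1 * pg].reshape(J1, pg); pos += J1 * pg
        st.theta = beta[pos:pos + J2]; pos += J2
        st.mu4 = beta[pos:pos + pz]

    c_re = re_mean(cd, st.re)
    fit_fixed = fixed_mean(cd, st)
    accept_re = 0
    warmup = scfg.b1 // 2
    hz = st.hz

    for it in range(scfg.b1):
        sigma2 = st.sigma2

        # --- all coefficient blocks, jointly ----------------------------
        r = cd.y - c_re
        Fr = F.T @ r
        M = FtF / sigma2 + eyeP / tau2
        L = np.linalg.cholesky(M)
        mean = solve_triangular(L.T, solve_triangular(L, Fr / sigma2, lower=True,
                                                      check_finite=False),
                                check_finite=False)
        beta = mean + solve_triangular(L.T, rng.standard_normal(P),
                                       check_finite=False)
        unpack(beta)
        fit_fixed = F @ beta

        # --- random effects ---------------------------------------------
        Vinv = np.linalg.inv(sigma2 * st.Sigma)
        res = cd.y - fit_fixed
        Zr = np.add.reduceat(res[:, None] * cd.Z3, cd.starts, axis=0)
        Q = cd.ZtZ / sigma2 + Vinv
        Lq = np.linalg.cholesky(Q)
        mean_re = np.linalg.solve(Q, (Zr / sigma2)[:, :, None])[:, :, 0]
        eps = rng.standard_normal((cd.n, 3))
        prop = mean_re + np.linalg.solve(np.transpose(Lq, (0, 2, 1)),
                                         eps[:, :, None])[:, :, 0]
        H0 = cd.E @ np.exp(hz.log_levels)
        base = np.exp(np.clip(hz.lambda0 * cd.trt, -30, 30)) * H0
        u_old = hz.eta1 * st.re[:, 0] + hz.eta2 * st.re[:, 2]
        u_new = hz.eta1 * prop[:, 0] + hz.eta2 * prop[:, 2]
        log_acc = (cd.delta * (u_new - u_old)
                   - base * (np.exp(np.clip(u_new, -30, 30))
                             - np.exp(np.clip(u_old, -30, 30))))
        take = np.log(rng.uniform(size=cd.n)) < log_acc
        st.re[take] = prop[take]
        accept_re += int(take.sum())
        c_re = re_mean(cd, st.re)

        # --- variance components ----------------------------------------
        resid = res - c_re
        quad = float(np.einsum("ni,ij,nj->", st.re, np.linalg.inv(st.Sigma),
                               st.re))
        shape = cfg.a0 + 0.5 * (cd.N + 3 * cd.n)
        rate = cfg.b0 + 0.5 * (float(resid @ resid) + quad)
        st.sigma2 = 1.0 / rng.gamma(shape, 1.0 / rate)
        Sre = st.re.T @ st.re
        scale = np.linalg.inv(cfg.b0 * np.eye(3) + Sre / st.sigma2)
        W = _wishart(3.0 + cfg.a0 + cd.n, scale, rng)
        st.Sigma = np.linalg.inv(W)

        # --- survival block ---------------------------------------------
        zfull = np.exp(np.clip(hz.lambda0 * cd.trt
                               + hz.eta1 * st.re[:, 0] + hz.eta2 * st.re[:, 2],
                               -30, 30))
        R = zfull @ cd.E
        lam = hz.log_levels.copy()
        mode = lam.copy()
        for _ in range(5):
            el = np.exp(mode)
            g2 = el * R + 1.0 / tau2
            mode += (cd.d_k - el * R - mode / tau2) / g2
        var = 1.0 / (np.exp(mode) * R + 1.0 / tau2)
        lam_p = mode + np.sqrt(var) * rng.standard_normal(cfg.K)

        def ell_lam(l):
            return cd.d_k * l - np.exp(l) * R - l ** 2 / (2 * tau2)

        log_acc = (ell_lam(lam_p) - ell_lam(lam)
                   + (lam_p - mode) ** 2 / (2 * var)
                   - (lam - mode) ** 2 / (2 * var))
        take = np.log(rng.uniform(size=cfg.K)) < log_acc
        lam[take] = lam_p[take]
        hz.log_levels = lam

        H0 = cd.E @ np.exp(lam)
        Xs = np.column_stack([cd.trt, st.re[:, 0], st.re[:, 2]])
        psi = np.array([hz.lambda0, hz.eta1, hz.eta2])

        def ell_psi(p):
            u = Xs @ p
            return float(cd.delta @ u - np.exp(np.clip(u, -30, 30)) @ H0
                         - p @ p / (2 * tau2))

        pm = psi.copy()
        for _ in range(5):
            mvec = np.exp(np.clip(Xs @ pm, -30, 30)) * H0
            grad = Xs.T @ (cd.delta - mvec) - pm / tau2
            Hess = -(Xs.T * mvec) @ Xs - np.eye(3) / tau2
            pm = pm - np.linalg.solve(Hess, grad)
        Hm = (Xs.T * (np.exp(np.clip(Xs @ pm, -30, 30)) * H0)) @ Xs \
            + np.eye(3) / tau2
        Lh = np.linalg.cholesky(Hm)
        psi_p = pm + solve_triangular(Lh.T, rng.standard_normal(3),
                                      check_finite=False)

        def logq(p):
            d = p - pm
            return -0.5 * float(d @ Hm @ d)

        if np.log(rng.uniform()) < (ell_psi(psi_p) - ell_psi(psi)
                                    + logq(psi) - logq(psi_p)):
            hz.lambda0, hz.eta1, hz.eta2 = psi_p

        if collect is not None and it >= warmup:
            b0x = cd.Xb @ st.mu3
            g0x = np.einsum("ij,ij->i", cd.Xg, st.mu1[st.leaf[1]])
            cs = cd.w * b0x + (1.0 - cd.w) * g0x
            leaf_cs = np.array([float(cs[idx].mean()) for idx in mem2])
            collect.append({"theta": st.theta.copy(), "control_slope": leaf_cs})

    return {"accept_re": accept_re / (cd.n * scfg.b1)}


# ---------------------------------------------------------------------------
# chain driver


@dataclass
class ChainResult:
    draws: list[SPState]
    diagnostics: pd.DataFrame
    inner: list[dict]
    prior: TreePrior
    compiled: CompiledData


def run_chain(data: TrialDataset, cfg: ModelConfig, scfg: SamplerConfig,
              rng: np.random.Generator, grids=None, grid_names=None,
              init_trees=None, update_tree_structure: bool = True) -> ChainResult:
    """Run b2 round-trips and return the retained draws.

    ``init_trees`` with ``update_tree_structure=False`` freezes the tree
    structures (honest refits); only parameters are then updated and, when
    ``scfg.keep_inner`` is set, every post-warmup inner draw of the
    treatment-effect block is retained for interval summaries.
    """
    cd = CompiledData(data, cfg, grids=grids, grid_names=grid_names)
    prior = make_tree_prior(cd, cfg)
    st = init_state(cd, cfg, init_trees=init_trees)
    draws: list[SPState] = []
    diag_rows = []
    inner: list[dict] = []
    for b in range(scfg.b2):
        collect = inner if (scfg.keep_inner and not update_tree_structure) else None
        d1 = update_sp_params(cd, st, scfg, rng, collect=collect)
        if update_tree_structure:
            d2 = update_trees(cd, st, prior, scfg, rng)
        else:
            d2 = {"accept": np.zeros(3, int), "leaves": [t.n_leaves for t in st.trees]}
            st.logmarg = np.nan
        draws.append(st.light_copy())
        diag_rows.append({"iter": b, "accept_re": d1["accept_re"],
                          "accept_trees": int(np.sum(d2["accept"])),
                          "J0": d2["leaves"][0], "J1": d2["leaves"][1],
                          "J2": d2["leaves"][2], "logmarg": st.logmarg})
    return ChainResult(draws=draws, diagnostics=pd.DataFrame(diag_rows),
                       inner=inner, prior=prior, compiled=cd)


# ---------------------------------------------------------------------------
# prior-only tree chain (calibration checks)


def prior_tree_chain(prior: TreePrior, n_draws: int, rng: np.random.Generator,
                     thin: int = 10) -> list[DecisionTree]:
    """Birth/death chain targeting the tree prior alone (no data).

    Used to verify the sampler against the analytic prior, e.g. the 5%
    root-only mass under c0=0.95, d0=2.
    """
    tree = DecisionTree()
    out = []
    logprior = log_tree_prior(tree, prior)
    for i in range(n_draws * thin):
        do_birth = tree.n_leaves == 1 or rng.uniform() < 0.5
        prop = (birth_proposal if do_birth else death_proposal)(tree, prior, rng)
        if prop is not None:
            new_tree, log_q, _ = prop
            new_logprior = log_tree_prior(new_tree, prior)
            if np.log(rng.uniform()) < new_logprior - logprior + log_q:
                tree, logprior = new_tree, new_logprior
        if (i + 1) % thin == 0:
            out.append(tree.copy())
    return out
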