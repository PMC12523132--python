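"""Honest subgroup workflow.

Tree structures are *discovered* on 60% of the subjects and subgroup effects
are *estimated* on the held-out 40%, so that the reported credible intervals
are not distorted by the adaptive splitting.  The workflow is repeated over
``b3`` random splits; each split's retained posterior draws are summarized
by the "most representative" tree (the draw whose treatment-effect surface
is closest, in mean squared difference over discovery subjects, to the
posterior-mean surface), and the modal representative tree across splits —
the "super-representative" tree — defines the reported subgroups.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import HonestConfig, ModelConfig, SamplerConfig
from .data_model import TrialDataset, split_dataset
from .sampler import ChainResult, SPState, run_chain
from .trees import DecisionTree, build_cutpoint_grid

__all__ = [
    "RepresentativeTree",
    "HteReport",
    "most_representative_tree",
    "super_representative_tree",
    "intersection_tree",
    "honest_refit",
    "ordering_probability",
    "concordance_summary",
    "honest_pipeline",
]


@dataclass
class RepresentativeTree:
    """A retained draw selected as closest to the posterior-mean surface."""

    tree: DecisionTree
    leaf_params: np.ndarray
    distance: float
    draw_index: int
    source_split: int = -1


def _surfaces(draws: list[SPState], result: ChainResult, kind: str) -> np.ndarray:
    cd = result.compiled
    if kind == "tau0":
        return np.stack([d.theta[d.leaf[2]] for d in draws])
    if kind == "alpha0":
        return np.stack([np.einsum("ij,ij->i", cd.Xa, d.mu0[d.leaf[0]]) for d in draws])
    if kind == "gamma0":
        return np.stack([np.einsum("ij,ij->i", cd.Xg, d.mu1[d.leaf[1]]) for d in draws])
    raise ValueError(f"unknown surface kind {kind!r}")


def most_representative_tree(result: ChainResult, kind: str = "tau0",
                             source_split: int = -1) -> RepresentativeTree:
    """Minimum-distance tree among the retained draws.

    Distance of draw *b* is ``sum_i (surface_b(x_i) - mean_surface(x_i))^2``
    over discovery subjects; ties go to the draw with fewer leaves, then to
    canonical tree order.
    """
    draws = result.draws
    if not draws:
        raise ValueError("no retained draws")
    surf = _surfaces(draws, result, kind)
    dist = ((surf - surf.mean(axis=0)) ** 2).sum(axis=1)
    k = {"tau0": 2, "alpha0": 0, "gamma0": 1}[kind]
    order = sorted(range(len(draws)),
                   key=lambda b: (dist[b], draws[b].trees[k].n_leaves,
                                  draws[b].trees[k].canonical_key()))
    b = order[0]
    params = (draws[b].theta if kind == "tau0"
              else (draws[b].mu0 if kind == "alpha0" else draws[b].mu1))
    return RepresentativeTree(tree=draws[b].trees[k].copy(), leaf_params=np.array(params),
                              distance=float(dist[b]), draw_index=b,
                              source_split=source_split)


def super_representative_tree(rep_trees: list[RepresentativeTree]):
    """Modal tree (by canonical structure) among the representative trees.

    Returns ``(representative, frequency, counts)`` where ``representative``
    is the first matching :class:`RepresentativeTree` instance, ``frequency``
    its share of the splits, and ``counts`` the full frequency table.  Ties
    are broken toward fewer leaves, then canonical order.
    """
    if not rep_trees:
        raise ValueError("no representative trees supplied")
    counts: dict = {}
    first: dict = {}
    for rt in rep_trees:
        key = rt.tree.canonical_key()
        counts[key] = counts.get(key, 0) + 1
        first.setdefault(key, rt)
    best = sorted(counts, key=lambda k: (-counts[k], first[k].tree.n_leaves, k))[0]
    freq = counts[best] / len(rep_trees)
    return first[best], freq, counts


def intersection_tree(bt0: DecisionTree, bt1: DecisionTree, bt2: DecisionTree,
                      SX: np.ndarray) -> np.ndarray:
    """Cell labels of the intersection partition of three trees.

    Cells are the nonempty intersections of the trees' leaf regions, judged
    on the supplied covariate sample; labels are 0-based and contiguous.
    The partition refines each input tree's partition.
    """
    a = np.stack([bt0.assign(SX), bt1.assign(SX), bt2.assign(SX)], axis=1)
    _, labels = np.unique(a, axis=0, return_inverse=True)
    return labels


def ordering_probability(theta_a, theta_b, paired: bool | None = None) -> float:
    """Posterior probability that effect A exceeds effect B.

    With paired draws (same chain), the indexwise fraction of draws with
    ``theta_a > theta_b``; exact ties count one half.  With independent
    pooling, the all-pairs (Mann-Whitney-type) fraction with the same tie
    convention, so identical draw sets give exactly 0.5.
    """
    a = np.asarray(theta_a, float).ravel()
    b = np.asarray(theta_b, float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("no posterior draws supplied")
    if paired is None:
        paired = a.size == b.size
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison needs equal draw counts")
        return float(np.mean((a > b) + 0.5 * (a == b)))
    order = np.sort(b)
    hi = np.searchsorted(order, a, side="left")
    lo = np.searchsorted(order, a, side="right")
    return float(np.mean(hi + 0.5 * (lo - hi)) / b.size)


def concordance_summary(splits: list[dict], rng: np.random.Generator | None = None
                        ) -> pd.DataFrame:
    """Validation-set effects by discovery-CATE tertile, one row per split.

    Each element of ``splits`` supplies ``disc_cate`` (validation subjects'
    effects under the discovery-set representative tree) and ``val_cate``
    (their honest validation estimates).  Ties in the tertile ranking are
    broken at random under the supplied generator.
    """
    rng = rng or np.random.default_rng(0)
    rows = []
    for s, item in enumerate(splits):
        disc = np.asarray(item["disc_cate"], float)
        val = np.asarray(item["val_cate"], float)
        jitter = rng.uniform(size=len(disc))
        order = np.lexsort((jitter, disc))
        tert = np.empty(len(disc), dtype=int)
        tert[order] = np.minimum(np.arange(len(disc)) * 3 // max(len(disc), 1), 2)
        row = {"split": s}
        for t in range(3):
            row[f"tertile{t + 1}"] = float(val[tert == t].mean()) if np.any(tert == t) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RefitResult:
    """Honest per-leaf posteriors from a frozen-tree validation refit."""

    theta_draws: np.ndarray          # (draws, J2)
    control_slope_draws: np.ndarray  # (draws, J2)
    leaf_sizes: np.ndarray
    uncensored_prop: np.ndarray
    estimable: np.ndarray
    result: ChainResult


def honest_refit(validation_data: TrialDataset, fixed_trees: list[DecisionTree],
                 cfg: ModelConfig, scfg: SamplerConfig, rng: np.random.Generator,
                 grids=None, grid_names=None) -> RefitResult:
    """Refit the shared-parameter model on validation data with trees frozen.

    Only parameters are updated; every post-warmup inner draw of the
    treatment-effect block is retained.  Leaves lacking either arm in the
    validation set are flagged non-estimable.
    """
    scfg = SamplerConfig(b1=scfg.b1, b2=scfg.b2, keep_inner=True)
    res = run_chain(validation_data, cfg, scfg, rng, grids=grids,
                    grid_names=grid_names, init_trees=fixed_trees,
                    update_tree_structure=False)
    cd = res.compiled
    leaf2 = res.draws[-1].leaf[2]
    J = fixed_trees[2].n_leaves
    sizes = np.bincount(leaf2, minlength=J)
    unc = np.array([cd.delta[leaf2 == j].mean() if sizes[j] else np.nan for j in range(J)])
    est = np.array([bool(sizes[j]) and 0 < cd.trt[leaf2 == j].sum() < sizes[j]
                    for j in range(J)])
    theta = np.stack([row["theta"] for row in res.inner]) if res.inner else \
        np.stack([d.theta for d in res.draws])
    cslope = np.stack([row["control_slope"] for row in res.inner]) if res.inner else \
        np.full_like(theta, np.nan)
    return RefitResult(theta_draws=theta, control_slope_draws=cslope,
                       leaf_sizes=sizes, uncensored_prop=unc, estimable=est,
                       result=res)


@dataclass
class HteReport:
    """Pipeline output: super-representative tree and honest leaf summaries."""

    super_tree: DecisionTree
    frequency: float
    counts: dict
    rep_trees: list[RepresentativeTree]
    leaf_table: pd.DataFrame
    theta_draws: np.ndarray
    ordering: pd.DataFrame
    val_data: TrialDataset
    tau_hat_val: np.ndarray
    refit_splits: list[int]
    concordance: pd.DataFrame | None = None
    grid_names: list[str] | None = None


def honest_pipeline(data: TrialDataset, cfg: ModelConfig, scfg: SamplerConfig,
                    hcfg: HonestConfig, rng: np.random.Generator,
                    concordance: bool = False) -> HteReport:
    """Full honest analysis: b3 splits, chains, representative and super trees,
    frozen-tree validation refit, and per-leaf honest summaries.

    Cutpoint grids are computed once from the full covariate table (covariates
    only — no outcome data) and shared across splits so that representative
    trees live in a common finite space and can be counted.
    """
    split_cols = data.spec.role_columns("split")
    grids, grid_names = build_cutpoint_grid(data.cov, split_cols, cfg.n_cuts)

    reps: list[RepresentativeTree] = []
    rep_all: list[dict] = []
    for s in range(hcfg.b3):
        seed = int(rng.integers(2 ** 31 - 1))
        disc, val = split_dataset(data, hcfg.frac_discovery, seed)
        res = run_chain(disc, cfg, scfg, rng, grids=grids, grid_names=grid_names)
        rt = most_representative_tree(res, "tau0", source_split=s)
        reps.append(rt)
        rep_all.append({
            "split": s, "disc": disc, "val": val,
            "alpha": most_representative_tree(res, "alpha0", source_split=s),
            "gamma": most_representative_tree(res, "gamma0", source_split=s),
            "tau": rt,
        })

    super_rep, freq, counts = super_representative_tree(reps)
    key = super_rep.tree.canonical_key()
    match = [r for r in rep_all if r["tau"].tree.canonical_key() == key]
    refit_splits = [m["split"] for m in (match if hcfg.refit_all else match[:1])]

    rcfg = hcfg.refit or scfg
    refits = []
    for m in match[: len(refit_splits)]:
        trees = [m["alpha"].tree, m["gamma"].tree, super_rep.tree]
        refits.append(honest_refit(m["val"], trees, cfg, rcfg, rng,
                                   grids=grids, grid_names=grid_names))

    J = super_rep.tree.n_leaves
    theta = np.vstack([rf.theta_draws for rf in refits])
    cslope = np.vstack([rf.control_slope_draws for rf in refits])
    e_n = np.mean([rf.leaf_sizes for rf in refits], axis=0)
    e_p = np.nanmean(np.stack([rf.uncensored_prop for rf in refits]), axis=0)
    estimable = np.all([rf.estimable for rf in refits], axis=0)
    mean = theta.mean(axis=0)
    lo, hi = np.percentile(theta, [2.5, 97.5], axis=0)
    cs = np.nanmean(cslope, axis=0)
    leaf_table = pd.DataFrame({
        "leaf": np.arange(J), "E_n": e_n, "E_p": e_p,
        "control_slope": cs, "treatment_slope": cs + mean,
        "effect_mean": mean, "ci_low": lo, "ci_high": hi,
        "estimable": estimable,
    })

    pairs = []
    for a in range(J):
        for b in range(J):
            if a != b:
                pairs.append({"leaf_a": a, "leaf_b": b,
                              "prob": ordering_probability(theta[:, a], theta[:, b])})
    ordering = pd.DataFrame(pairs) if pairs else pd.DataFrame(
        columns=["leaf_a", "leaf_b", "prob"])

    # honest CATE estimates on the refit split's validation set
    first = match[0]
    val = first["val"]
    val_sx = np.column_stack([val.cov[c].to_numpy(dtype=float) for c in grid_names])
    leaf_val = super_rep.tree.assign(val_sx)
    tau_leaf = np.where(estimable, mean, float(np.average(mean, weights=np.maximum(e_n, 1))))
    tau_hat_val = tau_leaf[leaf_val]

    conc = None
    if concordance:
        items = []
        for m, rf in zip(match[: len(refit_splits)], refits):
            vsx = np.column_stack([m["val"].cov[c].to_numpy(dtype=float) for c in grid_names])
            disc_cate = m["tau"].leaf_params[m["tau"].tree.assign(vsx)]
            val_cate = rf.theta_draws.mean(axis=0)[super_rep.tree.assign(vsx)]
            items.append({"disc_cate": disc_cate, "val_cate": val_cate})
        conc = concordance_summary(items, rng)

    return HteReport(super_tree=super_rep.tree, frequency=freq, counts=counts,
                     rep_trees=reps, leaf_table=leaf_table, theta_draws=theta,
                     ordering=ordering, val_data=val, tau_hat_val=tau_hat_val,
                     refit_splits=refit_splits, concordance=conc,
                     grid_names=list(grid_names))
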