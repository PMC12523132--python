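"""Bayesian decision trees with birth/death Metropolis-Hastings proposals.

A tree partitions the covariate space with axis-aligned rules drawn from a
frozen, finite grid of candidate cutpoints, so the space of reachable trees
is finite and trees can be compared and counted across runs.  The prior
penalizes depth: a node at depth D splits with probability
``c0 * (1 + D) ** -d0`` and the split variable and cutpoint are uniform over
the pre-specified grid.  Only birth (split a leaf) and death (collapse a
pair of sibling leaves) moves are used.

Routing convention: ``x[var] <= cut`` goes left; ties go left.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Node",
    "DecisionTree",
    "TreePrior",
    "SplitData",
    "build_cutpoint_grid",
    "log_tree_prior",
    "leaf_assign",
    "predict_surface",
    "birth_proposal",
    "death_proposal",
]


@dataclass
class Node:
    var: int | None = None
    cut_idx: int | None = None
    cut: float | None = None
    left: "Node | None" = None
    right: "Node | None" = None
    depth: int = 0

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def copy(self) -> "Node":
        if self.is_leaf:
            return Node(depth=self.depth)
        return Node(var=self.var, cut_idx=self.cut_idx, cut=self.cut,
                    left=self.left.copy(), right=self.right.copy(), depth=self.depth)


class DecisionTree:
    """Binary decision tree; leaves are numbered left-to-right from 0."""

    def __init__(self, root: Node | None = None):
        self.root = root if root is not None else Node()

    # -- structure queries ------------------------------------------------
    def leaves(self) -> list[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            nd = stack.pop()
            if nd.is_leaf:
                out.append(nd)
            else:
                stack.extend([nd.right, nd.left])
        return out

    def internal(self) -> list[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            nd = stack.pop()
            if not nd.is_leaf:
                out.append(nd)
                stack.extend([nd.right, nd.left])
        return out

    def prunable(self) -> list[Node]:
        """Internal nodes whose children are both leaves."""
        return [nd for nd in self.internal() if nd.left.is_leaf and nd.right.is_leaf]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def copy(self) -> "DecisionTree":
        return DecisionTree(self.root.copy())

    # -- routing ----------------------------------------------------------
    def assign(self, SX: np.ndarray) -> np.ndarray:
        """Leaf index (left-to-right, 0-based) for each row of the split design."""
        SX = np.atleast_2d(np.asarray(SX, dtype=float))
        labels = np.zeros(len(SX), dtype=np.int64)
        self._assign(self.root, np.arange(len(SX)), SX, labels, [0])
        return labels

    def _assign(self, node: Node, idx: np.ndarray, SX: np.ndarray,
                labels: np.ndarray, counter: list[int]) -> None:
        if node.is_leaf:
            labels[idx] = counter[0]
            counter[0] += 1
            return
        if not np.all(np.isfinite(SX[idx, node.var])):
            raise ValueError("cannot route observations with missing split-variable values")
        go_left = SX[idx, node.var] <= node.cut
        self._assign(node.left, idx[go_left], SX, labels, counter)
        self._assign(node.right, idx[~go_left], SX, labels, counter)

    # -- identity / serialization ----------------------------------------
    def canonical_key(self):
        def key(nd: Node):
            if nd.is_leaf:
                return ("L",)
            return ("S", nd.var, nd.cut_idx, float(nd.cut),
                    key(nd.left), key(nd.right))
        return key(self.root)

    def to_dict(self, var_names: list[str] | None = None) -> dict:
        def rec(nd: Node, leaf_counter: list[int]):
            if nd.is_leaf:
                lid = leaf_counter[0]
                leaf_counter[0] += 1
                return {"leaf_id": lid}
            name = var_names[nd.var] if var_names else nd.var
            return {"var": name, "var_index": nd.var, "cut": float(nd.cut),
                    "cut_idx": int(nd.cut_idx),
                    "left": rec(nd.left, leaf_counter), "right": rec(nd.right, leaf_counter)}
        return rec(self.root, [0])

    @classmethod
    def from_dict(cls, d: dict) -> "DecisionTree":
        def rec(obj: dict, depth: int) -> Node:
            if "leaf_id" in obj:
                return Node(depth=depth)
            return Node(var=int(obj["var_index"]), cut_idx=int(obj["cut_idx"]),
                        cut=float(obj["cut"]), depth=depth,
                        left=rec(obj["left"], depth + 1), right=rec(obj["right"], depth + 1))
        return cls(rec(d, 0))

    def to_json(self, var_names=None) -> str:
        return json.dumps(self.to_dict(var_names), indent=1, sort_keys=True)


@dataclass
class TreePrior:
    """Depth prior plus the frozen cutpoint grids of the split variables."""

    grids: list[np.ndarray]
    c0: float = 0.95
    d0: float = 2.0
    min_leaf: int = 25
    max_depth: int | None = None
    var_names: list[str] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.c0 < 1.0:
            raise ValueError("c0 must lie in (0, 1)")
        if self.d0 < 0:
            raise ValueError("d0 must be non-negative")
        self.grids = [np.asarray(g, dtype=float) for g in self.grids]

    @property
    def n_vars(self) -> int:
        return len(self.grids)

    def p_split(self, depth: int) -> float:
        if self.max_depth is not None and depth >= self.max_depth:
            return 0.0
        return self.c0 * (1.0 + depth) ** (-self.d0)


@dataclass
class SplitData:
    """Discovery-set information constraining proposals: split design, arms, leaf size."""

    SX: np.ndarray
    trt: np.ndarray
    min_leaf: int = 25


def build_cutpoint_grid(covariates, variables=None, n_cuts: int = 9):
    """Frozen candidate cutpoints per split variable.

    Continuous variables get ``n_cuts`` interior quantiles (deciles by
    default) of the supplied sample; binary variables get the single
    midpoint cutpoint.  Constant columns are excluded with a warning (their
    grid is empty).  Returns ``(grids, names)``.
    """
    if hasattr(covariates, "columns"):
        names = list(variables) if variables is not None else [
            c for c in covariates.columns if c not in ("subject_id", "trt")]
        cols = [covariates[v].to_numpy(dtype=float) for v in names]
    else:
        arr = np.atleast_2d(np.asarray(covariates, dtype=float))
        idx = list(variables) if variables is not None else list(range(arr.shape[1]))
        names = [str(i) for i in idx]
        cols = [arr[:, i] for i in idx]
    grids = []
    for name, col in zip(names, cols):
        vals = np.unique(col)
        if len(vals) < 2:
            warnings.warn(f"split variable {name!r} is constant; excluded from splitting")
            grids.append(np.empty(0))
        elif len(vals) == 2:
            grids.append(np.array([vals.mean()]))
        else:
            qs = np.quantile(col, np.arange(1, n_cuts + 1) / (n_cuts + 1), method="linear")
            grids.append(np.unique(qs))
    return grids, names


def log_tree_prior(tree: DecisionTree, prior: TreePrior) -> float:
    """Log prior: depth-penalized structure plus uniform variable/cutpoint terms."""
    logp = 0.0
    stack = [tree.root]
    while stack:
        nd = stack.pop()
        ps = prior.p_split(nd.depth)
        if nd.is_leaf:
            if ps >= 1.0:
                return -np.inf
            logp += np.log1p(-ps)
        else:
            if ps <= 0.0 or len(prior.grids[nd.var]) == 0:
                return -np.inf
            logp += np.log(ps) - np.log(prior.n_vars) - np.log(len(prior.grids[nd.var]))
            stack.extend([nd.left, nd.right])
    return float(logp)


def leaf_assign(tree: DecisionTree, x) -> int | np.ndarray:
    """Leaf index for a single covariate vector or a matrix of them."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return int(tree.assign(x[None, :])[0])
    return tree.assign(x)


def predict_surface(tree: DecisionTree, leaf_params, x_design, x_split, kind: str):
    """Evaluate a tree-structured surface.

    ``kind`` in {"alpha0", "gamma0"}: within-leaf linear form ``x . mu_leaf``
    (``leaf_params`` is (J, p)).  ``kind == "tau0"``: piecewise-constant
    ``theta_leaf`` (``leaf_params`` is (J,)).
    """
    if kind not in ("alpha0", "gamma0", "tau0"):
        raise ValueError(f"unknown surface kind {kind!r}")
    x_split = np.atleast_2d(np.asarray(x_split, dtype=float))
    leaf = tree.assign(x_split)
    params = np.asarray(leaf_params, dtype=float)
    if kind == "tau0":
        if params.ndim != 1 or len(params) != tree.n_leaves:
            raise ValueError("tau0 needs one scalar per leaf")
        return params[leaf]
    x_design = np.atleast_2d(np.asarray(x_design, dtype=float))
    if params.shape != (tree.n_leaves, x_design.shape[1]):
        raise ValueError("leaf coefficient block does not match design dimension")
    return np.einsum("ij,ij->i", x_design, params[leaf])


# ---------------------------------------------------------------------------
# birth / death proposals


def _p_birth(tree: DecisionTree) -> float:
    return 1.0 if tree.n_leaves == 1 else 0.5


def eligible_splits(members: np.ndarray, prior: TreePrior,
                    split_data: SplitData | None):
    """Eligible (variable -> cut indices) for splitting a leaf holding ``members``.

    Without data constraints (prior-only chains) every nonempty grid is
    eligible.  With data, each child must hold at least ``min_leaf`` subjects
    and contain both treatment arms, so within-leaf effects stay estimable.
    """
    out: dict[int, np.ndarray] = {}
    if split_data is None:
        for v, grid in enumerate(prior.grids):
            if len(grid):
                out[v] = np.arange(len(grid))
        return out
    SX = split_data.SX[members]
    trt = split_data.trt[members]
    n = len(members)
    treated = trt == 1
    for v, grid in enumerate(prior.grids):
        if len(grid) == 0:
            continue
        vals = SX[:, v]
        left = vals[:, None] <= grid[None, :]
        n_left = left.sum(axis=0)
        t_left = (left & treated[:, None]).sum(axis=0)
        n_right = n - n_left
        t_right = treated.sum() - t_left
        ok = ((n_left >= split_data.min_leaf) & (n_right >= split_data.min_leaf)
              & (t_left > 0) & (t_right > 0)
              & (n_left - t_left > 0) & (n_right - t_right > 0))
        if ok.any():
            out[v] = np.flatnonzero(ok)
    return out


def birth_proposal(tree: DecisionTree, prior: TreePrior, rng: np.random.Generator,
                   split_data: SplitData | None = None,
                   membership: list[np.ndarray] | None = None,
                   leaf_index: int | None = None, elig: dict | None = None):
    """Propose splitting a uniformly chosen leaf.

    Returns ``(new_tree, log_q_ratio, info)`` where ``log_q_ratio`` is
    ``log q(T'->T) - log q(T->T')`` (the proposal part of the Hastings
    ratio) and ``info = {"move": "birth", "leaf": j, "var": v, "cut_idx": c,
    "cut": value, "depth": D}``; ``None`` if the chosen leaf admits no
    eligible split (a null iteration).  ``leaf_index``/``elig`` let a caller
    supply the chosen leaf and its cached eligibility.
    """
    leaves = tree.leaves()
    j = int(rng.integers(len(leaves))) if leaf_index is None else leaf_index
    leaf = leaves[j]
    if prior.max_depth is not None and leaf.depth >= prior.max_depth:
        return None
    if elig is None:
        members = membership[j] if membership is not None else None
        if split_data is not None and members is None:
            raise ValueError("split_data requires leaf membership")
        elig = (eligible_splits(members, prior, split_data)
                if split_data is not None
                else eligible_splits(np.empty(0, dtype=int), prior, None))
    if not elig:
        return None
    vars_ = sorted(elig)
    v = vars_[int(rng.integers(len(vars_)))]
    cuts = elig[v]
    c = int(cuts[int(rng.integers(len(cuts)))])

    new = tree.copy()
    target = new.leaves()[j]
    target.var, target.cut_idx, target.cut = v, c, float(prior.grids[v][c])
    target.left = Node(depth=target.depth + 1)
    target.right = Node(depth=target.depth + 1)

    log_fwd = (np.log(_p_birth(tree)) - np.log(len(leaves))
               - np.log(len(vars_)) - np.log(len(cuts)))
    log_rev = np.log(0.5) - np.log(len(new.prunable()))
    info = {"move": "birth", "leaf": j, "var": v, "cut_idx": c,
            "cut": float(prior.grids[v][c]), "depth": leaf.depth}
    return new, float(log_rev - log_fwd), info


def death_proposal(tree: DecisionTree, prior: TreePrior, rng: np.random.Generator,
                   split_data: SplitData | None = None,
                   membership: list[np.ndarray] | None = None,
                   elig_fn=None):
    """Propose collapsing a uniformly chosen leaf-pair parent (reverse of birth).

    Returns ``(new_tree, log_q_ratio, info)`` with ``info["leaf"]`` the
    left-to-right index of the collapsed node's left child; ``None`` for a
    root-only tree (move unavailable).  ``elig_fn(j, merged_members)`` may
    supply cached eligibility of the merged leaf.
    """
    prunable = tree.prunable()
    if not prunable:
        return None
    pick = int(rng.integers(len(prunable)))

    new = tree.copy()
    # locate the matching node in the copy and its left child's leaf index
    target = new.prunable()[pick]
    j = 0
    for nd in new.leaves():
        if nd is target.left:
            break
        j += 1
    v, c = target.var, target.cut_idx
    depth = target.depth
    target.var = target.cut_idx = target.cut = None
    target.left = target.right = None

    # reverse move: a birth on the merged leaf choosing exactly (v, c)
    leaves_after = new.leaves()
    if split_data is not None:
        if membership is None:
            raise ValueError("split_data requires leaf membership")
        merged = np.concatenate([membership[j], membership[j + 1]])
        elig = (elig_fn(pick, merged) if elig_fn is not None
                else eligible_splits(merged, prior, split_data))
    else:
        elig = eligible_splits(np.empty(0, dtype=int), prior, None)
    if v not in elig or c not in elig[v]:
        # the reverse birth could never propose this split; treat as unavailable
        return None
    log_fwd = np.log(0.5) - np.log(len(prunable))
    log_rev = (np.log(_p_birth(new)) - np.log(len(leaves_after))
               - np.log(len(elig)) - np.log(len(elig[v])))
    info = {"move": "death", "leaf": j, "var": v, "cut_idx": c, "depth": depth}
    return new, float(log_rev - log_fwd), info
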