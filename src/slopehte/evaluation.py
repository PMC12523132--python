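"""Simulation metrics and the Monte-Carlo harness.

Metrics are evaluated on the held-out validation set (size ``0.4 n``):

* ``l1`` — mean absolute error of the estimated treatment-effect surface;
* ``R1`` — regret of treating exactly those with positive estimated effect,
  relative to the oracle rule (``r1_naive`` is the same loss for the
  treat-everyone strategy);
* ``Htr`` — 0/1 indicator that the declared presence of effect
  heterogeneity (non-constancy of the estimated surface) disagrees with the
  truth;
* ``BEP`` — "Bayesian empirical power": the posterior probability that the
  effect in the oracle benefit subgroup exceeds the effect in the oracle
  harm subgroup, from two conventional (root-tree) shared-parameter fits.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import HonestConfig, ModelConfig, SamplerConfig
from .data_model import TrialDataset
from .honest import honest_pipeline, honest_refit, ordering_probability
from .simulate import ScenarioConfig, gen_trial
from .trees import DecisionTree

__all__ = ["l1_error", "r1_regret", "htr_indicator", "bep", "monte_carlo_study"]


def _check(cate_hat, cate_true):
    a = np.asarray(cate_hat, float).ravel()
    b = np.asarray(cate_true, float).ravel()
    if a.size == 0 or a.size != b.size:
        raise ValueError("need equal-length, nonempty effect vectors")
    return a, b


def l1_error(cate_hat, cate_true) -> float:
    """Mean absolute difference between estimated and true effects."""
    a, b = _check(cate_hat, cate_true)
    return float(np.mean(np.abs(a - b)))


def r1_regret(cate_hat, cate_true) -> float:
    """Mean of |true effect| over subjects whose recommendation sign is wrong."""
    a, b = _check(cate_hat, cate_true)
    wrong = (a > 0) != (b > 0)
    return float(np.mean(np.abs(b) * wrong))


def htr_indicator(cate_hat, cate_true) -> int:
    """1 iff predicted constancy of the effect surface disagrees with the truth."""
    a, b = _check(cate_hat, cate_true)
    const_hat = np.all(a == a[0])
    const_true = np.all(b == b[0])
    return int(const_hat != const_true)


def bep(data: TrialDataset, true_cate, cfg: ModelConfig, scfg: SamplerConfig,
        rng: np.random.Generator) -> float:
    """Oracle-subgroup ordering probability from two conventional SP fits.

    Root-tree shared-parameter models are fitted on the subsets with true
    effect > 0 and <= 0; the returned probability pairs posterior draws by
    index (recycling the shorter chain).  An empty harm subset fixes its
    effect at 0.
    """
    true_cate = np.asarray(true_cate, float)
    ids = data.subject_ids
    roots = [DecisionTree() for _ in range(3)]

    def fit(mask):
        sub = data.subset(ids[mask])
        rf = honest_refit(sub, roots, cfg, scfg, rng)
        return rf.theta_draws[:, 0]

    pos, neg = true_cate > 0, true_cate <= 0
    if not pos.any():
        raise ValueError("no subjects with positive true effect")
    tp = fit(pos)
    tn = fit(neg) if neg.any() else np.zeros(1)
    m = max(len(tp), len(tn))
    tp = np.resize(tp, m)
    tn = np.resize(tn, m)
    return ordering_probability(tp, tn, paired=True)


def monte_carlo_study(scenario: ScenarioConfig, reps: int, cfg: ModelConfig,
                      scfg: SamplerConfig, hcfg: HonestConfig, seed: int,
                      compute_bep: bool = False, label: str = "scenario"
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate-and-analyze ``reps`` trials; return per-replicate and summary tables.

    Each replicate simulates a trial, runs the honest pipeline, and scores
    the estimated effect surface on that replicate's validation set.
    Failures are recorded (metrics NaN), never silently dropped.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    root = np.random.SeedSequence(seed)
    rows = []
    for rep, ss in enumerate(root.spawn(reps)):
        rng = np.random.default_rng(ss)
        row = {"scenario": label, "n": scenario.n, "rep": rep, "seed": seed}
        try:
            data = gen_trial(scenario, rng)
            report = honest_pipeline(data, cfg, scfg, hcfg, rng)
            val_ids = report.val_data.subject_ids
            truth = data.truth.set_index("subject_id").loc[val_ids, "true_cate"].to_numpy()
            tau_hat = report.tau_hat_val
            row.update(
                l1=l1_error(tau_hat, truth),
                r1_propose=r1_regret(tau_hat, truth),
                r1_naive=r1_regret(np.ones_like(truth), truth),
                htr=htr_indicator(tau_hat, truth),
            )
            if compute_bep:
                full_truth = data.truth["true_cate"].to_numpy()
                row["bep"] = bep(data, full_truth, cfg, hcfg.refit or scfg, rng)
        except Exception as exc:  # noqa: BLE001 - recorded, not dropped
            warnings.warn(f"replicate {rep} failed: {exc!r}")
            row.update(l1=np.nan, r1_propose=np.nan, r1_naive=np.nan,
                       htr=np.nan, error=str(exc))
        rows.append(row)
    table = pd.DataFrame(rows)
    metrics = [c for c in ("l1", "r1_propose", "r1_naive", "htr", "bep")
               if c in table.columns]
    summary = table[metrics].agg(["mean", "std"]).T.reset_index(names="metric")
    if reps == 1:
        warnings.warn("single replicate: standard deviations are undefined")
    return table, summary
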