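# slopehte

Bayesian subgroup discovery for slope-based endpoints in chronic kidney
disease (CKD) trials.

CKD progresses slowly, so trials increasingly use the **3-year total eGFR
slope** — the weighted average `w·(acute slope) + (1−w)·(chronic slope)`
with `w = t*/T*` — as a surrogate endpoint. Two things complicate its
analysis. First, dropout is *informative*: patients reaching dialysis,
transplantation or death stop contributing eGFR values, and they are
exactly the fast decliners. Second, treatment effects are rarely uniform,
and pre-specified subgroups may miss the heterogeneity that matters.

`slopehte` addresses both jointly. eGFR trajectories follow a two-slope
linear spline mixed model with change-point `t*` (default 1/3 year) and
horizon `T*` (default 3 years); a piecewise-exponential survival model for
the composite dropout event shares the subject's baseline and chronic-slope
random effects through its frailty `z_i = exp(λ0·trt + η1·a_i + η2·g_i)`
(a shared-parameter model, correcting the slopes for informative
censoring); and the covariate surfaces for the expected baseline eGFR
α0(x), the control chronic slope γ0(x) and the **total treatment effect
τ0(x)** are Bayesian decision trees — τ0(x) is piecewise constant over its
tree's leaves, so the leaves *are* the discovered subgroups. Trees carry a
depth-penalizing prior (split probability `0.95·(1+depth)^-2`) and are
sampled by birth/death Metropolis–Hastings inside a round-trip Gibbs
sampler, with subject random effects integrated out via a Laplace
(Gaussian) replacement of the survival factor so that subtle effects are
not washed out by random-effect noise.

Because adaptive splitting biases naive intervals, inference is **honest**:
trees are discovered on a 60% split and effects are re-estimated on the
held-out 40% with the structures frozen. Repeating over `B3` random splits
yields a *most representative tree* per split (closest to the
posterior-mean effect surface) and a modal **super-representative tree**
across splits, reported with per-leaf effect posteriors, credible
intervals, and ordering probabilities between subgroups.

A trial simulator (step / continuous / constant effect surfaces over six
covariates, switchable informative censoring) and the evaluation metrics
ℓ1 (surface error), R1 (recommendation regret), Htr (heterogeneity
misclassification) and BEP (oracle-subgroup ordering probability) make the
whole workflow testable end to end without any restricted data.

## Worked example

Simulate a strong-heterogeneity trial (step effect on the first covariate
with a harmed subgroup: true τ0 = −0.85 for x1 ≤ 0 and 0.9 + 0.2·x6
above) and run the honest pipeline:

```python
import numpy as np
from slopehte import (ModelConfig, SamplerConfig, HonestConfig,
                      honest_pipeline, scenario_catalog, gen_trial)

scenario = scenario_catalog()["setting1"]   # strong step effect, harmed subgroup
scenario.n = 800
data = gen_trial(scenario, seed=7)

report = honest_pipeline(
    data, ModelConfig(), SamplerConfig(b1=40, b2=40),
    HonestConfig(b3=10, refit=SamplerConfig(b1=40, b2=40)),
    np.random.default_rng(7),
)
print(report.leaf_table.round(2).to_string(index=False))
```

Output (about four minutes on one core):

```
 leaf   E_n  E_p  control_slope  treatment_slope  effect_mean  ci_low  ci_high  estimable
    0 146.0 0.31          -3.63            -4.42        -0.79   -1.42    -0.07       True
    1 174.0 0.25          -2.56            -1.08         1.49    0.96     2.04       True
```

The super-representative tree (modal across the 10 splits, frequency 50%)
splits on x1 at −0.14 — the grid cutpoint nearest the true threshold 0.
Leaf 0 is the harmed subgroup: its honest effect estimate −0.79 eGFR
units/year on the 3-year total slope (95% credible interval
[−1.42, −0.07]) recovers the truth of −0.85; leaf 1 benefits
(1.49 [0.96, 2.04], truth ≈ 1.0). `E_n` and `E_p` are the validation-set
leaf size and its uncensored proportion; treatment slope = control slope +
effect. `report.ordering` gives the posterior probability that one leaf's
effect exceeds the other's — here 1.00, i.e. the treatment is more
effective above the cut in every retained draw.

The same workflow is scriptable from the shell:

```bash
slopehte simulate --scenario setting1 --n 800 --seed 7 --out trial/
slopehte report --longitudinal trial/longitudinal.csv \
    --survival trial/survival.csv --covariates trial/covariates.csv \
    --b3 10 --out report/
slopehte evaluate --scenario setting13 --reps 10 --n 300 --out metrics.csv
```

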