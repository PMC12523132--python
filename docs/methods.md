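# Methods

## The model

`slopehte` estimates heterogeneous treatment effects on the 3-year total
eGFR slope in chronic-kidney-disease trials, jointly with an informative
dropout process.

**Longitudinal submodel.** eGFR trajectories follow a two-slope linear
spline with a change-point `t*` (default 1/3 year — the fourth month, so at
least two visits inform the acute phase) joining an acute and a chronic
phase. For subject *i* at year *t*:

    mu_i(t) = (alpha0(x_i) + a_i) + (beta0(x_i) + b_i) A(t) + (gamma0(x_i) + g_i) C(t)
              + tau0(x_i) trt_i C(t)/(1-w) + zeta0(x_i) trt_i (t - C(t)/(1-w)),

with acute/chronic bases `A(t) = t - d(t)(t - t*)`, `C(t) = d(t)(t - t*)`,
`d = 1(t > t*)` (at `t = t*` both indicator conventions give the same mean),
and `w = t*/T*` with horizon `T* = 3` years. `tau0(x)` is the *total*
treatment effect — the treatment-induced change in the weighted slope
`w * (acute slope) + (1-w) * (chronic slope)` — and the `1/(1-w)` factors
make the mean linear in it; the implied chronic effect is
`nu0 = (tau0 - w zeta0)/(1-w)`. Random effects
`(a_i, b_i, g_i) ~ N(0, sigma^2 Sigma)` and residuals `N(0, sigma^2)`; the
random-effect covariance is deliberately parameterized proportional to the
residual variance, which keeps both variance updates conjugate.

**Dropout submodel.** Time to the composite event (death / ESKD) has a
piecewise-exponential hazard `z_i * exp(lambda_k)` on `K = 5` intervals with
knots at the quantiles of the observed event times (linear-interpolation
sample quantiles; with too few events the package falls back to a uniform
grid over the horizon). The frailty
`z_i = exp(lambda0 trt_i + eta1 a_i + eta2 g_i)` shares the baseline and
chronic-slope random effects with the longitudinal model; nonzero
`eta1, eta2` make dropout informative and their estimation corrects the
slope estimates for it. The acute random effect is excluded from the
frailty — with visits every four months at most two observations inform it,
too few to identify an association with the event time. No covariates enter
the frailty. Times beyond the last finite knot keep the last hazard level.

**Covariate surfaces.** `alpha0` (expected baseline eGFR) and `gamma0`
(control chronic slope) are within-leaf linear regressions under Bayesian
decision trees; `tau0` is piecewise constant under its own tree (one average
treatment effect per leaf — the interpretable subgroups); `beta0` and
`zeta0` (acute slope and acute effect) are global linear forms, since the
acute phase carries too little information to support tree structure.
Modeling `alpha0`/`gamma0` flexibly is not optional: unmodeled heterogeneity
in the control chronic slope leaks into the treatment-effect tree and can
fabricate subgroups.

**Priors.** Tree structures follow the standard depth-penalized prior: a
node at depth D splits with probability `c0 (1+D)^-d0` (`c0 = 0.95`,
`d0 = 2`), with the split variable uniform over the eligible set and the
cutpoint uniform over a frozen grid (deciles of each continuous variable,
the midpoint for binary ones). The grid freezing makes the tree space
finite so trees can be counted across runs. All regression-type
coefficients and log-hazard parameters get vague `N(0, 1000^2)` priors;
`sigma^-2 ~ Gamma(0.01, 0.01)`; `Sigma^-1` gets a dimension-3 Wishart with
`3 + 0.01` degrees of freedom and scale `(0.01 I)^-1` (the random-effect
vector is 3-dimensional, and these degrees of freedom are the smallest
keeping the prior proper).

## Posterior computation

One *round trip* = a parameter step followed by a tree step; `b2` round
trips are retained (defaults `b1 = b2 = 100`).

**Parameter step.** An inner chain of `b1` Metropolis-within-Gibbs sweeps,
keeping the last state. All fixed-effect blocks (leaf coefficients, the
global acute terms, the per-leaf treatment effects) are drawn *jointly* from
their Gaussian full conditional — the cross-product matrix is assembled once
per round trip since leaf structure is fixed there. Random effects use an
independence Metropolis proposal from their longitudinal-conditional
Gaussian, accepted with the survival-factor ratio (exactly the full
conditional when `eta = 0`). `sigma^2` and `Sigma` are conjugate
(inverse-gamma / inverse-Wishart; Wishart draws use the Bartlett
construction). The hazard levels factorize given the frailties and are
updated by per-interval Laplace independence proposals on their log-concave
conditionals; `(lambda0, eta1, eta2)` get a joint 3-D Newton/Laplace
independence proposal. These kernels are near-iid on their conditionals, so
a short inner chain suffices; any ergodic kernel targeting the same
conditionals would do.

**Tree step.** For each of the three trees in turn, `b1` birth/death
Metropolis-Hastings moves. The acceptance ratio uses a marginal likelihood
in which (i) the subject random effects are integrated out after replacing
the survival-likelihood-times-prior factor with a Gaussian (Laplace), and
(ii) the affected leaves' coefficients are integrated exactly under their
conjugate Gaussian prior — so the ratio depends only on the subjects in the
split/merged leaf and regularizes through the usual Bayesian dimension
penalty. Leaf coefficients are then redrawn from their full conditionals
under the marginalized covariance. Integrating the random effects rather
than conditioning on sampled values is what preserves power against subtle
effects; conditioning on "coarse" random-effect draws washes them out.

**The Laplace replacement.** The survival factor depends on the random
effects only through the scalar `u = eta1 a_i + eta2 g_i`, so the problem is
one-dimensional per subject. We expand `log f(u) = delta u - kappa e^u` to
second order at the mode of the *full* per-subject integrand (the
longitudinal information locates the expansion point; a vectorized Newton
iteration, tolerance 1e-8, at most 50 iterations with a fallback warning on
non-convergence). Expanding where the integrand mass sits, rather than at
the mode of the survival-times-prior factor alone, is a deliberate accuracy
choice; the Gaussian form — hence the conjugacy the tree moves rely on — is
identical. The reported scalar marginal additionally carries a closed-form
cumulant correction (second and, while the series is decreasing, third
cumulant of the expansion residual under the Gaussianized posterior); the
correction is constant in the tree parameters, so it never affects
acceptance ratios, but it brings the per-subject marginal within ~1e-4 log
units of adaptive quadrature in model-realistic configurations. With
`eta1 = eta2 = 0` the whole construction is exact.

**Initialization.** Root-only trees; coefficients from a least-squares fit
of the full two-slope design; `sigma^2` from its residual variance;
`Sigma = diag(0.5, 0.25, 0.25)`; constant-hazard start;
`lambda0 = eta1 = eta2 = 0`; random effects at zero.

## Honest subgroup estimation

Adaptive splitting biases naive within-leaf intervals, so inference is
*honest*: the data are split 60/40 at the subject level (stratified by arm
so no leaf can lose an arm by chance — the stratification is our choice).
Trees are discovered on the 60% set; a most-representative tree is selected
per chain as the retained draw minimizing the summed squared distance
between its effect surface and the posterior-mean surface over discovery
subjects (ties to fewer leaves, then canonical order). The split is
repeated `b3` times (default 100) with fresh randomization; the modal
representative tree under canonical serialization — the
super-representative tree — defines the reported subgroups. The model is
then refitted on the validation set with all three tree structures frozen
(representative intercept and chronic-slope trees from the matching split,
the super-representative effect tree), and per-leaf effect posteriors,
control/treatment total slopes, leaf sizes and uncensored proportions are
reported with 95% credible intervals. Cutpoint grids are computed once from
the full covariate table — covariates only, never outcomes — and shared
across splits, so all chains explore one finite tree space; honesty (no
validation *outcome* enters structure selection) is preserved by
construction. By default one matching split is refitted (`refit_all` pools
every matching split, as one would for a final report). Ordering
probabilities between leaves are the paired fraction of posterior draws in
which one leaf's effect exceeds the other's (exact ties count one half;
with independent pooling the same convention makes identical draw sets give
exactly 0.5).

Leaves lacking either arm in the validation set are flagged non-estimable;
the metric surface substitutes the size-weighted overall effect for them.
The concordance summary sorts validation subjects into tertiles of their
discovery-tree effects (rank ties broken at random under the run seed) and
averages their validation estimates per tertile.

The intersection partition (cells = nonempty intersections of the three
trees' leaf regions, judged on the supplied sample) is provided for
refitting conventional models inside fully homogeneous cells; region
intersection is our reading of the construction, and its cells can be small.

## Simulator

The generator emulates a two-arm CKD trial: six covariates (five
`Unif(-2, 2)`, one `Bernoulli(0.5)`), 1:1 randomization, surfaces from
step (ST), continuous (CON) or constant (CST) families in which any
heterogeneity depends only on the first (continuous, threshold at 0) and
sixth (binary) covariate — the rest are nuisance; constant acute slope and
acute effect; visits at baseline and every 4 months to 3 years; dropout
from a constant baseline hazard calibrated so ~30% of control subjects
have events by year 3 when `eta = 0`, with `eta1 = eta2 = -0.5` switching
informative censoring on (steeper decliners and lower baselines drop out
earlier). Administrative censoring at 3 years; visits truncated at the
event time. Default magnitudes: residual SD `sigma = 3` eGFR units,
random-effect SDs `(2.0, 1.5, 1.5)` for intercept/acute/chronic (so the
slope signal-to-noise resembles CKD trials; the intercept SD is our
choice), strong-step effect `{-0.85 below 0; 0.9 + 0.2 x6 above}` (so the mean
harmed-subgroup loss under treat-everyone is ~0.42 eGFR units/yr, a
clinically consequential regret), subtle-step gap 0.4 (`+/-0.2`),
near-null gap 0.2 (all positive),
and the null at `tau0 = 0.1` everywhere. True per-subject effects are
recorded for evaluation. The scenario catalog mirrors the 16-setting
layout (families x informative censoring); exact magnitudes beyond the
main-text constraints are configurable package choices.

The MDRD-like fixture is *synthetic*: it reuses the standard CKD covariate
names and heavy-tailed UACR/TG marginals and plants a treatment-effect
split on baseline eGFR for end-to-end smoke tests. It stands in for no real
data and supports no clinical conclusion.

What passing simulations do **not** show about real data: the generator has
no visit-time irregularity or missed visits, no measurement-batch effects,
Gaussian residuals, a step/linear truth, and exact proportional frailty —
real trials violate all of these to some degree.

## Evaluation metrics

On the validation set (size 0.4 n): `l1` = mean absolute error of the
estimated effect surface; `R1` = mean `|tau0|` over subjects whose
treat/don't-treat recommendation sign is wrong (`r1_naive`: the same loss
for treat-everyone); `Htr` = indicator that declared constancy of the
estimated surface (exact equality — for tree surfaces, a root-only
super-representative tree) disagrees with the truth; `BEP` = posterior
probability that the oracle benefit-subgroup effect exceeds the oracle
harm-subgroup effect from two conventional root-tree fits (index-paired
draws, shorter chain recycled; an empty harm subset fixes its effect at 0).
The estimator scored by `l1`/`R1`/`Htr` is the honest validation-refit
surface of the super-representative tree, so one `tau-hat` serves all three
metrics. `BEP` is optional in the Monte-Carlo harness (it costs two extra
chains per replicate).

## Problem sizes and numerical choices

The shipped evaluation runs use shortened schedules chosen as desk-scale
defaults: chains `b1 = b2 = 40`, `b3 = 10` splits, 10 Monte-Carlo
replicates, n = 300 for the null designs and n = 800 for the strong-step
design. At n = 300 the strong step's marginal-likelihood advantage over a
root tree is borderline (the likelihood gain barely exceeds the Bayesian
dimension penalty), so detection is only reliable from moderate-to-large
samples — n = 800 — and the strong-step evaluation runs there. Minimum
leaf size is
`max(25, 2% of discovery n)` and every leaf must contain both arms, making
within-leaf effects estimable. Exponent guards clip log-scale quantities at
+/-30; all covariance solves are Cholesky-based. Every random draw flows
from one `numpy` Generator per run, so runs are exactly reproducible under
a seed.

## Known limitations

- Single trees per surface (no ensembles); step-function truth is the model
  class, continuous effect surfaces are only approximated.
- The honest split spends 40% of subjects on estimation; no selective
  inference beyond the split.
- The Laplace replacement is approximate when `eta != 0`; accuracy is
  verified at ~1e-4 log units in realistic regimes but degrades for very
  sparse visit histories combined with strong frailty coupling.
- Per-interval hazard levels need events in every interval to be
  well-informed; with very few events the knot fallback coarsens the
  baseline hazard.
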