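# Methods

## The observation model

Each patrol record carries a binary outcome y (violation detected or not)
and covariates describing the patrol and its target. The model treats the
outcome as the end of a two-stage Bernoulli process: a violation is present
with probability v, and is then detected with probability p, so

    y ~ Bernoulli(v·p).

The two probabilities are logistic regressions over disjoint predictor sets.
Detectability p depends on how the patrol was run — scaled patrol time,
scaled group size, actor category, administrative region, year. Violation
probability v depends on what was being enforced — species group and
violation type. The assignment is configurable (`ModelSpec`); the
`fit_model_ladder` helper fits any collection of assignments, including the
alternative in which region and year sit on the violation side, and ranks
them by WAIC.

The latent violation indicator s is marginalised analytically:
P(y=1) = v·p and P(y=0) = 1 − v·p. Sampling s explicitly would give the
identical likelihood at a higher computational cost; a latent-simulation
route (`model.simulate_outcomes`) exists and the test suite checks by Monte
Carlo that the two routes agree. All likelihood work is done in log space,
with log(v·p) factored as log v + log p and log(1 − v·p) computed via
`log1p` so probabilities near 0 and 1 stay stable.

### Identifiability

For y=1 the intercepts enter only through the product v·p, so μ_v and μ_p
are separated only by covariate variation across the two submodels and by
the bounded prior. The primary recovery contract is therefore the product
curve v·p; individual intercepts are a weaker, prior-dependent check. The
sampler includes a dedicated joint move along this ridge (below), and the
test suite checks product calibration (mean predicted probability against
the empirical detection rate) rather than intercept point recovery.

## Priors and coding

Every coefficient, intercepts included, carries a flat prior on the closed
box [−2.2, 2.2] — log-odds ratios of roughly −90% to +90%, wide enough to be
uninformative at these effect sizes while keeping the explored volume
finite. The boundary is treated as inside the support (a measure-zero
convention that matters only for determinism of `log_prior`). Categorical
factors use treatment coding: the first level of each factor in the
`CategoryScheme` is the reference, its coefficient exactly 0, and it carries
no prior dimension.

## Data handling

* Continuous effort covariates are min-max scaled to [0, 1] from the
  training data; the `ScalingInfo` is stored and reused on held-out data,
  where out-of-range values are clipped to [0, 1] with a warning. A constant
  column is a fatal error naming the column.
* Rows failing validation on read (unparseable fields, time < 0, group size
  < 1, non-binary outcome, unknown category under a fixed scheme) are
  dropped complete-case with a counted report.
* Predictor pairs with |Pearson r| > 0.7 are flagged; the estimator's
  default action drops the column that appears later in design order — a
  deterministic, overridable rule (`collinearity_action`).
* Category collapsing (merging minority levels) conserves record counts and
  shrinks the scheme; targets not already in the scheme must be declared.

## Sampler

Adaptive random-walk Metropolis inside the prior box, chosen for robustness
and zero heavy dependencies at this dimensionality (roughly 25–65
parameters):

* one Gaussian proposal per coordinate per sweep, rejected outright outside
  the box;
* per-coordinate proposal scales adapted during warmup toward a 0.44
  acceptance rate by Robbins–Monro on the log scale (step (t+1)^−0.6),
  frozen at the end of warmup so the sampling phase is Markovian;
* one antisymmetric joint proposal (μ_p + δ, μ_v − δ) per sweep, with its
  own adapted scale, to traverse the intercept ridge described above;
* chains initialised at independent uniform draws from the prior box, with
  per-chain seeds spawned from the master seed;
* incremental linear-predictor updates (a coordinate change touches one
  design column), so a sweep costs O(K·n).

Defaults are 3 chains of 3000 iterations (600 warmup, 2400 retained).
Convergence is assessed with the classic split-chain Gelman–Rubin statistic
(each chain halved; pass iff every R̂ < 1.1) — cross-checked in the tests
against `arviz`'s split variant — plus `arviz` effective sample sizes.

## Model comparison

WAIC on the deviance scale, WAIC = −2(lppd − p_waic), with the pointwise
variance penalty. The variance uses ddof = 1 (the convention of the R `loo`
package); `arviz` uses ddof = 0, a difference of order 1/S that the
cross-check test accounts for. Per-draw pointwise log-likelihoods are stored
as float32 — at 3 × 2400 draws and 5,000 records that is ~140 MB, and the
float32 rounding is orders of magnitude below the Monte-Carlo error of the
WAIC estimate.

## Posterior-predictive classification

A record's predicted probability is the posterior mean of v·p over all
retained draws — the standard posterior-predictive point summary (the
median or per-draw classification would be defensible alternatives). A
record at or above the threshold classifies as "detected" (ties go to 1,
documented and deterministic). Because detections are a small minority,
precision/recall/F1 are the reported scores, with zero-denominator ratios
reported as missing rather than silently 0, and the operative threshold is
chosen by sweeping a grid of step 0.01 ({0.01, …, 0.99}) and taking the
smallest threshold attaining the maximal F1.

## Reporting conventions

Credible intervals are equal-tailed 2.5–97.5 percentile pairs of the stored
draws (not HPD). Category summaries report each non-reference level's
posterior mean and 95% CI log-odds ratio together with its effort share
(proportion of patrol records in that level; shares sum to 1 within a
factor); reference levels are printed as exactly 0 with a degenerate
interval. The annual detectability series averages posterior-mean p over
each year's realized covariate mix — marginal over observed patrols, not
evaluated at reference covariates — so it reflects what the patrols of that
year actually faced. Plots are deliberately out of the core: the canonical
outputs are tables and JSON, keeping the pipeline headless.

## Synthetic data generator

The generator executes the two-stage process literally: covariates are
drawn, v and p computed from configured true parameters on the scaled
covariates, then s ~ Bernoulli(v) and y ~ Bernoulli(p·s). It emulates a
national land-based fisheries enforcement programme:

* patrol time ~ Normal(311.6, 217.9) minutes truncated above 0 (analytic
  truncation via `scipy.stats.truncnorm`);
* group size ~ Normal(2.0, 1.1) truncated, rounded half-up and floored at 1
  — only the normal moments are constrained; the rounding rule is a
  documented package choice;
* categorical effort follows a geometric-decay profile (rate 0.8 per level;
  0.9 across years), concentrating effort in a few categories while leaving
  minority species groups under 1% of records, as real enforcement effort
  distributions do;
* the default scheme has 16 regions (including a mobile unit), 8
  supply-chain actor categories, 31 species groups, 7 violation types and
  years 2014–2020; `reference_config` defaults to intercepts
  logit(0.18)/logit(0.34), a time slope of +1.79 and a group-size slope of
  −1.52, with the remaining effects drawn uniformly from the prior box under
  the config seed;
* one master seed spawns independent substreams per variable, so changing
  one covariate's stream leaves the others untouched.

What the generator does **not** emulate: correlation between factors (e.g.
region × actor effort structure — factors are drawn independently),
deterrence or displacement feedback over time, intra-year seasonality, and
reactive (violation-seeking) patrol allocation. Passing recovery tests on
this generator therefore demonstrates correctness of the inference under
the model's own assumptions, not robustness to the biases of real
enforcement data.

## Problem sizes used in the checks

Recovery and model-comparison experiments run at 5,000 records with reduced
factor cardinalities (4 regions, 4 actors, 6 species, 3 violation types —
about 23 parameters) and the default chain settings, repeated over three
seeds; the threshold-sweep experiment uses 30,000 records at the same
cardinalities; generator smoke checks run at the full 77,820-record,
full-cardinality design. These sizes give stable Monte-Carlo behaviour
(split-R̂ comfortably below 1.1, interval coverage near nominal) while
keeping a full test run fast.

## Known limitations

* The two intercepts are only weakly separated (see Identifiability); with
  predictors that overlap across submodels the separation would weaken
  further, and users adding such configurations should check the product
  contract, not the intercepts.
* The ±2.2 prior box binds per coefficient, not per linear predictor; summed
  logits may exceed the box.
* Flat box priors make posterior mass pile up at the boundary when a true
  effect is at or beyond ±2.2; interval coverage for such levels reflects
  the truncated support.
* The random-walk sampler is adequate at tens of parameters but would need
  a gradient-based backend for much larger schemes (hundreds of levels).
* Min-max scaling ties coefficient interpretation to the training range;
  clipping held-out extremes biases their linear predictor toward the
  training hull.
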