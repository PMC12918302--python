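# Methods

## Setting

A cohort of n patients carries proxy features `X1`, structured covariates
`X2`, a binary reference phenotype `Strue`, a continuous proxy score
`S* ∈ [0,1]`, a binary outcome `Y`, and a right-censored event time
`(T, δ)`. The learner maintains a phenotype vector `S_t` over the training
pool, initialised `S_0 = S*`. At each iteration it reveals `Strue` for a
batch of k patients (never re-querying anyone) until a budget B is
exhausted, retraining the downstream risk model after every batch. The
task is to choose the batches so that the downstream model on `(S_t, X2)`
approaches the oracle trained with `Strue` everywhere.

## Synthetic cohort generator

The generator draws, per patient:

- `X1 ~ N(0, I_d1)` (d1 = 5 by default);
- `Strue ~ Bernoulli(logistic(a1 + uᵀX1))` with `u` uniform across columns
  at total scale 1.5 and `a1` calibrated by monotone root-finding so the
  empirical mean of the Bernoulli probabilities equals the configured
  phenotype prevalence (tolerance 1e-6, Brent's method);
- proxy degradation: with probability `1 − proxy_sensitivity` a
  phenotype-positive patient's `X1` is zeroed (the stored `X1` is this
  *observed* matrix), then `S* = logistic(a1 + uᵀX1_obs + ε)`,
  `ε ~ N(0, proxy_noise_sd²)`. This makes the noise one-sided — missed
  positives look like typical negatives — which is exactly the
  under-ascertainment regime code-based proxies exhibit (roughly 30% of
  patients with a documented smoking history versus ~10% with any
  smoking-related diagnosis code in the motivating health-system data);
- `Y ~ Bernoulli(logistic(α + β_s·Strue + β₂ᵀX2))` with `X2 ~ N(0, I_d2)`
  (d2 = 4), `β_s = 2.0` (a strong log-odds effect of the order of
  smoking → lung cancer), `‖β₂‖ = 0.5`, and `α` calibrated to the outcome
  prevalence;
- `T` exponential with rate `∝ exp(β_s·Strue + β₂ᵀX2)` (the same linear
  predictor as Y), administratively censored at the empirical quantile
  that yields the configured censoring rate (default 0.7). This is the
  simplest generative model consistent with the proportional-hazards form
  fitted downstream.

All randomness flows from a single integer seed through spawned
`SeedSequence` sub-streams, one per field, so cohorts are reproducible
field-by-field and changing one mechanism does not perturb the others.

Default prevalences follow the study sweep {1%, 10%, 30%}
(`PREVALENCE_PRESETS`). Coefficient magnitudes and noise levels are this
package's own choices of a realistic regime (noticeable proxy noise,
strong phenotype effect); they are config-exposed, not tuned.

`duhs_like_fixture` is a *synthetic* stand-in for a large health-system
lung-cancer cohort, calibrated in expectation to its published marginals:
outcome prevalence 0.78%, any-smoking-code coverage 9.0%, never-smoker
fraction 52.7%. Its `X1` are sparse nonnegative code counts and its proxy
is the fitted probability of a code-only logistic model, mirroring how
code-only proxies are built in practice. No real patient data are used or
emulated at the individual level.

What the generator does **not** emulate: clinical notes and NLP-derived
signals, missing-data mechanisms, site/coding drift, temporal structure,
and correlated covariates. Passing benchmarks here therefore demonstrate
the mechanics and direction of the method (querying closes the
proxy-to-oracle gap; strategy choice matters more when the outcome is
rare), not effect sizes on real EHR data.

## Strategies

Features for strategy models are z-scored with the mean and *population*
SD of the current labeled set (zero-variance columns are centered only).
Labeled patients contribute their binary `Strue` and unlabeled ones their
continuous `S*` wherever a strategy needs the phenotype as a feature or
label.

- **Uncertainty**: binary entropy `H(p̂) = −p̂ ln p̂ − (1−p̂) ln(1−p̂)` of the
  current downstream model's predicted outcome probability (`0·ln 0 := 0`).
- **Diversity**: Euclidean distance to the nearest labeled neighbour,
  divided by `1 + mean per-dimension variance of the labeled features`.
  The adjustment is a bounded, order-preserving numerical stabilizer;
  its form is this package's choice and it is switchable to `none`.
- **Query-by-committee**: M = 7 logistic models on bootstrap resamples of
  the labeled set, each with its L2 penalty multiplied by
  `exp(N(0, 0.1²))` and feature dropout at probability 0.1. Score =
  population variance of the committee probabilities plus `λ·H(mean)`,
  λ = 0.1 — an entropy stabilizer so that confidently-agreed patients rank
  below boundary cases when variance alone is flat. λ and the jitter SD
  are config-exposed.

Each score is min-max normalized to [0,1] per iteration (constant vectors
map to zeros, contributing nothing that round), combined with the simplex
weights, and perturbed by a seeded `U(0, 1e-6)` jitter to break ties
symmetrically. A batch smaller than k is taken when the remaining budget
(or pool) runs short.

## Downstream models and metrics

Classification: L2 logistic regression (inverse-penalty C = 1.0) of `Y` on
`(S_t, X2)`, refit from scratch every iteration. Survival: ridge-penalized
Cox partial likelihood (penalizer 0.1) on `Z = (S_t, X2)` after feature
screening; the default screen drops exactly-constant columns, with an
optional univariate-score cap for wide feature sets. The penalty type
(ridge) and screen are package defaults where the source design leaves
them open.

Metrics: rank-based AUC with tie correction; Brier-type probability MSE;
F1/TPR/PPV at the operating point with the **largest empirical FPR ≤ 0.1**
(no interpolation, so the realized FPR never exceeds 0.1); Harrell's
C-index with half-credit for risk ties.

## POMDP, state, reward, PPO

The summary state has 13 fixed components: mean and max of each normalized
strategy score over the unlabeled pool (6), labeled fraction and
labeled-positive fraction (2), last metric / one-step change / moving
average over a window of 3 (3), remaining-budget fraction (1), and
iteration fraction t/H (1).

The action is a point on the probability simplex Δ². The policy network
(tanh MLP, one hidden layer of 32) outputs three unconstrained mean
logits; actions are sampled from a diagonal Gaussian over the logits with
a learned state-independent log-SD and mapped through a softmax. The
softmax acts on the *mixture logits*, never on raw per-patient scores.
Deterministic evaluation uses the mean logits.

Reward: `R_t = (m_t − baseline) · (1 + c·b_t)` with `baseline` the mean of
the last w = 3 metrics before t, `c = 0.5`, and `b_t` the remaining-budget
fraction. The moving baseline de-noises one-step metric jitter; the budget
term mildly front-loads improvements. w and c are config-exposed
constants of this implementation.

PPO: clipped surrogate (ε = 0.2), GAE (λ = 0.95, γ = 0.99), a separate MLP
value baseline, Adam (lr 0.01), 4 epochs per update, updates every
iteration from the transitions gathered since the last update (the
bootstrap value uses the next observed state; the final segment bootstraps
zero). Advantages are batch-normalized unless identically zero — a
zero-advantage batch leaves the policy parameters exactly unchanged. The
entropy bonus defaults to 0 and is config-exposed. Networks and the
optimizer are plain numpy with hand-written backprop; no deep-learning
framework is required.

The policy-learning sanity check trains the agent on a bandit-style
environment whose reward is 1 exactly when the mixture is dominated by a
designated strategy; it verifies the PPO machinery concentrates weight
correctly without paying for full cohort episodes.

## Experiment design

80/20 outcome-stratified split with largest-remainder rounding (event
rates preserved within one patient, deterministic under the seed). A
balanced seed set (half of each `Strue` class) initialises the labeled
set. Episodes run `ceil(B/k)` iterations.

Validation mirroring: the replacement dynamic is mirrored on the
validation set cumulatively and proportionally — after the training pool
holds L reference labels, `round(L·|val|/|train|)` validation patients
have had their phenotype feature upgraded, chosen by the same composite
score and weights from the current model (balanced at random for the seed
set, before any model exists). This reading makes a full-budget run
upgrade the entire validation set, so budget ≥ pool reproduces the oracle
*exactly* — a useful end-to-end invariant. A flag disables mirroring
(proxy features throughout) for sensitivity analysis.

Comparator arms: proxy-only (zero labels), oracle (all labels), random
(uniform querying, outside the RL action space), the three one-hot fixed
strategies (implemented as the same episode runner with frozen weights —
an exact equivalence, tested), and RELEAP. Within a replication all arms
share the split and seed set; replication r derives every seed from
`(master_seed, r)`. Aggregation reports mean ± 1.96·SD/√R per
method × iteration; with one replication the CI is reported absent.
Subgroup analysis re-scores stored validation predictions within groups,
skipping single-outcome-class groups with a warning.

A weak-supervision comparator based on real clinical notes and NLP
concept extraction has no synthetic counterpart; requesting it raises an
explanatory error.

## Problem sizes

The default desk-scale preset — n = 20 000, budget 4 000, k = 200, seed
set 200, 5 replications — preserves the ~43% training-pool budget
fraction of the motivating full-scale design (238 119 patients, 82 000
queries in 40 iterations of 2 000 over a seed set of 2 000, 10
replications) at roughly a hundredth of the compute. Direction-style
benchmarks (querying arms between proxy-only and oracle; wider strategy
spread at 1% than at 30% prevalence) use this preset or smaller seeded
cohorts; calibration checks use n = 50 000.

## Numerical choices and degenerate inputs

- Intercept calibration brackets the root adaptively and errors if the
  target prevalence cannot be bracketed.
- Constant score vectors normalize to zeros; exact ties break by seeded
  jitter; `k` truncates to the pool.
- Zero-variance feature columns: centered only (z-scoring), dropped
  (Cox screening).
- Single-class labeled sets, all-censored cohorts, empty batches, budget
  overruns and re-queries raise explicit errors rather than degrading.
- Seeds everywhere are integers below 2³¹ derived via `SeedSequence`.

## Known limitations

- PPO hyperparameters and the state layout are fixed defaults; no
  hyperparameter search is performed, so the learned agent is competitive
  with, but not reliably better than, strong fixed heuristics at desk
  scale — consistent with the saturation behaviour expected under batched
  querying.
- The Gaussian-over-logits head cannot express exactly one-hot mixtures
  (softmax outputs are strictly positive); frozen one-hot arms exist for
  that purpose.
- The simulator's independence assumptions (Gaussian features,
  independent censoring) are idealisations; see the generator section for
  what passing tests do and do not establish.
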