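# Methods

`peerselect` models a *secondary distribution* programme for HIV self-testing
(HIVST): index participants (here, MSM recruited into a three-arm trial
structure) order several self-test kits and pass them to members of their
social network ("alters"). Programmes want to find, in advance, the **key
influencers** among indexes:

- **key distributors** — indexes who pass kits to at least 2 alters;
- **key promoters** — indexes with at least 1 alter who is a first-time
  tester;
- **key detectors** — indexes with at least 1 alter who tests HIV-positive.

The package implements and compares two identification strategies — a
machine-learning ensemble and a self-reported leadership-scale cutoff — on
synthetic trials, and quantifies the downstream effect of the choice with a
kit-diffusion simulation.

## Synthetic trial generator

Individual-level data from such trials are not public, so every stage runs on
synthetic data with the published marginal structure. The generative model:

1. **Covariates.** A configurable schema (defaults: age, education, income
   band, ever-tested, months since last test, partner count, app-use
   frequency, disclosure of orientation, plus a three-level arm assignment).
   The default schema is a plausible survey instrument, not a claim about the
   original trial's predictor set, which is unpublished.
2. **Latent propensity.** η_i = β₀ + Σⱼ βⱼ z(xᵢⱼ) with z-scored covariates;
   θ_i = logistic(η_i). Defaults: β₀ = −2.2 and weights 0.8 (partner count),
   0.5 (app use), 0.5 (disclosure), 0.4 (ever tested); other covariates are
   noise predictors the identification system should ignore.
3. **Alter counts.** N_i ~ zero-inflated Poisson with inflation π₀ = 0.1 and
   mean μ·θ_i, μ = 6.5. The logistic-normal heterogeneity in θ yields both
   the mass at 0–1 kits and the overdispersed tail the published counts
   imply (most indexes pass on ≤1 kit; ~19% reach ≥2 alters who hold >70% of
   all alters).
4. **Alter outcomes.** Per alter, independent Bernoulli flags: first-time
   tester with p = 103/269 and HIV-positive with p = 25/269 (the published
   per-alter rates).
5. **Leadership scale.** Six items, each 0–4, from a discretised
   latent-Gaussian factor model: item latent = s·z(η) + √(1−s²)·ε with
   loading `scale_signal` s (default 0.5), cut at fixed normal quantiles
   (item level probabilities 0.25/0.30/0.25/0.15/0.05). Totals are integers,
   so ranks tie and the top-20% cutoff is bracketed by two thresholds, the
   regime the human baseline operates in.

All randomness flows from one `numpy` `SeedSequence` via spawned child
streams; a config plus seed reproduces a dataset byte-for-byte on disk.

**Calibration.** The defaults were calibrated once, by Monte-Carlo search
over (π₀, μ, β₀, coefficient scale), to the published marginals for a
309-index trial: ≈269 alters, ≈60 key distributors, ≈73 key promoters,
≈23 key detectors, ≈103 first-time alters, ≈25 positive alters. Over 200
seeds the expected marginals sit within ~7% of every target (the test suite
enforces 15%).

**What the generator does not emulate.** Real covariate marginals and their
correlations; item wording and psychometrics of the real scale; any arm
effect on distribution (arm is carried only as a covariate); network
structure beyond the observed one-hop index→alter star per index. Passing
tests therefore show the pipeline's statistical machinery behaves correctly
under the published marginal structure, not that the real trial's accuracy
values would be reproduced.

## Identification system

Two-pass procedure wrapped as the scikit-learn estimator
`KeyInfluencerClassifier`:

1. **Pass 1 — importance.** Four base classifiers are fitted on all
   predictors: L2 logistic regression (C=1), linear-kernel SVM with
   Platt-type sigmoid calibration, decision tree (minimum leaf 5), and a
   100-tree random forest. Continuous predictors are z-scored on the
   training split; binary ones stay 0/1. Per-model predictor rankings:
   logistic regression by |standardised coefficient|; SVM by recursive
   feature elimination, removing one predictor per iteration
   (last-eliminated = most important); tree and forest by total
   Gini-impurity decrease. Ties break by column order for determinism.
2. **Vote.** The selected predictors are those inside every model's top-k
   prefix. Default k = ⌈p/3⌉; if the 4-way intersection is empty, k grows
   until it is not, so the selected set is never empty and always sits
   inside each model's final top-k′ prefix.
3. **Pass 2 — ensemble.** The four models are refitted on the selected
   predictors and combined by soft voting: the class-1 probability is the
   weighted mean of member probabilities (default weights ¼ each), and an
   index is flagged when it reaches the decision threshold 0.5 (ties flag
   positive). The ensemble probability is a convex combination of member
   probabilities, which the tests assert row-wise.

Hyperparameters are deliberately fixed (no tuning loop) and overridable via
`ClassifierSpec`; missing values fail fast since the generator never emits
them.

## Leadership-scale baseline

The human comparator scores six self-rated 0–4 items, totals them (0–24) and
flags the top ~20% by rank order. Integer totals tie, so the head-count
target usually falls inside a tied block; `find_cutoffs` returns the two
bracketing thresholds — cutoff **A** (≥ threshold, flags at most the target)
and cutoff **B** (one point lower, flags at least the target). On a
trial-shaped score vector this reproduces the published 49-at-≥11 /
81-at-≥10 structure exactly. In cross-validation the cutoff pair is
re-learned on each training fold and applied to the test fold, so the
baseline is scored on exactly the same held-out indexes as the classifiers.

## Evaluation

Stratified 5-fold cross-validation (stratification avoids single-class
training folds at the detector rule's ~7% prevalence); accuracy, precision,
recall and F1 from confusion counts with the conservative convention that a
zero-denominator ratio is 0; fold averages are unweighted means.

Comparison statistics follow the published conventions exactly:

- **Increased percentage** on a shared denominator:
  100·(n_ML − n_base)/n_total — e.g. (146−97)/269 → 18.2 points, not
  (146−97)/146.
- **Wald difference-of-proportions CI** with the shared denominator:
  (p₁−p₂) ± z·√(p₁(1−p₁)/n + p₂(1−p₂)/n), z = 1.959964. This recovers the
  published intervals (9.9, 26.5), (1.9, 25.3) and (−14.7, 38.7) from the
  printed counts.
- **Fold-difference CI**: mean ± z·SD over per-fold differences, with the
  population (n-denominator) SD — the convention that reproduces the
  published (−3.5, 38.8) from the per-fold efficiency differences.

These two CI conventions are distinct on purpose; both are implemented as
recovered from the printed intervals.

## Diffusion simulation

On each test fold, the fold's bipartite index–alter network is built (one
edge per kit actually passed). A seeding strategy flags indexes; each seed
starts with 4 kits (the trial allocation cap) and Poisson mean 4. Per step,
each kit-holding distributor draws d ~ Poisson(its mean), capped by kits
held and unreached neighbours, and hands one kit each to that many distinct
unreached neighbours chosen uniformly; a receiver is marked tested (the
efficiency metric equates receiving with self-testing), keeps the kit (so
kits are conserved), and takes its received count as its own Poisson mean.
By default alters do not redistribute (the empirical network is one hop);
the process runs to quiescence with a 10-step guard. **Intervention
efficiency** = % of fold nodes (indexes + alters) tested at the end.

Strategy comparison is **head-count matched**: within each fold the scale
baseline seeds its own top-k indexes by rank order, with k equal to the
ensemble's flagged count (the published comparison was likewise matched, at
49 vs 49 influencers). Without matching, the comparison mostly measures
which strategy flags more seeds, since every seed counts itself as tested.
Efficiencies average over replicate simulations with common random numbers
across strategies, so identical seed sets tie exactly.

**A deliberate caveat:** on default synthetic data the matched count and
efficiency comparisons come out near a tie, unlike the published +18.2 / 
+17.7 point gains. This is a property of the generator, not a bug: the
synthetic scale loads on the same single latent propensity that drives alter
counts, so ranking by scale total captures degree almost as well as the
ensemble does. The classification-accuracy comparison (where the ensemble
sees all covariates) does favour the ensemble in most seeds, matching the
published direction. The published desk-scale statistics themselves are
recomputed exactly from their printed inputs by
`peerselect.pipeline.printed_arithmetic_selftest`.

## Problem sizes and numerical choices

Default study size is the trial's own (309 indexes); cross-validation uses
5 folds; the direction experiment uses 10 generator seeds; simulation
comparisons use 20 replicates per fold. Percentages are reported at one
decimal, Table-1-style metrics at two, matching the published display. The
"11.0% average accuracy gain" mentioned in the original report is not
exactly recoverable from the rounded published per-model metrics; the
package recomputes the analogous fold-averaged quantity on synthetic data
rather than asserting it.

## Known limitations

- The covariate schema and scale items are synthetic stand-ins; results on
  synthetic data say nothing about which real predictors matter.
- The diffusion model is a one-parameter Poisson sketch of distribution
  behaviour; no epidemic dynamics, no contact-network inference.
- Equal ensemble weights and fixed hyperparameters are defaults, not
  optima; the published report is silent on both.
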