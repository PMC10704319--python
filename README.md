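# peerselect

Identify **key influencers** for secondary distribution of HIV self-testing
(HIVST) kits. In a secondary-distribution programme, an *index* participant
orders several self-test kits and passes them to members of their social
network (*alters*). A minority of indexes do most of the work: **key
distributors** pass kits to ≥2 alters, **key promoters** reach ≥1 first-time
tester, **key detectors** reach ≥1 alter who tests HIV-positive. Programmes
that can find these people in advance test more of the network per kit.

`peerselect` implements, on calibrated synthetic trial data, an intelligent
identification system and the comparisons needed to judge it against the
conventional human approach:

- **Synthetic trial generator** — a latent-propensity model
  (θᵢ = logistic(β·zᵢ), alter counts zero-inflated Poisson with mean μ·θᵢ)
  calibrated to the published marginals of a 309-index / 269-alter MSM trial.
- **Ensemble identification** (`KeyInfluencerClassifier`, a scikit-learn
  estimator) — logistic regression, linear SVM, decision tree and random
  forest fitted twice: once on all predictors to rank importance (|standardised
  coefficient|, RFE elimination order, Gini decrease), the four rankings vote
  for a common top predictor set, and the refitted models soft-vote:
  p(x) = Σₘ wₘ pₘ(x), flag when p ≥ 0.5.
- **Leadership-scale baseline** (`LeadershipScaleClassifier`) — six 0–4
  self-rated items; the top ~20% by rank order are flagged, with the tie-induced
  dual cutoffs A/B (e.g. 49 indexes at ≥11 points but 81 at ≥10).
- **Evaluation** — stratified 5-fold CV; accuracy/precision/recall/F1; the
  shared-denominator increased percentage 100·(n_ML−n_base)/n_total; Wald
  difference-of-proportions CIs; mean ± 1.96·population-SD fold CIs.
- **Diffusion simulation** — kits spread along the empirical index–alter
  edges; per step each kit-holder draws Poisson(kits received), capped by
  kits held and unreached neighbours; intervention efficiency = % of nodes
  tested. Seeding strategies are compared head-count matched per fold.

See `docs/methods.md` for the model details and assumptions.

## Worked example

```python
from peerselect import (
    GeneratorConfig, generate_trial, run_identification, find_cutoffs,
)
from peerselect.evaluate import cross_validate
from peerselect.synthetic import SCALE_COLS

d = generate_trial(GeneratorConfig(rng_seed=1))
print(len(d.indexes), len(d.alters), int(d.indexes.is_key_distributor.sum()))
# 309 249 55        <- one synthetic trial: ~269 alters, ~60 distributors in expectation

res = run_identification(d, "distributor", random_state=1)
print(res.classifier.selected_predictors_)
# ['partner_count', 'age', 'disclosed_orientation', 'scale_2']
#   the 4-model vote kept the planted degree-driving covariates

ens = cross_validate(d, "distributor", "ensemble", fold_seed=1, random_state=1)
base = cross_validate(d, "distributor", "cutoffA", fold_seed=1, random_state=1)
print(f"{ens.average.accuracy:.3f} vs {base.average.accuracy:.3f}")
# 0.842 vs 0.838    <- 5-fold accuracy, ensemble vs scale cutoff A

print(find_cutoffs(d.indexes[SCALE_COLS].sum(axis=1), 0.2))
# CutoffPair(target_count=62, threshold_A=13, count_A=55, threshold_B=12, count_B=69)
#   integer scale totals tie, so the top-20% target is bracketed by two cutoffs
```

The `peerselect` CLI wraps the same stages
(`generate`, `identify`, `baseline`, `evaluate`, `simulate`, `report`,
`selftest`); `peerselect report --seed 0 --out out/` runs the full study and
writes `report.json` / `report.md` plus every intermediate table.

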