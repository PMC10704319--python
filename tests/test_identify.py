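"""Identification system: base fits, importance rules, predictor voting and
the soft-voting ensemble."""

import numpy as np
import pandas as pd
import pytest

from peerselect.errors import ConfigurationError, DegenerateLabelError, SchemaError
from peerselect.identify import (
    ClassifierSpec,
    ImportanceRanking,
    KeyInfluencerClassifier,
    ensemble_predict,
    feature_frame,
    fit_base,
    importance,
    run_identification,
    vote_select,
)
from peerselect.synthetic import SCALE_COLS, GeneratorConfig, generate_trial

from conftest import stub_model


def _toy_separable(n=10):
    rng = np.random.default_rng(0)
    X = pd.DataFrame({"a": np.r_[rng.normal(-3, 0.3, n // 2), rng.normal(3, 0.3, n // 2)],
                      "b": rng.normal(0, 1, n)})
    y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
    return X, y


def test_decision_tree_fits_separable_toy_perfectly():
    X, y = _toy_separable()
    model = fit_base(ClassifierSpec("decision-tree", {"min_samples_leaf": 1}), X, y)
    pred = (model.predict_proba1(X) >= 0.5).astype(int)
    assert (pred == y).all()


def test_single_class_labels_rejected():
    X, _ = _toy_separable()
    with pytest.raises(DegenerateLabelError):
        fit_base(ClassifierSpec("logistic-regression"), X, np.ones(len(X), int))


def test_unknown_family_rejected():
    with pytest.raises(ConfigurationError):
        ClassifierSpec("gradient-boosting")


def test_logistic_fit_recovers_two_by_two_odds_ratio():
    """Fitted odds ratio on a binary predictor matches the closed-form 2x2
    contingency-table odds ratio within 2 SEs of the log odds ratio."""
    rng = np.random.default_rng(3)
    n = 200
    x = rng.integers(0, 2, n)
    p = np.where(x == 1, 0.8, 0.2)
    y = (rng.random(n) < p).astype(int)
    # independent closed-form oracle from the contingency table
    a = ((x == 1) & (y == 1)).sum()
    b = ((x == 1) & (y == 0)).sum()
    c = ((x == 0) & (y == 1)).sum()
    d = ((x == 0) & (y == 0)).sum()
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    model = fit_base(
        ClassifierSpec("logistic-regression", {"C": 1e4}), pd.DataFrame({"x": x}), y
    )
    fitted_log_or = float(model.estimator.coef_.ravel()[0])
    assert abs(fitted_log_or - log_or) < 2 * se


def test_tree_importance_prefers_predictive_over_noise():
    rng = np.random.default_rng(1)
    n = 400
    signal = rng.normal(size=n)
    X = pd.DataFrame({"noise": rng.normal(size=n), "signal": signal})
    y = (signal > 0).astype(int)
    model = fit_base(ClassifierSpec("decision-tree"), X, y)
    ranking = importance(model, X, y)
    assert ranking.ordered_predictors[0] == "signal"


def test_logistic_importance_recovers_planted_coefficient_order():
    """Standardised-coefficient ranking recovers planted magnitudes
    (2.0, -3.0, 0.1) as the order (b, a, c) at large n."""
    rng = np.random.default_rng(5)
    n = 5000
    X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
    logits = 2.0 * X["a"] - 3.0 * X["b"] + 0.1 * X["c"]
    y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
    model = fit_base(ClassifierSpec("logistic-regression"), X, y)
    ranking = importance(model, X, y)
    assert ranking.ordered_predictors == ["b", "a", "c"]


def test_rfe_ranking_is_permutation_with_full_elimination(trial_dataset):
    X = feature_frame(trial_dataset)
    y = trial_dataset.indexes["is_key_distributor"].to_numpy(int)
    model = fit_base(ClassifierSpec("support-vector-machine", {"random_state": 0}), X, y)
    ranking = importance(model, X, y)
    assert sorted(ranking.ordered_predictors) == sorted(X.columns)
    # one elimination per round: the scores are exactly p..1
    assert sorted(ranking.scores, reverse=True) == list(
        map(float, range(len(X.columns), 0, -1))
    )


def test_importance_rankings_are_permutations(trial_dataset):
    X = feature_frame(trial_dataset)
    y = trial_dataset.indexes["is_key_distributor"].to_numpy(int)
    for family in ("logistic-regression", "decision-tree", "random-forest"):
        model = fit_base(ClassifierSpec(family, {}), X, y)
        ranking = importance(model, X, y)
        assert sorted(ranking.ordered_predictors) == sorted(X.columns)
        assert all(a >= b for a, b in zip(ranking.scores, ranking.scores[1:]))


def _ranking(order):
    return ImportanceRanking(
        family="decision-tree",
        ordered_predictors=list(order),
        scores=list(map(float, range(len(order), 0, -1))),
    )


def test_vote_select_identical_rankings():
    r = _ranking("abcde")
    assert set(vote_select([r] * 4, top_k=3)) == {"a", "b", "c"}


def test_vote_select_single_common_predictor():
    rankings = [
        _ranking(["q", "a", "b", "c"]),
        _ranking(["b", "q", "a", "c"]),
        _ranking(["c", "q", "b", "a"]),
        _ranking(["q", "c", "a", "b"]),
    ]
    assert vote_select(rankings, top_k=2) == ["q"]


def test_vote_select_full_prefix_returns_everything():
    rng = np.random.default_rng(0)
    letters = list("abcdefg")
    rankings = [_ranking(rng.permutation(letters)) for _ in range(4)]
    assert set(vote_select(rankings, top_k=len(letters))) == set(letters)


def test_vote_select_auto_increments_until_nonempty():
    rankings = [
        _ranking(["a", "b", "c", "d"]),
        _ranking(["b", "c", "d", "a"]),
        _ranking(["c", "d", "a", "b"]),
        _ranking(["d", "a", "b", "c"]),
    ]
    selected = vote_select(rankings, top_k=1)
    assert selected  # grows k until the 4-way intersection is non-empty
    # the result sits inside every ranking's top-k' prefix for the k' used
    k_used = max(max(r.ordered_predictors.index(s) for s in selected) for r in rankings) + 1
    for r in rankings:
        assert set(selected) <= set(r.ordered_predictors[:k_used])


def test_vote_select_rejects_mismatched_universes():
    with pytest.raises(SchemaError):
        vote_select([_ranking("abc"), _ranking("abd"), _ranking("abc"), _ranking("abc")])


def test_ensemble_stub_probabilities_and_tie_rule():
    X = pd.DataFrame({"x": [0.0]})
    models = [stub_model([p]) for p in (0.2, 0.4, 0.6, 0.8)]
    proba, labels = ensemble_predict(models, [0.25] * 4, X)
    assert proba[0] == pytest.approx(0.5)
    assert labels[0] == 1  # tie at the threshold goes to the positive class


def test_ensemble_degenerate_weights_identity():
    X = pd.DataFrame({"x": [0.0, 0.0]})
    models = [stub_model([0.3, 0.7]), stub_model([0.9, 0.9]),
              stub_model([0.1, 0.1]), stub_model([0.5, 0.5])]
    proba, _ = ensemble_predict(models, [1, 0, 0, 0], X)
    assert np.allclose(proba, [0.3, 0.7])


def test_ensemble_matches_brute_force_weighted_mean():
    rng = np.random.default_rng(2)
    n = 100
    P = rng.random((4, n))
    w = np.array([0.4, 0.3, 0.2, 0.1])
    models = [stub_model(P[m]) for m in range(4)]
    proba, _ = ensemble_predict(models, w, pd.DataFrame({"x": np.zeros(n)}))
    oracle = sum(w[m] * P[m] for m in range(4))  # independent weighted mean
    assert np.max(np.abs(proba - oracle)) < 1e-12


def test_ensemble_probability_is_convex_combination(trial_dataset):
    X = feature_frame(trial_dataset)
    y = trial_dataset.indexes["is_key_distributor"].to_numpy(int)
    clf = KeyInfluencerClassifier(random_state=0).fit(X, y)
    member = np.column_stack(
        [m.predict_proba1(X[clf.selected_predictors_]) for m in clf.models_]
    )
    p = clf.predict_proba(X)[:, 1]
    assert (p >= member.min(axis=1) - 1e-12).all()
    assert (p <= member.max(axis=1) + 1e-12).all()


def test_ensemble_weight_count_mismatch():
    with pytest.raises(ConfigurationError):
        ensemble_predict([stub_model([0.5])] * 4, [0.5, 0.5], pd.DataFrame({"x": [0]}))


def test_run_identification_recovers_planted_predictors():
    """With signal confined to three covariates, the cross-model vote keeps
    all three."""
    cfg = GeneratorConfig(
        rng_seed=4,
        n_indexes=1000,
        propensity_coefficients={
            "partner_count": 1.5,
            "app_use_freq": 1.2,
            "disclosed_orientation": 1.0,
        },
        scale_signal=0.0,
    )
    d = generate_trial(cfg)
    res = run_identification(d, "distributor", random_state=4)
    assert {"partner_count", "app_use_freq", "disclosed_orientation"} <= set(
        res.classifier.selected_predictors_
    )


def test_scale_only_signal_selects_scale_items(trial_dataset):
    """When the feature set holds only scale items plus noise covariates and
    the scale fully loads on the propensity, the vote picks scale items."""
    cfg = GeneratorConfig(rng_seed=9, scale_signal=1.0)
    d = generate_trial(cfg)
    X = d.indexes[SCALE_COLS + ["age", "education"]].astype(float)
    y = d.indexes["is_key_distributor"].to_numpy(int)
    clf = KeyInfluencerClassifier(random_state=9).fit(X, y)
    assert set(clf.selected_predictors_) <= set(SCALE_COLS)


def test_predicted_positive_fraction_is_sane(trial_dataset):
    res = run_identification(trial_dataset, "distributor", random_state=1)
    assert 0.05 <= res.predicted.mean() <= 0.45


def test_planted_signal_ranks_above_noise_across_families():
    """Each family places the planted predictors above pure noise with high
    probability at n=2000."""
    hits = {f: 0 for f in ("logistic-regression", "support-vector-machine",
                           "decision-tree", "random-forest")}
    reps = 5
    for rep in range(reps):
        rng = np.random.default_rng(100 + rep)
        n = 2000
        X = pd.DataFrame(
            {
                "planted1": rng.normal(size=n),
                "planted2": rng.normal(size=n),
                "noise1": rng.normal(size=n),
                "noise2": rng.normal(size=n),
            }
        )
        logits = 1.5 * X["planted1"] - 1.5 * X["planted2"]
        y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
        for family in hits:
            model = fit_base(ClassifierSpec(family, {"random_state": rep}
                                            if family != "logistic-regression" else {}), X, y)
            ranking = importance(model, X, y)
            if set(ranking.ordered_predictors[:2]) == {"planted1", "planted2"}:
                hits[family] += 1
    for family, h in hits.items():
        assert h >= reps - 1, family
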