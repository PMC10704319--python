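"""Ensemble identification of key influencers.

Implements the two-pass identification system:

1. fit four base classifiers (logistic regression, linear-kernel support
   vector machine, decision tree, random forest) on the full predictor set
   and compute one predictor-importance ranking per model — logistic
   regression by absolute standardised coefficient, the SVM by recursive
   feature elimination order (one predictor eliminated per iteration), the
   tree models by total Gini-impurity decrease;
2. the four rankings vote for the selected predictors (the intersection of
   the four top-k prefixes), the models are refitted on the selected
   predictors only, and a soft-voting ensemble averages their class-1
   probabilities with configurable weights.

:class:`KeyInfluencerClassifier` wraps the whole procedure as a
scikit-learn-compatible estimator (``fit`` / ``predict`` /
``predict_proba``); the module-level operations are thin functions over its
pieces so each stage can be exercised on its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.calibration import CalibratedClassifierCV
from sklearn.feature_selection import RFE
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from peerselect.errors import (
    ConfigurationError,
    DegenerateLabelError,
    SchemaError,
)
from peerselect.synthetic import SCALE_COLS, TrialDataset

FAMILIES = ("logistic-regression", "support-vector-machine", "decision-tree", "random-forest")

Family = Literal[
    "logistic-regression", "support-vector-machine", "decision-tree", "random-forest"
]


@dataclass(frozen=True)
class ClassifierSpec:
    """One base classifier: its family and (overridable) hyperparameters."""

    family: Family
    hyperparameters: dict = field(default_factory=dict)
    calibration: bool = True  # Platt-type sigmoid calibration for margin models

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(f"family: unknown classifier family {self.family!r}")


def default_specs(random_state: int = 0) -> list[ClassifierSpec]:
    """The four default base classifiers with fixed, sensible hyperparameters."""
    return [
        ClassifierSpec("logistic-regression", {"C": 1.0, "max_iter": 2000}),
        ClassifierSpec("support-vector-machine", {"C": 1.0, "random_state": random_state}),
        ClassifierSpec(
            "decision-tree", {"min_samples_leaf": 5, "random_state": random_state}
        ),
        ClassifierSpec(
            "random-forest", {"n_estimators": 100, "random_state": random_state}
        ),
    ]


@dataclass
class EnsembleConfig:
    """Soft-voting ensemble configuration; weights normalise to sum 1."""

    base_specs: list[ClassifierSpec] = field(default_factory=default_specs)
    weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    decision_threshold: float = 0.5

    def __post_init__(self) -> None:
        if len(self.base_specs) != 4:
            raise ConfigurationError("base_specs: exactly four base classifiers expected")
        if len(self.weights) != len(self.base_specs):
            raise ConfigurationError("weights: one weight per base classifier required")
        if any(w < 0 for w in self.weights):
            raise ConfigurationError("weights: must be non-negative")
        total = float(sum(self.weights))
        if total <= 0:
            raise ConfigurationError("weights: must not all be zero")
        self.weights = tuple(w / total for w in self.weights)
        if not (0.0 < self.decision_threshold < 1.0):
            raise ConfigurationError("decision_threshold: must lie in (0, 1)")


@dataclass
class ImportanceRanking:
    """One model's predictors ordered most-important-first with scores."""

    family: Family
    ordered_predictors: list[str]
    scores: list[float]

    def __post_init__(self) -> None:
        if len(self.ordered_predictors) != len(self.scores):
            raise SchemaError("ordered_predictors and scores must have equal length")
        if any(a < b for a, b in zip(self.scores, self.scores[1:])):
            raise SchemaError("scores must be non-increasing along the ranking")


@dataclass
class FittedModel:
    """A fitted base classifier plus the standardisation learnt on its
    training split (continuous predictors z-scored, binary left as 0/1)."""

    spec: ClassifierSpec
    estimator: object
    predictors: list[str]
    scale_mean: pd.Series
    scale_sd: pd.Series

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        if list(X.columns) != self.predictors:
            X = X[self.predictors]
        Z = (X - self.scale_mean) / self.scale_sd
        return Z.to_numpy(dtype=float)

    def predict_proba1(self, X: pd.DataFrame) -> np.ndarray:
        """Class-1 probability for every row."""
        missing = set(self.predictors) - set(X.columns)
        if missing:
            raise SchemaError(f"missing predictor column(s): {sorted(missing)}")
        proba = self.estimator.predict_proba(self.transform(X[self.predictors]))
        return proba[:, list(self.estimator.classes_).index(1)]


def _make_estimator(spec: ClassifierSpec):
    hp = dict(spec.hyperparameters)
    if spec.family == "logistic-regression":
        return LogisticRegression(**{"C": 1.0, "max_iter": 2000, **hp})
    if spec.family == "support-vector-machine":
        hp.setdefault("random_state", 0)
        svc = SVC(kernel="linear", **hp)
        if not spec.calibration:
            return svc
        # Platt-type sigmoid calibration so the margin model can soft-vote
        return CalibratedClassifierCV(svc, method="sigmoid", cv=3, ensemble=False)
    if spec.family == "decision-tree":
        hp.setdefault("min_samples_leaf", 5)
        hp.setdefault("random_state", 0)
        return DecisionTreeClassifier(**hp)
    hp.setdefault("n_estimators", 100)
    hp.setdefault("random_state", 0)
    return RandomForestClassifier(**hp)


def _standardisation(X: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Mean/SD per column; binary (<=2 distinct values) columns pass through."""
    mean = pd.Series(0.0, index=X.columns)
    sd = pd.Series(1.0, index=X.columns)
    for col in X.columns:
        vals = X[col]
        if vals.nunique() > 2:
            s = float(vals.std(ddof=0))
            if s > 0:
                mean[col] = float(vals.mean())
                sd[col] = s
    return mean, sd


def fit_base(spec: ClassifierSpec, X: pd.DataFrame, y: Sequence[int]) -> FittedModel:
    """Fit one base classifier; deterministic given the spec's random_state."""
    y = np.asarray(y, dtype=int)
    if X.isna().any().any():
        raise ValueError("X contains missing values; impute before fitting")
    classes = np.unique(y)
    if classes.size < 2:
        raise DegenerateLabelError("y contains a single class; cannot fit a classifier")
    mean, sd = _standardisation(X)
    model = FittedModel(spec, _make_estimator(spec), list(X.columns), mean, sd)
    model.estimator.fit(model.transform(X), y)
    return model


def importance(fitted: FittedModel, X: pd.DataFrame, y: Sequence[int]) -> ImportanceRanking:
    """Family-specific predictor-importance ranking.

    - logistic regression: |standardised coefficient|, descending;
    - SVM: recursive feature elimination, one predictor per iteration
      (last-eliminated = most important);
    - decision tree / random forest: total Gini-impurity decrease, descending.

    Ties break by column order so rankings are deterministic.
    """
    if set(fitted.predictors) != set(X.columns):
        raise SchemaError("fitted model and X disagree on predictor names")
    X = X[fitted.predictors]
    names = np.asarray(fitted.predictors)
    family = fitted.spec.family
    if family == "logistic-regression":
        scores = np.abs(np.asarray(fitted.estimator.coef_).ravel())
    elif family == "support-vector-machine":
        # refit an uncalibrated linear SVM inside RFE; ranking_ is 1 for the
        # surviving predictor, increasing with earlier elimination
        svc = SVC(kernel="linear", **dict(fitted.spec.hyperparameters))
        rfe = RFE(svc, n_features_to_select=1, step=1)
        rfe.fit(fitted.transform(X), np.asarray(y, dtype=int))
        scores = (len(names) - rfe.ranking_ + 1).astype(float)
    else:
        scores = np.asarray(fitted.estimator.feature_importances_, dtype=float)
    order = np.argsort(-scores, kind="stable")
    return ImportanceRanking(
        family=family,
        ordered_predictors=[str(n) for n in names[order]],
        scores=[float(s) for s in scores[order]],
    )


def vote_select(rankings: Sequence[ImportanceRanking], top_k: int | None = None) -> list[str]:
    """Cross-model predictor voting: the predictors ranked in the top-k of
    every model's importance list.

    If the four top-k prefixes share no predictor, k is incremented until the
    intersection is non-empty.  Default ``top_k`` is ceil(p/3).  The result
    is ordered by mean rank across the four lists (best first).
    """
    if len(rankings) == 0:
        raise SchemaError("at least one ranking required")
    universe = set(rankings[0].ordered_predictors)
    for r in rankings[1:]:
        if set(r.ordered_predictors) != universe:
            raise SchemaError("rankings cover different predictor sets")
    p = len(universe)
    k = math.ceil(p / 3) if top_k is None else int(top_k)
    if not (1 <= k <= p):
        raise ConfigurationError(f"top_k: must be in [1, {p}]")
    while True:
        common = set(rankings[0].ordered_predictors[:k])
        for r in rankings[1:]:
            common &= set(r.ordered_predictors[:k])
        if common or k >= p:
            break
        k += 1
    mean_rank = {
        name: float(np.mean([r.ordered_predictors.index(name) for r in rankings]))
        for name in common
    }
    return sorted(common, key=lambda n: (mean_rank[n], n))


def ensemble_predict(
    models: Sequence[FittedModel],
    weights: Sequence[float],
    X: pd.DataFrame,
    decision_threshold: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Soft-voting ensemble: weighted average of member class-1 probabilities.

    Returns ``(probability, label)``; the label is 1 when the averaged
    probability reaches the decision threshold (ties go to the positive
    class).
    """
    if len(weights) != len(models):
        raise ConfigurationError("weights: one weight per model required")
    w = np.asarray(weights, dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise ConfigurationError("weights: must be non-negative with positive sum")
    w = w / w.sum()
    proba = np.zeros(len(X), dtype=float)
    for wm, model in zip(w, models):
        proba += wm * model.predict_proba1(X)
    labels = (proba >= decision_threshold).astype(int)
    return proba, labels


class KeyInfluencerClassifier(BaseEstimator, ClassifierMixin):
    """Two-pass ensemble identification system as a scikit-learn estimator.

    ``fit(X, y)`` runs the full procedure on a predictor DataFrame: fit the
    four base families on all predictors, rank predictor importance per
    family, vote-select the common top predictors, refit the four models on
    the selected predictors, and form the soft-voting ensemble.

    Parameters
    ----------
    top_k:
        Prefix length for cross-model predictor voting; ``None`` means
        ceil(p/3), auto-incremented until the 4-way intersection is
        non-empty.
    weights:
        Soft-voting weights of the four base models (normalised to sum 1).
    decision_threshold:
        Class-1 probability needed to flag an index (ties flag positive).
    random_state:
        Seed for every stochastic base learner.

    Attributes (after ``fit``)
    --------------------------
    rankings_ : list[ImportanceRanking]
        First-pass importance ranking per family.
    selected_predictors_ : list[str]
        Predictors chosen by the cross-model vote.
    models_ : list[FittedModel]
        Second-pass models refitted on the selected predictors.
    """

    def __init__(
        self,
        top_k: int | None = None,
        weights: tuple = (0.25, 0.25, 0.25, 0.25),
        decision_threshold: float = 0.5,
        random_state: int = 0,
    ) -> None:
        self.top_k = top_k
        self.weights = weights
        self.decision_threshold = decision_threshold
        self.random_state = random_state

    def _specs(self) -> list[ClassifierSpec]:
        return default_specs(self.random_state)

    def fit(self, X: pd.DataFrame, y) -> "KeyInfluencerClassifier":
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=int)
        specs = self._specs()
        first_pass = [fit_base(spec, X, y) for spec in specs]
        self.rankings_ = [importance(m, X, y) for m in first_pass]
        self.selected_predictors_ = vote_select(self.rankings_, self.top_k)
        Xs = X[self.selected_predictors_]
        self.models_ = [fit_base(spec, Xs, y) for spec in specs]
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "models_")
        X = pd.DataFrame(X)
        p1, _ = ensemble_predict(
            self.models_, self.weights, X[self.selected_predictors_],
            self.decision_threshold,
        )
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        p1 = self.predict_proba(X)[:, 1]
        return (p1 >= self.decision_threshold).astype(int)


def predictor_columns(dataset: TrialDataset) -> list[str]:
    """Predictor columns for identification: covariates (arm one-hot encoded)
    plus the six leadership-scale items; never the outcome counts/labels."""
    return ["arm_SD-M", "arm_SD-M-PR"] + dataset.covariate_names() + SCALE_COLS


def feature_frame(dataset: TrialDataset) -> pd.DataFrame:
    """Numeric predictor matrix for a trial dataset."""
    idx = dataset.indexes
    X = pd.DataFrame(index=idx.index)
    X["arm_SD-M"] = (idx["arm"] == "SD-M").astype(float)
    X["arm_SD-M-PR"] = (idx["arm"] == "SD-M-PR").astype(float)
    for col in dataset.covariate_names() + SCALE_COLS:
        X[col] = idx[col].astype(float)
    return X


RULES = ("distributor", "promoter", "detector")
RULE_LABEL = {
    "distributor": "is_key_distributor",
    "promoter": "is_key_promoter",
    "detector": "is_key_detector",
}


@dataclass
class IdentificationResult:
    """Output of a full identification run on one dataset."""

    rule: str
    classifier: KeyInfluencerClassifier
    probabilities: np.ndarray
    predicted: np.ndarray
    index_ids: list[str]


def run_identification(
    dataset: TrialDataset,
    rule: str,
    config: EnsembleConfig | None = None,
    random_state: int = 0,
) -> IdentificationResult:
    """End-to-end identification on a labelled dataset for one rule."""
    if rule not in RULES:
        raise ConfigurationError(f"rule: must be one of {RULES}")
    config = config or EnsembleConfig()
    clf = KeyInfluencerClassifier(
        weights=config.weights,
        decision_threshold=config.decision_threshold,
        random_state=random_state,
    )
    X = feature_frame(dataset)
    y = dataset.indexes[RULE_LABEL[rule]].to_numpy(dtype=int)
    clf.fit(X, y)
    proba = clf.predict_proba(X)[:, 1]
    pred = (proba >= config.decision_threshold).astype(int)
    return IdentificationResult(
        rule=rule,
        classifier=clf,
        probabilities=proba,
        predicted=pred,
        index_ids=list(dataset.indexes["index_id"]),
    )
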