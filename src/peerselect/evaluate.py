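"""Metrics, cross-validation harness and comparison statistics.

Covers three layers:

- classification metrics (accuracy, precision, recall, F1) from confusion
  counts with the conservative zero-denominator convention (undefined
  precision/recall/F1 reported as 0);
- a stratified 5-fold cross-validation harness that evaluates the ensemble,
  the four base families and the two leadership-scale cutoffs on identical
  test folds;
- the increased-percentage statistic with its shared-denominator convention
  (100*(n_ml - n_base)/n_total) and the two confidence-interval conventions
  used to summarise it: a Wald difference-of-proportions interval with the
  shared denominator, and mean +/- 1.96 * population-SD for per-fold
  differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.model_selection import StratifiedKFold

from peerselect.baseline import LeadershipScaleClassifier
from peerselect.errors import ConfigurationError
from peerselect.identify import (
    ClassifierSpec,
    KeyInfluencerClassifier,
    RULE_LABEL,
    default_specs,
    feature_frame,
    fit_base,
)
from peerselect.synthetic import SCALE_COLS, TrialDataset

Z95 = norm.ppf(0.975)  # 1.959964...


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsRow:
    model: str
    rule: str
    accuracy: float
    precision: float
    recall: float
    f1: float


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    """Standard confusion counts; positive class = key influencer (1)."""
    t = np.asarray(y_true, dtype=int)
    p = np.asarray(y_pred, dtype=int)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    if not (np.isin(t, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels must be binary 0/1")
    return ConfusionCounts(
        tp=int(((t == 1) & (p == 1)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
    )


def metrics(counts: ConfusionCounts, model: str = "", rule: str = "") -> MetricsRow:
    """Accuracy, precision, recall and F1 from confusion counts.

    F1 is the harmonic mean of precision and recall; any ratio with a zero
    denominator is reported as 0.
    """
    n = counts.n
    if n <= 0:
        raise ValueError("empty confusion table")
    acc = (counts.tp + counts.tn) / n
    prec = counts.tp / (counts.tp + counts.fp) if (counts.tp + counts.fp) else 0.0
    rec = counts.tp / (counts.tp + counts.fn) if (counts.tp + counts.fn) else 0.0
    f1 = 2 * prec * rec / (prec + rec) if (prec + rec) else 0.0
    return MetricsRow(model=model, rule=rule, accuracy=acc, precision=prec, recall=rec, f1=f1)


METHODS = ("LR", "SVM", "DT", "RF", "ensemble", "cutoffA", "cutoffB")
_FAMILY_OF = {
    "LR": "logistic-regression",
    "SVM": "support-vector-machine",
    "DT": "decision-tree",
    "RF": "random-forest",
}


def fold_plan(n: int, y: Sequence[int], seed: int = 0, k: int = 5) -> list[np.ndarray]:
    """Stratified k-fold test-index sets (stratification avoids single-class
    training folds at low label prevalence)."""
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test_idx for _, test_idx in skf.split(np.zeros(n), np.asarray(y, dtype=int))]


@dataclass
class CrossValidationResult:
    method: str
    rule: str
    per_fold: list[MetricsRow]
    folds: list[np.ndarray]
    predictions: np.ndarray  # out-of-fold predicted flag per index
    scores: np.ndarray  # out-of-fold ranking score (class-1 probability for
    # ML methods, scale total for the cutoff baselines)

    @property
    def average(self) -> MetricsRow:
        return MetricsRow(
            model=self.method,
            rule=self.rule,
            accuracy=float(np.mean([m.accuracy for m in self.per_fold])),
            precision=float(np.mean([m.precision for m in self.per_fold])),
            recall=float(np.mean([m.recall for m in self.per_fold])),
            f1=float(np.mean([m.f1 for m in self.per_fold])),
        )


def _fit_predict(method: str, X_tr, y_tr, X_te, random_state: int) -> np.ndarray:
    """Class-1 probability on the test split."""
    if method == "ensemble":
        clf = KeyInfluencerClassifier(random_state=random_state)
        clf.fit(X_tr, y_tr)
        return clf.predict_proba(X_te)[:, 1]
    spec_by_family = {s.family: s for s in default_specs(random_state)}
    spec: ClassifierSpec = spec_by_family[_FAMILY_OF[method]]
    model = fit_base(spec, X_tr, y_tr)
    return model.predict_proba1(X_te)


def cross_validate(
    dataset: TrialDataset,
    rule: str,
    method: str,
    fold_seed: int = 0,
    random_state: int = 0,
) -> CrossValidationResult:
    """5-fold cross-validation of one method for one key-influencer rule.

    ML methods are fitted on the 4 training folds and evaluated on the held
    out fold; the scale cutoffs learn their thresholds on the training folds'
    totals and flag the test fold, so every method is scored on identical
    test sets.  Averages are unweighted means over the 5 folds.
    """
    if method not in METHODS:
        raise ConfigurationError(f"method: must be one of {METHODS}")
    y = dataset.indexes[RULE_LABEL[rule]].to_numpy(dtype=int)
    folds = fold_plan(len(y), y, seed=fold_seed)
    X = feature_frame(dataset)
    totals = dataset.indexes[SCALE_COLS].sum(axis=1).to_numpy(dtype=int)
    oof = np.zeros(len(y), dtype=int)
    oof_scores = np.zeros(len(y), dtype=float)
    rows: list[MetricsRow] = []
    all_idx = np.arange(len(y))
    for test_idx in folds:
        train_idx = np.setdiff1d(all_idx, test_idx)
        if method in ("cutoffA", "cutoffB"):
            clf = LeadershipScaleClassifier(cutoff=method[-1])
            clf.fit(totals[train_idx])
            pred = clf.predict(totals[test_idx])
            score = totals[test_idx].astype(float)
        else:
            score = _fit_predict(
                method, X.iloc[train_idx], y[train_idx], X.iloc[test_idx], random_state
            )
            pred = (score >= 0.5).astype(int)
        oof[test_idx] = pred
        oof_scores[test_idx] = score
        rows.append(metrics(confusion(y[test_idx], pred), model=method, rule=rule))
    return CrossValidationResult(
        method=method, rule=rule, per_fold=rows, folds=folds,
        predictions=oof, scores=oof_scores,
    )


def metrics_table(results: Sequence[CrossValidationResult]) -> pd.DataFrame:
    """Average cross-validated metrics, one row per (rule, method)."""
    rows = []
    for r in results:
        avg = r.average
        rows.append(
            {
                "rule": r.rule,
                "method": r.method,
                "accuracy": round(avg.accuracy, 2),
                "precision": round(avg.precision, 2),
                "recall": round(avg.recall, 2),
                "f1": round(avg.f1, 2),
            }
        )
    return pd.DataFrame(rows)


def increased_percentage(n_ml: int, n_base: int, n_total: int) -> float:
    """Percentage-point gain of the ML strategy over the baseline, computed
    on the shared total: 100*(n_ml - n_base)/n_total, one decimal."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if n_ml > n_total or n_base > n_total:
        raise ValueError("counts cannot exceed n_total")
    return round(100.0 * (n_ml - n_base) / n_total, 1)


def wald_diff_ci(
    n_ml: int, n_base: int, n_total: int, level: float = 0.95
) -> tuple[float, float]:
    """Wald difference-of-proportions CI with a shared denominator.

    p1 = n_ml/n_total, p2 = n_base/n_total;
    CI = (p1-p2) +/- z*sqrt(p1(1-p1)/n_total + p2(1-p2)/n_total),
    reported in percent at one decimal.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    z = norm.ppf(0.5 + level / 2)
    p1, p2 = n_ml / n_total, n_base / n_total
    se = float(np.sqrt(p1 * (1 - p1) / n_total + p2 * (1 - p2) / n_total))
    diff = p1 - p2
    return (round(100 * (diff - z * se), 1), round(100 * (diff + z * se), 1))


def fold_diff_ci(
    per_fold_diffs: Sequence[float], level: float = 0.95
) -> tuple[float, float, float]:
    """Mean per-fold difference with a mean +/- z*SD interval, where the SD
    is the population (n-denominator) standard deviation of the fold
    differences.  Returns ``(mean, lower, upper)`` at one decimal."""
    d = np.asarray(list(per_fold_diffs), dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 fold differences")
    z = norm.ppf(0.5 + level / 2)
    mean = float(d.mean())
    sd = float(d.std(ddof=0))
    return (round(mean, 1), round(mean - z * sd, 1), round(mean + z * sd, 1))
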