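"""Human-identification baseline: the 6-item self-reported leadership scale.

Indexes rate six social-influence scenarios 0-4; the total (0-24) ranks them
and the top ~20% by rank order are flagged as key influencers.  Integer
totals tie, so the target head-count usually falls between two adjacent
thresholds; both bracketing cutoffs are kept — cutoff A (higher threshold,
flags at most the target count) and cutoff B (lower threshold, flags at
least the target count).  In the original trial (n=309, target 60) this
yields 49 indexes at >=11 points and 81 at >=10 points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from peerselect.errors import ConfigurationError


def score_scale(items: Sequence[int]) -> int:
    """Total leadership-scale score: the simple sum of the six 0-4 items."""
    items = list(items)
    if len(items) != 6:
        raise ValueError(f"expected 6 scale items, got {len(items)}")
    for v in items:
        if not float(v).is_integer() or not (0 <= int(v) <= 4):
            raise ValueError(f"scale item {v!r} outside 0..4")
    return int(sum(items))


@dataclass(frozen=True)
class CutoffPair:
    """The two thresholds bracketing a rank-order target count under ties.

    ``threshold_A = threshold_B + 1``; flagging at >= threshold_A captures
    ``count_A <= target_count`` indexes, at >= threshold_B captures
    ``count_B >= target_count``.
    """

    target_count: int
    threshold_A: int
    count_A: int
    threshold_B: int
    count_B: int

    def __post_init__(self) -> None:
        assert self.threshold_A == self.threshold_B + 1
        assert self.count_A <= self.target_count <= self.count_B

    def threshold(self, which: str) -> int:
        if which not in ("A", "B"):
            raise ConfigurationError("cutoff: must be 'A' or 'B'")
        return self.threshold_A if which == "A" else self.threshold_B


def find_cutoffs(scores: Iterable[int], target_fraction: float = 0.2) -> CutoffPair:
    """Find the dual rank-order cutoffs for a target top fraction.

    ``threshold_B`` is the largest score s with at least
    ``round(target_fraction * n)`` indexes scoring >= s; ``threshold_A`` is
    one point higher.  With no ties at the boundary both cutoffs capture the
    target count exactly.
    """
    scores = np.asarray(list(scores), dtype=int)
    if scores.size == 0:
        raise ValueError("empty score list")
    if not (0.0 < target_fraction < 1.0):
        raise ConfigurationError("target_fraction: must lie in (0, 1)")
    n = scores.size
    target = int(round(target_fraction * n))
    target = max(target, 1)
    # counts at or above each candidate threshold; scores are bounded 0..24
    # but accept any integer support
    lo, hi = int(scores.min()), int(scores.max())
    threshold_B = lo
    for s in range(hi, lo - 1, -1):
        if int((scores >= s).sum()) >= target:
            threshold_B = s
            break
    count_B = int((scores >= threshold_B).sum())
    threshold_A = threshold_B + 1
    count_A = int((scores >= threshold_A).sum())
    return CutoffPair(
        target_count=target,
        threshold_A=threshold_A,
        count_A=count_A,
        threshold_B=threshold_B,
        count_B=count_B,
    )


def baseline_classify(scores: Iterable[int], cutoffs: CutoffPair, which: str = "A") -> np.ndarray:
    """Flag every index whose total reaches the chosen cutoff's threshold."""
    threshold = cutoffs.threshold(which)
    return (np.asarray(list(scores), dtype=int) >= threshold).astype(int)


class LeadershipScaleClassifier(BaseEstimator, ClassifierMixin):
    """Rank-order leadership-scale cutoff as a scikit-learn estimator.

    ``X`` is either a 1-column array/DataFrame of scale totals or a 6-column
    one of raw items (summed internally).  ``fit`` learns the dual cutoff
    pair from the training totals; ``predict`` applies the chosen cutoff.

    Parameters
    ----------
    target_fraction:
        Top fraction of indexes to flag by rank order (default 0.2).
    cutoff:
        'A' (conservative: at most the target count) or 'B' (liberal: at
        least the target count).
    """

    def __init__(self, target_fraction: float = 0.2, cutoff: str = "A") -> None:
        self.target_fraction = target_fraction
        self.cutoff = cutoff

    @staticmethod
    def _totals(X) -> np.ndarray:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 1:
            return arr.astype(int)
        if arr.shape[1] == 1:
            return arr[:, 0].astype(int)
        if arr.shape[1] == 6:
            return arr.sum(axis=1).astype(int)
        raise ValueError("expected scale totals (1 column) or 6 item columns")

    def fit(self, X, y=None) -> "LeadershipScaleClassifier":
        totals = self._totals(X)
        self.cutoffs_ = find_cutoffs(totals, self.target_fraction)
        self.classes_ = np.array([0, 1])
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "cutoffs_")
        return baseline_classify(self._totals(X), self.cutoffs_, self.cutoff)
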