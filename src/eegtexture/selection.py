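"""Chi-square feature ranking against the class label, and top-k selection.

Each continuous feature is discretized into ``n_bins`` equal-width bins
over its observed range and a bins x classes contingency table of counts
is formed; the feature's score is the Pearson chi-square statistic
sum((O - E)^2 / E) over cells with positive expected count. Larger
scores mean stronger dependence between the feature and the class.
Constant features fall into a single bin and score 0. No continuity
correction is applied: the scores are used only for ranking.

Because bins are equal-width over the observed range, bin assignments —
hence scores — are invariant to positive affine rescaling of a feature.

Bin edges are computed on whatever rows are passed in; leakage control
(fitting on training rows only) is the caller's responsibility and is
what :class:`Chi2TopK` gives you for free inside a sklearn pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from .io import FeatureTable

__all__ = ["Chi2Ranking", "chi2_scores", "select_top_k", "Chi2TopK"]


@dataclass(frozen=True)
class Chi2Ranking:
    """Per-feature chi-square scores and the descending-score order.

    Ties are broken by ascending feature index, so the order is a
    deterministic permutation.
    """

    scores: np.ndarray
    order: np.ndarray
    n_bins: int


def _discretize(X: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width binning per column over each column's observed range."""
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    span[span == 0] = 1.0  # constant feature -> everything in bin 0
    bins = np.floor((X - lo) / span * n_bins).astype(np.int64)
    return np.clip(bins, 0, n_bins - 1)


def chi2_scores(
    tbl: FeatureTable | None = None,
    n_bins: int = 10,
    *,
    X: np.ndarray | None = None,
    y: np.ndarray | None = None,
) -> Chi2Ranking:
    """Score every feature by the Pearson chi-square statistic vs the label.

    Accepts either a :class:`~eegtexture.io.FeatureTable` or raw ``X``/``y``
    arrays.
    """
    if tbl is not None:
        X, y = tbl.values, tbl.labels
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    classes, y_idx = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise ValueError("chi-square scoring needs at least two classes")
    if np.min(np.bincount(y_idx)) < 2:
        raise ValueError("each class needs at least 2 subjects")

    n, F = X.shape
    bins = _discretize(X, n_bins)
    # observed counts, vectorized over features: one bincount per class
    obs = np.empty((F, n_bins, classes.size))
    base = np.arange(F, dtype=np.int64) * n_bins
    for c in range(classes.size):
        flat = (base[None, :] + bins[y_idx == c]).ravel()
        obs[:, :, c] = np.bincount(flat, minlength=F * n_bins).reshape(F, n_bins)

    row_tot = obs.sum(axis=2, keepdims=True)  # per bin
    col_tot = obs.sum(axis=1, keepdims=True)  # per class
    expected = row_tot * col_tot / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (obs - expected) ** 2 / expected, 0.0)
    scores = terms.sum(axis=(1, 2))
    order = np.lexsort((np.arange(F), -scores))
    return Chi2Ranking(scores=scores, order=order, n_bins=n_bins)


def select_top_k(rank: Chi2Ranking, k: int) -> np.ndarray:
    """The indices of the k highest-scoring features, best first."""
    n_features = rank.scores.size
    if not 1 <= k <= n_features:
        raise ValueError(f"k must be in 1..{n_features}, got {k}")
    return rank.order[:k]


class Chi2TopK(SelectorMixin, BaseEstimator):
    """Select the k features most dependent on the class label.

    sklearn-compatible selector: ``fit`` computes chi-square scores on
    the rows it sees (inside a pipeline, the training fold only), and
    ``transform`` keeps the top ``k`` columns.

    Parameters
    ----------
    k : int, default=1000
        Number of features to keep (capped at the number available).
    n_bins : int, default=10
        Equal-width bins used to discretize each feature.

    Attributes
    ----------
    scores_ : ndarray of shape (n_features,)
        Chi-square score per feature.
    ranking_ : ndarray of shape (n_features,)
        Feature indices sorted by descending score.
    selected_ : ndarray of shape (min(k, n_features),)
        Indices of the kept features, best first.
    """

    def __init__(self, k: int = 1000, n_bins: int = 10):
        self.k = k
        self.n_bins = n_bins

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if self.k < 1:
            raise ValueError("k must be >= 1")
        rank = chi2_scores(X=X, y=y, n_bins=self.n_bins)
        self.n_features_in_ = X.shape[1]
        self.scores_ = rank.scores
        self.ranking_ = rank.order
        self.selected_ = rank.order[: min(self.k, X.shape[1])]
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "selected_")
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.selected_] = True
        return mask
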