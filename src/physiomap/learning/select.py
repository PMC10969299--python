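"""Radiomic feature selection: ReliefF ranking and wrapper subset search.

The two-stage strategy ranks all features by ReliefF relevance, keeps the top
25%, then runs a learner-specific forward best-first wrapper search scored by
k-fold cross-validated accuracy of the wrapped classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold, cross_val_score

__all__ = ["SelectionReport", "relieff_rank", "top_fraction", "wrapper_select"]


@dataclass
class SelectionReport:
    """Outcome of the two-stage feature selection."""

    weights: np.ndarray
    ranking: np.ndarray                 # feature indices, best first
    shortlist: np.ndarray               # top-25% indices (in ranking order)
    selected: list = field(default_factory=list)
    cv_scores: list = field(default_factory=list)
    seed: int = 0


def relieff_rank(X, y, k_neighbors: int = 10, sigma: float = 2.0,
                 weight_by_distance: bool = False):
    """ReliefF feature weights and descending ranking.

    Features are min-max scaled to [0, 1]; every instance is used once.  For
    an instance, the k nearest hits and (per opposite class, prior-weighted)
    k nearest misses contribute the mean per-feature value difference; the
    weight is the expected miss difference minus the expected hit difference.
    Neighbours can optionally be weighted by an exponential rank kernel with
    width ``sigma``.  Ties in the ranking break by feature order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, y_idx = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise ValueError("ReliefF requires at least two classes")
    n, f = X.shape
    span = X.max(axis=0) - X.min(axis=0)
    span[span == 0] = 1.0
    Xs = (X - X.min(axis=0)) / span
    priors = np.bincount(y_idx) / n

    # full pairwise manhattan distances (cohort-scale data)
    D = np.abs(Xs[:, None, :] - Xs[None, :, :]).sum(axis=2)
    np.fill_diagonal(D, np.inf)

    if weight_by_distance:
        ranks = np.arange(1, k_neighbors + 1, dtype=float)
        infl = np.exp(-((ranks / sigma) ** 2))
        infl = infl / infl.sum()
    else:
        infl = np.full(k_neighbors, 1.0 / k_neighbors)

    W = np.zeros(f)
    for i in range(n):
        ci = y_idx[i]
        for c in range(classes.size):
            same = np.flatnonzero((y_idx == c) & (np.arange(n) != i))
            if same.size < k_neighbors:
                raise ValueError("each class needs more members than k_neighbors")
            nearest = same[np.argsort(D[i, same], kind="stable")[:k_neighbors]]
            diff = (np.abs(Xs[nearest] - Xs[i]) * infl[:, None]).sum(axis=0)
            if c == ci:
                W -= diff / n
            else:
                W += priors[c] / (1.0 - priors[ci]) * diff / n
    order = np.lexsort((np.arange(f), -W))
    return W, order


def top_fraction(ranking: np.ndarray, n_features: int, fraction: float = 0.25) -> np.ndarray:
    """The shortlist: ceil(fraction * n_features) best-ranked feature indices."""
    k = int(np.ceil(fraction * n_features))
    return np.asarray(ranking[:k])


def wrapper_select(shortlist, X, y, classifier, folds: int = 10,
                   threshold: float = 0.01, seed: int = 0,
                   max_features: int | None = None,
                   candidate_cap: int | None = None):
    """Forward best-first wrapper selection scored by k-fold CV accuracy.

    Starting from the empty set, the candidate whose addition maximises the
    cross-validated accuracy of the wrapped classifier is accepted while the
    improvement is at least ``threshold``.  ``candidate_cap`` optionally
    limits each round to the best-ranked remaining shortlist features (a
    compute cap for wide shortlists); ``max_features`` bounds the subset
    size.  Deterministic for fixed seed.

    Returns ``(selected_indices, cv_history)``.
    """
    shortlist = list(shortlist)
    if not shortlist:
        raise ValueError("wrapper selection requires a nonempty shortlist")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)

    def score(feats: list[int]) -> float:
        # ``classifier`` may be a factory taking the subset size (models whose
        # architecture depends on the input width, e.g. the MLP)
        est = classifier(len(feats)) if callable(classifier) and not hasattr(
            classifier, "fit") else clone(classifier)
        try:
            scores = cross_val_score(est, X[:, feats], y, cv=cv, scoring="accuracy",
                                     error_score=np.nan)
        except ValueError:
            return np.nan
        valid = scores[~np.isnan(scores)]
        if valid.size < max(folds - 2, 1):
            return np.nan
        return float(valid.mean())

    selected: list[int] = []
    # the empty subset scores at the majority-class rate
    best = float(np.bincount(np.unique(y, return_inverse=True)[1]).max() / y.size)
    history = []
    remaining = list(shortlist)
    while remaining:
        if max_features is not None and len(selected) >= max_features:
            break
        pool = remaining[:candidate_cap] if candidate_cap else remaining
        trial = [(score(selected + [f]), f) for f in pool]
        trial = [(s, f) for s, f in trial if not np.isnan(s)]
        if not trial:
            break
        s_best, f_best = max(trial, key=lambda t: (t[0], -shortlist.index(t[1])))
        if s_best - best < threshold:
            break
        selected.append(f_best)
        remaining.remove(f_best)
        history.append(s_best)
        best = s_best
    return selected, history
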