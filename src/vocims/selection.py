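"""Wilcoxon rank-sum feature screening.

Each feature is ranked by a two-sided rank-sum p-value comparing the two
training classes; the k features with the smallest p-values are selected
(ties broken by ascending feature index).  The p-value is exact — by
enumeration of rank assignments — when the combined sample size is at most
12 and there are no ties; otherwise the normal approximation with tie and
continuity corrections is used.  Zero-variance features are defined to have
p = 1 so they always rank last.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import norm, rankdata

from .errors import InvalidInputError, InvalidLabelsError

__all__ = ["SelectionResult", "ranksum_pvalue", "rank_features", "select_top_k"]

EXACT_MAX_N = 12  # exact enumeration limit (combined sample size, no ties)


@dataclass(frozen=True)
class SelectionResult:
    """Per-feature p-values plus the ordered selected indices."""

    pvalues: np.ndarray
    selected: np.ndarray
    k: int


def _exact_two_sided(ranks_x: np.ndarray, n: int) -> float:
    """Exact two-sided p by enumerating all C(n, n1) rank assignments."""
    n1 = ranks_x.size
    w_obs = float(ranks_x.sum())
    mu = n1 * (n + 1) / 2.0
    dev = abs(w_obs - mu)
    count = 0
    for combo in combinations(range(1, n + 1), n1):
        if abs(sum(combo) - mu) >= dev - 1e-9:
            count += 1
    return count / comb(n, n1)


def _approx_two_sided(w_x: float, n1: int, n2: int, tie_counts: np.ndarray) -> float:
    """Normal approximation with tie correction and continuity correction."""
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    z = (abs(w_x - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * norm.sf(z)))


def ranksum_pvalue(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value for two independent samples.

    Exact by enumeration for tie-free inputs with ``len(x)+len(y) <= 12``;
    normal approximation (tie-corrected, continuity-corrected) otherwise.
    Identical constant samples yield exactly 1.0.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise InvalidInputError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    ranks = rankdata(pooled)
    n = pooled.size
    has_ties = np.unique(pooled).size < n
    if n <= EXACT_MAX_N and not has_ties:
        return _exact_two_sided(ranks[: x.size], n)
    _, tie_counts = np.unique(pooled, return_counts=True)
    return _approx_two_sided(float(ranks[: x.size].sum()), x.size, y.size, tie_counts)


def rank_features(train_matrix, train_labels) -> np.ndarray:
    """Columnwise two-sided rank-sum p-values (class 1 vs class 0).

    Requires binary labels with at least one member per class.  For combined
    sample sizes above the exact-enumeration limit the computation is fully
    vectorized across columns.
    """
    X = np.asarray(train_matrix, dtype=float)
    labels = np.asarray(train_labels)
    if X.ndim != 2 or X.shape[0] != labels.size:
        raise InvalidInputError("matrix rows must match labels")
    classes = np.unique(labels)
    if classes.size != 2:
        raise InvalidLabelsError(f"need exactly 2 classes, got {classes.size}")
    mask1 = labels == classes[1]
    n1, n0 = int(mask1.sum()), int((~mask1).sum())
    n = n1 + n0

    if n <= EXACT_MAX_N:
        return np.array(
            [ranksum_pvalue(X[mask1, j], X[~mask1, j]) for j in range(X.shape[1])]
        )

    ranks = rankdata(X, axis=0)
    w1 = ranks[mask1].sum(axis=0)
    mu = n1 * (n + 1) / 2.0
    # per-column tie correction: sum(t^3 - t) over tied groups
    n_feat = X.shape[1]
    Xs = np.sort(X, axis=0)
    boundary = np.ones_like(Xs, dtype=bool)
    boundary[1:] = Xs[1:] != Xs[:-1]
    # run lengths of tied groups, all columns at once: flatten column-major so
    # each column is contiguous and every column begins a new run
    starts = np.flatnonzero(boundary.T.ravel())
    lengths = np.diff(np.append(starts, n * n_feat)).astype(float)
    col_of_run = starts // n
    tie_term = np.bincount(col_of_run, weights=lengths**3 - lengths, minlength=n_feat)
    var = n1 * n0 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    pvalues = np.ones(X.shape[1])
    ok = var > 0
    z = np.zeros(X.shape[1])
    z[ok] = np.maximum(np.abs(w1[ok] - mu) - 0.5, 0.0) / np.sqrt(var[ok])
    pvalues[ok] = np.minimum(1.0, 2.0 * norm.sf(z[ok]))
    return pvalues


def select_top_k(pvalues, k: int) -> np.ndarray:
    """Indices of the ``k`` smallest p-values, ties broken by ascending index.

    When fewer than ``k`` features exist, all are returned (in selection
    order).
    """
    if k < 1:
        raise InvalidInputError("k must be >= 1")
    pvalues = np.asarray(pvalues, dtype=float)
    order = np.argsort(pvalues, kind="stable")  # stable sort = index tie-break
    return order[: min(k, pvalues.size)]


def select_features(train_matrix, train_labels, k: int) -> SelectionResult:
    """Convenience wrapper: rank then select."""
    pvalues = rank_features(train_matrix, train_labels)
    selected = select_top_k(pvalues, k)
    return SelectionResult(pvalues=pvalues, selected=selected, k=int(k))
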