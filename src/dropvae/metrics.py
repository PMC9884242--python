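"""Self-contained evaluation metrics.

Partition agreement (adjusted Rand index, Fowlkes–Mallows index) is computed
from the pair-counting confusion table; cluster compactness by the mean
silhouette coefficient; classifier quality by confusion-matrix accuracy and
one-vs-rest ROC AUC with midrank tie handling. These are implemented here
directly (not delegated to scikit-learn) so they form a single auditable
source of truth for every number the pipeline reports; the test suite
cross-checks them against both brute-force pair enumeration and sklearn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_io import ValidationError

__all__ = [
    "PairConfusion",
    "pair_confusion",
    "adjusted_rand_index",
    "fowlkes_mallows",
    "silhouette_score",
    "accuracy",
    "roc_auc_ovr",
]


@dataclass
class PairConfusion:
    """Pair-level confusion counts between two partitions of n items.

    TP: pairs co-clustered in both; FP: co-clustered in A only;
    FN: co-clustered in B only; TN: separated in both.
    TP + FP + FN + TN == n(n-1)/2.
    """

    TP: int
    FP: int
    FN: int
    TN: int


def _as_codes(labels) -> np.ndarray:
    labels = np.asarray(labels)
    _, codes = np.unique(labels, return_inverse=True)
    return codes


def _check_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a, b = _as_codes(a), _as_codes(b)
    if a.shape != b.shape:
        raise ValidationError("label vectors must have equal length")
    if a.size < 2:
        raise ValidationError("need at least 2 items")
    return a, b


def _contingency(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ka, kb = a.max() + 1, b.max() + 1
    return np.bincount(a * kb + b, minlength=ka * kb).reshape(ka, kb)


def _comb2(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.int64)
    return x * (x - 1) // 2


def pair_confusion(labels_a, labels_b) -> PairConfusion:
    """Pair counts from the contingency table (O(ka*kb), exact integers)."""
    a, b = _check_pair(labels_a, labels_b)
    C = _contingency(a, b)
    n = a.size
    tp = int(_comb2(C).sum())
    fp = int(_comb2(C.sum(axis=1)).sum()) - tp
    fn = int(_comb2(C.sum(axis=0)).sum()) - tp
    tn = n * (n - 1) // 2 - tp - fp - fn
    return PairConfusion(tp, fp, fn, tn)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Rand index adjusted for chance, (RI - E[RI]) / (max RI - E[RI]).

    Computed via the contingency pair-counting identity (Hubert–Arabie);
    1 for partitions identical up to relabeling, 0 expected under random
    co-clustering. Degenerate cases where the adjustment denominator is 0
    (both partitions trivial) return 1.0.
    """
    a, b = _check_pair(labels_a, labels_b)
    C = _contingency(a, b)
    n = a.size
    sum_cells = _comb2(C).sum()
    sum_rows = _comb2(C.sum(axis=1)).sum()
    sum_cols = _comb2(C.sum(axis=0)).sum()
    total = n * (n - 1) // 2
    expected = sum_rows * sum_cols / total
    max_index = 0.5 * (sum_rows + sum_cols)
    if max_index == expected:
        return 1.0
    return float((sum_cells - expected) / (max_index - expected))


def _same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    """True if the partitions are identical up to label renaming."""
    pair = a.astype(np.int64) * (b.max() + 1) + b
    return np.unique(pair).size == np.unique(a).size == np.unique(b).size


def fowlkes_mallows(labels_a, labels_b) -> float:
    """Geometric mean of pairwise precision and recall, in [0, 1].

    Identical partitions (up to relabeling) give 1.0 — including the
    all-singletons case where no pair is co-clustered at all; otherwise a
    zero TP+FP or TP+FN is reported as 0 with a warning.
    """
    a, b = _check_pair(labels_a, labels_b)
    if _same_partition(a, b):
        return 1.0
    pc = pair_confusion(a, b)
    if pc.TP + pc.FP == 0 or pc.TP + pc.FN == 0:
        warnings.warn(
            "no co-clustered pairs in one partition; FMI defined as 0",
            stacklevel=2,
        )
        return 0.0
    return float(
        np.sqrt((pc.TP / (pc.TP + pc.FP)) * (pc.TP / (pc.TP + pc.FN)))
    )


def silhouette_score(points, labels) -> float:
    """Mean silhouette coefficient (y - x) / max(x, y), Euclidean metric.

    Per point: x = mean distance to the other members of its own cluster,
    y = minimum over other clusters of the mean distance to that cluster.
    Points in singleton clusters contribute 0.
    """
    X = np.asarray(points, dtype=float)
    codes = _as_codes(labels)
    if X.ndim != 2 or X.shape[0] != codes.size:
        raise ValidationError("points must be n×d with one label per row")
    n = X.shape[0]
    if n < 3:
        raise ValidationError("need at least 3 points")
    k = codes.max() + 1
    if k < 2:
        raise ValidationError("silhouette needs at least 2 clusters")

    sq = np.sum(X**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    D = np.sqrt(np.clip(d2, 0.0, None))
    np.fill_diagonal(D, 0.0)

    sizes = np.bincount(codes, minlength=k)
    # mean distance from every point to every cluster (including its own)
    cluster_sums = np.zeros((n, k))
    for c in range(k):
        cluster_sums[:, c] = D[:, codes == c].sum(axis=1)

    s = np.zeros(n)
    for i in range(n):
        c = codes[i]
        if sizes[c] == 1:
            continue  # singleton: silhouette 0
        x = cluster_sums[i, c] / (sizes[c] - 1)
        other = [cluster_sums[i, cc] / sizes[cc] for cc in range(k) if cc != c]
        y = min(other)
        denom = max(x, y)
        s[i] = 0.0 if denom == 0 else (y - x) / denom
    return float(s.mean())


def accuracy(TP: int, TN: int, FP: int, FN: int) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    if min(TP, TN, FP, FN) < 0:
        raise ValidationError("confusion counts must be non-negative")
    total = TP + TN + FP + FN
    if total == 0:
        raise ValidationError("total number of predictions is zero")
    return (TP + TN) / total


def _midranks(x: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) with ties sharing their midrank."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty(x.size, dtype=float)
    sx = x[order]
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _binary_auc(y: np.ndarray, score: np.ndarray) -> float:
    """Mann–Whitney form of the ROC AUC with midrank tie handling."""
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    ranks = _midranks(score)
    rank_sum = ranks[y].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_auc_ovr(true_labels, scores) -> tuple[dict, float]:
    """One-vs-rest ROC AUC per class plus the unweighted macro average.

    ``scores`` is n × k, column j the score for class j in the sorted order
    of the unique labels. Classes absent from the truth are excluded with a
    warning. For k == 2 a single score column is also accepted (score of
    the second class).
    """
    labels = np.asarray(true_labels)
    classes = np.unique(labels)
    S = np.asarray(scores, dtype=float)
    if S.ndim == 1:
        if classes.size != 2:
            raise ValidationError("1-D scores only valid for binary labels")
        S = np.column_stack([-S, S])
    if S.shape[0] != labels.size:
        raise ValidationError("scores must have one row per item")
    if S.shape[1] < classes.size:
        raise ValidationError(
            f"{S.shape[1]} score columns for {classes.size} classes"
        )
    if classes.size < 2:
        raise ValidationError("need at least 2 classes")
    per_class: dict = {}
    for j, cls in enumerate(classes):
        y = labels == cls
        if y.all() or not y.any():
            warnings.warn(f"class {cls!r} degenerate; AUC undefined", stacklevel=2)
            continue
        per_class[cls] = _binary_auc(y, S[:, j])
    macro = float(np.mean(list(per_class.values())))
    return per_class, macro
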