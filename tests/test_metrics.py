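"""Metric formulas against brute-force pair enumeration and sklearn."""

import math

import numpy as np
import pytest
import sklearn.metrics as skm

from dropvae.data_io import ValidationError
from dropvae.metrics import (
    accuracy,
    adjusted_rand_index,
    fowlkes_mallows,
    pair_confusion,
    roc_auc_ovr,
    silhouette_score,
)

# ---------------------------------------------------------------- oracles


def brute_pair_confusion(a, b):
    """O(n^2) enumeration of co-clustered/separated pairs."""
    TP = FP = FN = TN = 0
    n = len(a)
    for i in range(n):
        for j in range(i + 1, n):
            same_a = a[i] == a[j]
            same_b = b[i] == b[j]
            if same_a and same_b:
                TP += 1
            elif same_a:
                FP += 1
            elif same_b:
                FN += 1
            else:
                TN += 1
    return TP, FP, FN, TN


def brute_ari(a, b):
    TP, FP, FN, TN = brute_pair_confusion(a, b)
    total = TP + FP + FN + TN
    sum_a = TP + FP
    sum_b = TP + FN
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return (TP - expected) / (max_index - expected)


def brute_silhouette(X, labels):
    n = len(X)
    D = [[math.dist(X[i], X[j]) for j in range(n)] for i in range(n)]
    vals = []
    for i in range(n):
        own = [D[i][j] for j in range(n) if j != i and labels[j] == labels[i]]
        if not own:
            vals.append(0.0)
            continue
        x = sum(own) / len(own)
        y = min(
            sum(D[i][j] for j in range(n) if labels[j] == c)
            / sum(1 for j in range(n) if labels[j] == c)
            for c in set(labels)
            if c != labels[i]
        )
        vals.append(0.0 if max(x, y) == 0 else (y - x) / max(x, y))
    return sum(vals) / n


def brute_auc(y, score):
    """Mann-Whitney pair counting: concordant + half ties."""
    pos = [s for s, t in zip(score, y) if t]
    neg = [s for s, t in zip(score, y) if not t]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


# ---------------------------------------------------------------- worked values


def test_ari_worked_example():
    assert adjusted_rand_index([0, 0, 1, 1], [0, 0, 1, 2]) == pytest.approx(4 / 7)


def test_fmi_worked_example():
    # TP=1, FP=0, FN=1 over the 6 pairs -> sqrt(1 * 1/2)
    assert fowlkes_mallows([0, 0, 1, 1], [0, 0, 1, 2]) == pytest.approx(math.sqrt(0.5))


def test_silhouette_worked_example():
    X = np.array([[0.0], [1.0], [10.0], [11.0]])
    labels = [0, 0, 1, 1]
    expected = (0.90476190476 + 0.89473684210 * 2 + 0.90476190476) / 4
    assert silhouette_score(X, labels) == pytest.approx(expected, abs=1e-9)


def test_identical_partitions_score_one():
    a = [0, 1, 1, 2, 0]
    b = [5, 3, 3, 9, 5]  # same partition, renamed
    assert adjusted_rand_index(a, b) == pytest.approx(1.0)
    assert fowlkes_mallows(a, b) == pytest.approx(1.0)


def test_degenerate_partitions():
    # one big cluster vs anything informative: ARI 0
    assert adjusted_rand_index([0, 0, 0, 0], [0, 0, 1, 2]) == pytest.approx(0.0)
    # all singletons vs all singletons: identical partitions -> 1
    assert fowlkes_mallows([0, 1, 2, 3], [3, 2, 1, 0]) == pytest.approx(1.0)
    # disjoint co-clustering with no shared pairs -> 0 with warning
    with pytest.warns(UserWarning):
        assert fowlkes_mallows([0, 0, 1, 1], [0, 1, 2, 3]) == 0.0


def test_pair_confusion_totals(rng):
    a = rng.integers(0, 4, 30)
    b = rng.integers(0, 3, 30)
    pc = pair_confusion(a, b)
    assert pc.TP + pc.FP + pc.FN + pc.TN == 30 * 29 // 2
    assert (pc.TP, pc.FP, pc.FN, pc.TN) == brute_pair_confusion(a.tolist(), b.tolist())


@pytest.mark.parametrize(
    "counts,expected",
    [((3, 5, 1, 1), 0.8), ((4, 6, 0, 0), 1.0), ((0, 0, 3, 7), 0.0)],
)
def test_accuracy_formula(counts, expected):
    TP, TN, FP, FN = counts
    assert accuracy(TP, TN, FP, FN) == pytest.approx(expected)


def test_accuracy_rejects_empty():
    with pytest.raises(ValidationError):
        accuracy(0, 0, 0, 0)


def test_auc_perfect_and_inverted():
    y = np.array(["a", "a", "b", "b"])
    scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.2, 0.8], [0.1, 0.9]])
    per_class, macro = roc_auc_ovr(y, scores)
    assert per_class["a"] == 1.0 and per_class["b"] == 1.0 and macro == 1.0
    _, macro_inv = roc_auc_ovr(y, scores[::-1])
    assert macro_inv == 0.0


def test_auc_tie_handling():
    # 8-point binary toy with one tied score across classes
    y = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=bool)
    s = np.array([0.9, 0.8, 0.5, 0.3, 0.5, 0.4, 0.2, 0.1])
    per_class, _ = roc_auc_ovr(y, np.column_stack([-s, s]))
    assert per_class[True] == pytest.approx(brute_auc(y, s))


# ---------------------------------------------------------------- random cross-checks


def test_ari_fmi_random_vs_oracle_and_sklearn(rng):
    for _ in range(30):
        n = int(rng.integers(5, 60))
        a = rng.integers(0, int(rng.integers(2, 6)), n)
        b = rng.integers(0, int(rng.integers(2, 6)), n)
        assert adjusted_rand_index(a, b) == pytest.approx(
            brute_ari(a.tolist(), b.tolist()), abs=1e-9
        )
        assert adjusted_rand_index(a, b) == pytest.approx(
            skm.adjusted_rand_score(a, b), abs=1e-9
        )
        assert fowlkes_mallows(a, b) == pytest.approx(
            skm.fowlkes_mallows_score(a, b), abs=1e-9
        )


def test_ari_fmi_symmetry_and_renaming(rng):
    a = rng.integers(0, 3, 40)
    b = rng.integers(0, 4, 40)
    remap = {v: 10 - v for v in range(4)}
    b2 = np.array([remap[v] for v in b])
    assert adjusted_rand_index(a, b) == pytest.approx(adjusted_rand_index(b, a))
    assert fowlkes_mallows(a, b) == pytest.approx(fowlkes_mallows(b, a))
    assert adjusted_rand_index(a, b2) == pytest.approx(adjusted_rand_index(a, b))
    assert fowlkes_mallows(a, b2) == pytest.approx(fowlkes_mallows(a, b))


def test_silhouette_random_vs_oracle_and_sklearn(rng):
    for _ in range(10):
        n = int(rng.integers(6, 40))
        X = rng.normal(size=(n, 3))
        labels = rng.integers(0, 3, n)
        if np.unique(labels).size < 2:
            continue
        ours = silhouette_score(X, labels)
        assert ours == pytest.approx(brute_silhouette(X.tolist(), labels.tolist()), abs=1e-9)
        if np.bincount(labels, minlength=3)[np.unique(labels)].min() > 1:
            assert ours == pytest.approx(skm.silhouette_score(X, labels), abs=1e-9)


def test_silhouette_separated_identical_points():
    X = np.array([[0.0, 0.0], [0.0, 0.0], [9.0, 9.0], [9.0, 9.0]])
    assert silhouette_score(X, [0, 0, 1, 1]) == 1.0


def test_silhouette_rejects_single_cluster():
    with pytest.raises(ValidationError):
        silhouette_score(np.eye(3), [0, 0, 0])


def test_auc_random_vs_oracle_and_sklearn(rng):
    for _ in range(20):
        n = int(rng.integers(10, 80))
        y = rng.integers(0, 3, n)
        if np.unique(y).size < 3:
            continue
        scores = np.round(rng.random((n, 3)), 1)  # rounding forces ties
        probs = scores / np.clip(scores.sum(1, keepdims=True), 1e-12, None)
        per_class, macro = roc_auc_ovr(y, probs)
        for c in np.unique(y):
            assert per_class[c] == pytest.approx(
                brute_auc((y == c).tolist(), probs[:, c].tolist()), abs=1e-9
            )
        assert macro == pytest.approx(
            skm.roc_auc_score(y, probs, multi_class="ovr", average="macro"),
            abs=1e-9,
        )
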