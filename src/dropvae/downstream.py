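"""Downstream analyses: embedding, graph clustering, classifier benchmark.

Cluster identification follows the standard four-stage recipe: the matrix
(already normalized/scaled or imputed) is reduced by PCA, a k-nearest-
neighbor graph is built in PC space, and Louvain modularity optimization
(igraph's multilevel algorithm) at a given resolution assigns cluster
labels. Quantitative clustering metrics (ARI/FMI against reference labels,
silhouette) are computed in PC space via the :mod:`dropvae.metrics` module —
the single source of truth for every reported number. t-SNE and UMAP are
offered for visualization only.

The classification benchmark trains up to seven classifiers (LR, SVM, RF,
NB, KNN, DT, GB) on a stratified 70/30 split, grid-searching a small
documented hyperparameter grid per algorithm by cross-validated accuracy on
the training portion, and reports held-out accuracy and macro one-vs-rest
AUC.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field

import igraph
import numpy as np
from sklearn.decomposition import PCA
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier, kneighbors_graph
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from . import metrics as _metrics
from .data_io import ExpressionMatrix, ValidationError

__all__ = [
    "ClusteringResult",
    "ClassificationReport",
    "embed",
    "cluster_cells",
    "clustering_metrics",
    "classify_benchmark",
    "compare_raw_vs_imputed",
    "CLASSIFIER_GRIDS",
]

_MODEL_LAYERS = ("scaled", "imputed")


@dataclass
class ClusteringResult:
    """Louvain cluster labels plus a 2-D embedding for visualization."""

    labels: np.ndarray
    embedding: np.ndarray  # n × 2
    pcs: np.ndarray        # n × n_pcs_used, the space metrics are computed in
    n_pcs_used: int
    resolution: float

    @property
    def n_clusters(self) -> int:
        return int(np.unique(self.labels).size)


@dataclass
class ClassificationReport:
    """Held-out accuracy / macro AUC per algorithm, with chosen grid points."""

    accuracy: dict
    auc: dict
    best_hyperparameters: dict
    split_fractions: tuple = (0.7, 0.3)

    def mean_accuracy(self) -> float:
        return float(np.mean(list(self.accuracy.values())))

    def mean_auc(self) -> float:
        return float(np.mean(list(self.auc.values())))


def _values(mat: ExpressionMatrix | np.ndarray) -> np.ndarray:
    if isinstance(mat, ExpressionMatrix):
        if mat.layer not in _MODEL_LAYERS:
            raise ValidationError(
                f"expected layer in {_MODEL_LAYERS}, got {mat.layer!r}"
            )
        return mat.values
    return np.asarray(mat, dtype=float)


def _fix_pc_signs(scores: np.ndarray, components: np.ndarray) -> np.ndarray:
    """Sign convention: the largest-|loading| entry of each PC is positive."""
    for j in range(components.shape[0]):
        i = np.argmax(np.abs(components[j]))
        if components[j, i] < 0:
            scores[:, j] *= -1
            components[j] *= -1
    return scores


def embed(
    mat: ExpressionMatrix | np.ndarray,
    method: str = "pca",
    n_components: int = 2,
    seed: int = 0,
) -> np.ndarray:
    """Low-dimensional embedding by PCA, t-SNE or UMAP.

    PCA is deterministic (component signs fixed by the
    largest-absolute-loading-positive convention); t-SNE/UMAP are seeded.
    """
    X = _values(mat)
    if n_components > min(X.shape):
        raise ValidationError(
            f"n_components={n_components} exceeds min(n_cells, n_genes)={min(X.shape)}"
        )
    if method == "pca":
        pca = PCA(n_components=n_components, svd_solver="full")
        scores = pca.fit_transform(X)
        return _fix_pc_signs(scores, pca.components_)
    if method == "tsne":
        from sklearn.manifold import TSNE

        return TSNE(
            n_components=n_components, random_state=seed, init="pca"
        ).fit_transform(X)
    if method == "umap":
        import umap

        return umap.UMAP(
            n_components=n_components, random_state=seed
        ).fit_transform(X)
    raise ValidationError(f"unknown embedding method {method!r}")


def cluster_cells(
    mat: ExpressionMatrix | np.ndarray,
    n_pcs: int = 30,
    n_neighbors: int = 15,
    resolution: float = 0.8,
    seed: int = 0,
) -> ClusteringResult:
    """PCA → kNN graph → Louvain modularity optimization.

    The kNN graph uses Euclidean distance in PC space and is symmetrized;
    Louvain runs at the given resolution with igraph's RNG seeded for
    reproducibility.
    """
    X = _values(mat)
    n = X.shape[0]
    if n_neighbors >= n:
        raise ValidationError(f"n_neighbors={n_neighbors} must be < n_cells={n}")
    n_pcs = min(n_pcs, min(X.shape))
    pcs = embed(X, "pca", n_components=n_pcs, seed=seed)
    adj = kneighbors_graph(pcs, n_neighbors=n_neighbors, mode="connectivity")
    adj = adj.maximum(adj.T).tocoo()
    edges = [(int(i), int(j)) for i, j in zip(adj.row, adj.col) if i < j]
    graph = igraph.Graph(n=n, edges=edges)
    igraph.set_random_number_generator(_random.Random(seed))
    part = graph.community_multilevel(resolution=resolution)
    igraph.set_random_number_generator(_random)
    labels = np.asarray(part.membership)
    return ClusteringResult(
        labels=labels,
        embedding=pcs[:, :2],
        pcs=pcs,
        n_pcs_used=n_pcs,
        resolution=resolution,
    )


def clustering_metrics(
    result: ClusteringResult, true_labels: np.ndarray | None = None
) -> dict:
    """ARI/FMI against reference labels and silhouette in PC space."""
    out: dict = {"n_clusters": result.n_clusters}
    if result.n_clusters >= 2:
        out["silhouette"] = _metrics.silhouette_score(result.pcs, result.labels)
    if true_labels is not None:
        out["ari"] = _metrics.adjusted_rand_index(true_labels, result.labels)
        out["fmi"] = _metrics.fowlkes_mallows(true_labels, result.labels)
    return out


#: Small documented hyperparameter grids, searched by 3-fold CV accuracy.
CLASSIFIER_GRIDS = {
    "LR": (
        lambda seed: LogisticRegression(max_iter=2000, random_state=seed),
        {"C": [0.01, 0.1, 1.0, 10.0]},
    ),
    "SVM": (
        lambda seed: SVC(decision_function_shape="ovr", random_state=seed),
        {"C": [0.1, 1.0, 10.0]},
    ),
    "RF": (
        lambda seed: RandomForestClassifier(random_state=seed),
        {"n_estimators": [100, 300]},
    ),
    "NB": (lambda seed: GaussianNB(), {"var_smoothing": [1e-9, 1e-7]}),
    "KNN": (lambda seed: KNeighborsClassifier(), {"n_neighbors": [3, 5, 11]}),
    "DT": (
        lambda seed: DecisionTreeClassifier(random_state=seed),
        {"max_depth": [None, 10]},
    ),
    "GB": (
        lambda seed: GradientBoostingClassifier(random_state=seed),
        {"n_estimators": [50, 100]},
    ),
}


def _scores_for_auc(clf, X) -> np.ndarray:
    if hasattr(clf, "predict_proba"):
        return clf.predict_proba(X)
    return clf.decision_function(X)


def classify_benchmark(
    mat: ExpressionMatrix | np.ndarray,
    labels,
    algorithms: tuple[str, ...] = ("LR", "SVM", "RF", "NB", "KNN", "DT", "GB"),
    seed: int = 0,
    cv: int = 3,
) -> ClassificationReport:
    """Grid-searched multi-classifier benchmark on a stratified 70/30 split."""
    X = _values(mat)
    y = np.asarray(labels)
    if X.shape[0] != y.size:
        raise ValidationError("one label per cell required")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValidationError("every class needs at least 2 members for a stratified split")
    unknown = set(algorithms) - set(CLASSIFIER_GRIDS)
    if unknown:
        raise ValidationError(f"unknown algorithms: {sorted(unknown)}")

    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=0.3, random_state=seed, stratify=y
    )
    acc: dict = {}
    auc: dict = {}
    best: dict = {}
    for name in algorithms:
        factory, grid = CLASSIFIER_GRIDS[name]
        search = GridSearchCV(factory(seed), grid, cv=cv, scoring="accuracy")
        search.fit(X_tr, y_tr)
        clf = search.best_estimator_
        pred = clf.predict(X_te)
        correct = int((pred == y_te).sum())
        # accuracy via the metrics module's confusion-count formula
        acc[name] = _metrics.accuracy(
            TP=correct, TN=0, FP=int((pred != y_te).sum()), FN=0
        )
        _, auc[name] = _metrics.roc_auc_ovr(y_te, _scores_for_auc(clf, X_te))
        best[name] = dict(search.best_params_)
    return ClassificationReport(accuracy=acc, auc=auc, best_hyperparameters=best)


def compare_raw_vs_imputed(
    raw: ExpressionMatrix | np.ndarray,
    imputed: ExpressionMatrix | np.ndarray,
    labels,
    seed: int = 0,
    n_pcs: int = 30,
    n_neighbors: int = 15,
    resolution: float = 0.8,
    algorithms: tuple[str, ...] = ("LR", "RF", "KNN"),
) -> dict:
    """Identical clustering + classification evaluation on both matrices.

    Returns ``{"raw": {...}, "imputed": {...}}`` with the same metric keys in
    both rows, so improvements attributable to imputation are read off
    directly.
    """
    labels = np.asarray(labels)
    report: dict = {}
    for name, mat in (("raw", raw), ("imputed", imputed)):
        res = cluster_cells(
            mat, n_pcs=n_pcs, n_neighbors=n_neighbors,
            resolution=resolution, seed=seed,
        )
        row = clustering_metrics(res, labels)
        cls = classify_benchmark(mat, labels, algorithms=algorithms, seed=seed)
        for alg in algorithms:
            row[f"accuracy_{alg}"] = cls.accuracy[alg]
            row[f"auc_{alg}"] = cls.auc[alg]
        row["mean_accuracy"] = cls.mean_accuracy()
        row["mean_auc"] = cls.mean_auc()
        report[name] = row
    return report
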