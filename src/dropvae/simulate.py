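"""Synthetic clustered scRNA-seq counts with ground truth.

The generator emulates the structure of droplet/plate scRNA-seq count
matrices: a shared log-normal baseline of gene means, k cell clusters each
shifting a fraction of genes up or down by a programmed log2 fold change,
log-normal per-cell library-size variation, negative-binomial counting
noise, and finally a dropout corruption step that zeroes nonzero entries —
either uniformly at random or preferentially at low expression. Because the
pre-dropout matrix, the dropout indicator and the cluster labels are all
returned, the corruption is exactly invertible for evaluation: every other
module can be scored against known truth.

Defaults describe the benchmark scenario used throughout the package:
600 cells × 300 genes, 4 clusters, 10% of genes differentially expressed
per cluster at a 2-fold change, negative-binomial dispersion 0.15,
library-size spread 0.35 on the log scale, and a 0.6 dropout rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .data_io import ExpressionMatrix, ValidationError

__all__ = ["SimConfig", "SimTruth", "simulate_counts", "apply_dropout", "recovery_report"]


@dataclass
class SimConfig:
    """Parameters of the count generator; see the module docstring."""

    n_cells: int = 600
    n_genes: int = 300
    n_clusters: int = 4
    de_fraction: float = 0.1
    log_fold_change: float = 1.0  # log2 units; 1.0 = 2-fold
    nb_dispersion: float = 0.15
    library_size_sigma: float = 0.35
    dropout_rate: float = 0.6
    dropout_mode: str = "random"
    baseline_log_mean: float = 0.5   # meanlog of the gene-mean log-normal
    baseline_log_sigma: float = 1.0  # sdlog of the gene-mean log-normal
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0 or self.n_genes <= 0 or self.n_clusters <= 0:
            raise ValidationError("n_cells, n_genes, n_clusters must be positive")
        if self.n_clusters > self.n_cells:
            raise ValidationError("n_clusters cannot exceed n_cells")
        if not 0 < self.de_fraction < 1:
            raise ValidationError("de_fraction must be in (0, 1)")
        if self.de_fraction * self.n_genes < 1:
            raise ValidationError("de_fraction * n_genes must be >= 1")
        if self.log_fold_change <= 0 or self.nb_dispersion <= 0:
            raise ValidationError("log_fold_change and nb_dispersion must be positive")
        if self.library_size_sigma < 0:
            raise ValidationError("library_size_sigma must be non-negative")
        if not 0 <= self.dropout_rate < 1:
            raise ValidationError("dropout_rate must be in [0, 1)")
        if self.dropout_mode not in ("random", "expression_dependent"):
            raise ValidationError(f"unknown dropout_mode {self.dropout_mode!r}")


@dataclass
class SimTruth:
    """Ground truth emitted by the simulator.

    ``corrupted == truth`` wherever ``dropout_mask`` is False; corrupted is 0
    (and truth > 0) wherever it is True. ``de_up``/``de_down`` list, per
    cluster, the gene indices shifted up/down, and ``baseline_means`` the
    shared pre-shift gene means — enough to verify programmed fold changes.
    """

    truth: np.ndarray
    corrupted: np.ndarray
    dropout_mask: np.ndarray
    labels: np.ndarray
    de_up: list = field(default_factory=list)
    de_down: list = field(default_factory=list)
    baseline_means: np.ndarray | None = None
    config: SimConfig | None = None

    def corrupted_matrix(self) -> ExpressionMatrix:
        """Corrupted counts as an ExpressionMatrix (the pipeline's input)."""
        n, g = self.corrupted.shape
        return ExpressionMatrix(
            self.corrupted,
            [f"cell{i}" for i in range(n)],
            [f"gene{j}" for j in range(g)],
            layer="raw",
        )

    def truth_matrix(self) -> ExpressionMatrix:
        n, g = self.truth.shape
        return ExpressionMatrix(
            self.truth,
            [f"cell{i}" for i in range(n)],
            [f"gene{j}" for j in range(g)],
            layer="raw",
        )


def apply_dropout(
    truth: np.ndarray, rate: float, mode: str = "random", seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Zero nonzero entries of a count matrix; returns (corrupted, mask).

    ``random`` zeroes each nonzero entry independently with probability
    ``rate``. ``expression_dependent`` zeroes entry x with probability
    proportional to exp(-lambda * log1p(x)), with lambda solved numerically
    so the expected zeroed fraction of nonzero entries equals ``rate`` —
    low-expression entries drop out preferentially, as in real data.
    Dropout never touches true zeros, so the mask cleanly separates false
    zeros from biological zeros.
    """
    truth = np.asarray(truth)
    if not 0 <= rate < 1:
        raise ValidationError("rate must be in [0, 1)")
    mask = np.zeros(truth.shape, dtype=bool)
    if rate == 0:
        return truth.copy(), mask
    rng = np.random.default_rng(seed)
    nonzero = truth > 0
    if mode == "random":
        p = np.full(int(nonzero.sum()), rate)
    elif mode == "expression_dependent":
        logx = np.log1p(truth[nonzero].astype(float))

        def mean_drop(lam: float) -> float:
            return float(np.mean(np.exp(-lam * logx)))

        # mean_drop(0) == 1 >= rate; decreasing in lam
        hi = 1.0
        while mean_drop(hi) > rate:
            hi *= 2.0
            if hi > 1e6:
                raise ValidationError("cannot calibrate expression-dependent dropout")
        lam = brentq(lambda L: mean_drop(L) - rate, 0.0, hi, xtol=1e-10)
        p = np.exp(-lam * logx)
    else:
        raise ValidationError(f"unknown dropout mode {mode!r}")
    drop = rng.random(p.size) < p
    mask[nonzero] = drop
    corrupted = truth.copy()
    corrupted[mask] = 0
    return corrupted, mask


def simulate_counts(config: SimConfig | None = None) -> SimTruth:
    """Draw a clustered negative-binomial count matrix and corrupt it.

    Cluster sizes are balanced (within 1). For each cluster, a disjoint-ish
    random subset of ``de_fraction * n_genes`` genes is shifted: half up by
    2**log_fold_change, half down by 2**-log_fold_change. Cell means are
    baseline * cluster shift * library factor, with the library factor
    log-normal and mean 1 so programmed fold changes survive averaging.
    Counts are NB with variance mu + dispersion * mu^2. Fully reproducible
    from ``config.seed``.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    n, g, k = config.n_cells, config.n_genes, config.n_clusters

    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sigma, g)
    labels = np.repeat(np.arange(k), -(-n // k))[:n]
    rng.shuffle(labels)

    n_de = max(1, round(config.de_fraction * g))
    shift = np.ones((k, g))
    de_up, de_down = [], []
    for c in range(k):
        genes = rng.choice(g, size=n_de, replace=False)
        up = genes[: n_de // 2 + n_de % 2]
        down = genes[n_de // 2 + n_de % 2 :]
        shift[c, up] = 2.0 ** config.log_fold_change
        shift[c, down] = 2.0 ** -config.log_fold_change
        de_up.append(np.sort(up))
        de_down.append(np.sort(down))

    sig = config.library_size_sigma
    lib = np.exp(rng.normal(-0.5 * sig**2, sig, n)) if sig > 0 else np.ones(n)
    mu = baseline[None, :] * shift[labels] * lib[:, None]

    r = 1.0 / config.nb_dispersion
    p = r / (r + mu)
    truth = rng.negative_binomial(r, p).astype(float)

    drop_seed = int(rng.integers(0, 2**31 - 1))
    corrupted, mask = apply_dropout(
        truth, config.dropout_rate, config.dropout_mode, drop_seed
    )
    return SimTruth(
        truth=truth,
        corrupted=corrupted,
        dropout_mask=mask,
        labels=labels,
        de_up=de_up,
        de_down=de_down,
        baseline_means=baseline,
        config=config,
    )


def recovery_report(
    truth: np.ndarray,
    corrupted: np.ndarray,
    imputed: np.ndarray,
    dropout_mask: np.ndarray,
) -> dict:
    """Correlation and RMSE against truth at the dropout positions.

    Scored for both the corrupted matrix (whose masked entries are all zero,
    so its correlation is undefined — reported as 0 with a flag) and the
    imputed matrix.
    """
    truth, corrupted, imputed, mask = (
        np.asarray(a) for a in (truth, corrupted, imputed, dropout_mask)
    )
    if not (truth.shape == corrupted.shape == imputed.shape == mask.shape):
        raise ValidationError("all matrices must share a shape")
    mask = mask.astype(bool)
    if not mask.any():
        raise ValidationError("dropout mask is empty; nothing to score")

    t = truth[mask].astype(float)
    report: dict = {"n_masked": int(mask.sum())}
    for name, vals in (("corrupted", corrupted[mask]), ("imputed", imputed[mask])):
        vals = vals.astype(float)
        report[f"rmse_{name}"] = float(np.sqrt(np.mean((vals - t) ** 2)))
        if np.std(vals) == 0 or np.std(t) == 0:
            report[f"pearson_{name}"] = 0.0
            report[f"pearson_{name}_degenerate"] = True
        else:
            report[f"pearson_{name}"] = float(np.corrcoef(vals, t)[0, 1])
            report[f"pearson_{name}_degenerate"] = False
    return report
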