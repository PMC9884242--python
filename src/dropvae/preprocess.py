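"""Matrix-level preprocessing chain for raw scRNA-seq counts.

The chain runs in a fixed order on a ``raw`` layer matrix:

1. ``filter_genes`` — drop genes detected in fewer than ``min_cells_per_gene``
   cells;
2. ``normalize_library_size`` — rescale each cell to the median library size,
   x_ij → (x_ij / T_i) · median(T);
3. ``log_transform`` — log2(1 + x) when the dynamic range exceeds
   ``log_threshold`` (default 100), otherwise a tagged no-op;
4. ``select_top_variance_genes`` — keep the highest-variance genes;
5. ``scale_genes`` — per-gene centering to mean 0 and unit population
   standard deviation.

Each operation checks the incoming layer tag, so running the chain out of
order raises. :class:`Preprocessor` drives the chain, records every
parameter it used (kept genes, cell totals, gene means/sds, whether the log
fired) and can map model-space values back to the count scale via
:meth:`Preprocessor.inverse_transform` — needed to export imputed counts and
to score recovery against simulated ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_io import ExpressionMatrix, ValidationError

__all__ = [
    "Mask",
    "PreprocessConfig",
    "filter_genes",
    "filter_outlier_cells",
    "normalize_library_size",
    "log_transform",
    "select_top_variance_genes",
    "scale_genes",
    "build_mask",
    "Preprocessor",
]


@dataclass
class Mask:
    """Boolean cells × genes matrix; True marks a valid observed entry."""

    flags: np.ndarray

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.flags.ndim != 2:
            raise ValidationError("mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.flags.shape


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    ``mask_zeros`` marks raw zeros as invalid in the training mask so the
    generative loss is fitted on observed (nonzero) entries only — zeros are
    the dropout candidates the model is later asked to fill in.
    """

    min_cells_per_gene: int = 3
    n_top_genes: int = 2000
    log_threshold: float = 100.0
    scale: bool = True
    mask_zeros: bool = True
    outlier_mads: float | None = None  # optional MAD cell filter, off by default

    def __post_init__(self) -> None:
        if self.min_cells_per_gene < 0:
            raise ValidationError("min_cells_per_gene must be >= 0")
        if self.n_top_genes <= 0:
            raise ValidationError("n_top_genes must be positive")
        if self.log_threshold <= 0:
            raise ValidationError("log_threshold must be positive")


def _require_layer(mat: ExpressionMatrix, layer: str, op: str) -> None:
    if mat.layer != layer:
        raise ValidationError(
            f"{op} expects a {layer!r} layer matrix, got {mat.layer!r}"
        )


def filter_genes(mat: ExpressionMatrix, min_cells_per_gene: int) -> ExpressionMatrix:
    """Keep genes with nonzero counts in at least ``min_cells_per_gene`` cells."""
    _require_layer(mat, "raw", "filter_genes")
    n_detected = (mat.values > 0).sum(axis=0)
    keep = n_detected >= min_cells_per_gene
    if not keep.any():
        raise ValidationError(
            f"no gene is detected in >= {min_cells_per_gene} cells; "
            "lower min_cells_per_gene"
        )
    return mat.copy(
        values=mat.values[:, keep],
        gene_ids=[g for g, k in zip(mat.gene_ids, keep) if k],
    )


def filter_outlier_cells(mat: ExpressionMatrix, n_mads: float = 5.0) -> ExpressionMatrix:
    """Drop cells whose total count is more than ``n_mads`` MADs from the median.

    Optional pre-filter (off by default in the pipeline): a crude guard
    against empty droplets and doublets based on library size only.
    """
    _require_layer(mat, "raw", "filter_outlier_cells")
    totals = mat.values.sum(axis=1)
    med = np.median(totals)
    mad = np.median(np.abs(totals - med))
    if mad == 0:
        return mat.copy()
    keep = np.abs(totals - med) <= n_mads * mad
    if not keep.any():
        raise ValidationError("outlier filter would remove every cell")
    return mat.copy(
        values=mat.values[keep],
        cell_ids=[c for c, k in zip(mat.cell_ids, keep) if k],
    )


def normalize_library_size(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale every cell to the median library size.

    x_ij → (x_ij / T_i) · median(T) with T_i the total count of cell i; after
    the operation every cell total equals the pre-operation median.
    """
    _require_layer(mat, "raw", "normalize_library_size")
    totals = mat.values.sum(axis=1)
    zero = totals == 0
    if zero.any():
        bad = [c for c, z in zip(mat.cell_ids, zero) if z]
        raise ValidationError(f"cells with zero total count: {bad[:5]}")
    median = float(np.median(totals))
    values = mat.values / totals[:, None] * median
    out = mat.copy(values=values, layer="normalized")
    out.meta["cell_totals"] = totals
    out.meta["median_total"] = median
    return out


def log_transform(mat: ExpressionMatrix, log_threshold: float = 100.0) -> ExpressionMatrix:
    """log2(1 + x) when the value range exceeds ``log_threshold``; tagged no-op otherwise."""
    _require_layer(mat, "normalized", "log_transform")
    if np.any(mat.values < 0):
        raise ValidationError("log_transform requires non-negative values")
    fired = bool(mat.values.size) and float(mat.values.max()) > log_threshold
    values = np.log2(1.0 + mat.values) if fired else mat.values.copy()
    out = mat.copy(values=values, layer="log")
    out.meta["log_fired"] = fired
    return out


def select_top_variance_genes(mat: ExpressionMatrix, n_top_genes: int) -> ExpressionMatrix:
    """Keep the ``n_top_genes`` genes with largest sample variance.

    Ties broken in favour of earlier genes; original gene order preserved.
    """
    if n_top_genes < 1:
        raise ValidationError("n_top_genes must be >= 1")
    if n_top_genes >= mat.n_genes:
        if n_top_genes > mat.n_genes:
            warnings.warn(
                f"n_top_genes={n_top_genes} exceeds gene count {mat.n_genes}; "
                "keeping all genes",
                stacklevel=2,
            )
        return mat.copy()
    var = mat.values.var(axis=0, ddof=1)
    # stable sort on -var keeps earlier genes first among ties
    order = np.argsort(-var, kind="stable")[:n_top_genes]
    keep = np.zeros(mat.n_genes, dtype=bool)
    keep[order] = True
    return mat.copy(
        values=mat.values[:, keep],
        gene_ids=[g for g, k in zip(mat.gene_ids, keep) if k],
    )


def scale_genes(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Center each gene to mean 0 and unit population standard deviation.

    Constant genes (sd = 0) are centered only.
    """
    _require_layer(mat, "log", "scale_genes")
    means = mat.values.mean(axis=0)
    sds = mat.values.std(axis=0)  # population (n) denominator
    safe = np.where(sds == 0, 1.0, sds)
    values = (mat.values - means) / safe
    out = mat.copy(values=values, layer="scaled")
    out.meta["gene_means"] = means
    out.meta["gene_sds"] = sds
    return out


def build_mask(mat: ExpressionMatrix, invalid_values: set | frozenset = frozenset()) -> Mask:
    """Mark entries False where non-finite or equal to a sentinel value."""
    flags = np.isfinite(mat.values)
    for sentinel in invalid_values:
        flags &= mat.values != sentinel
    return Mask(flags)


class Preprocessor:
    """Drives the fixed preprocessing chain and remembers how to undo it.

    Examples
    --------
    >>> prep = Preprocessor(PreprocessConfig(n_top_genes=100))
    >>> scaled, mask = prep.fit_transform(raw)      # doctest: +SKIP
    >>> counts = prep.inverse_transform(values)     # doctest: +SKIP
    """

    def __init__(self, config: PreprocessConfig | None = None):
        self.config = config or PreprocessConfig()
        self.fitted_: bool = False

    def fit_transform(self, raw: ExpressionMatrix) -> tuple[ExpressionMatrix, Mask]:
        """Run the chain on a raw matrix; returns the model-input layer and mask."""
        cfg = self.config
        _require_layer(raw, "raw", "Preprocessor.fit_transform")
        mat = raw
        if cfg.outlier_mads is not None:
            mat = filter_outlier_cells(mat, cfg.outlier_mads)
        mat = filter_genes(mat, cfg.min_cells_per_gene)
        self.cell_ids_ = list(mat.cell_ids)
        mat = normalize_library_size(mat)
        self.cell_totals_ = mat.meta["cell_totals"]
        self.median_total_ = mat.meta["median_total"]
        mat = log_transform(mat, cfg.log_threshold)
        self.log_fired_ = mat.meta["log_fired"]
        mat = select_top_variance_genes(mat, cfg.n_top_genes)
        self.gene_ids_ = list(mat.gene_ids)
        if cfg.scale:
            mat = scale_genes(mat)
            self.gene_means_ = mat.meta["gene_means"]
            self.gene_sds_ = mat.meta["gene_sds"]
        else:
            self.gene_means_ = np.zeros(mat.n_genes)
            self.gene_sds_ = np.ones(mat.n_genes)
        self.raw_subset_ = self.subset_like(raw)
        sentinels = {0} if cfg.mask_zeros else set()
        mask = build_mask(self.raw_subset_, sentinels)
        self.fitted_ = True
        self.matrix_ = mat
        return mat, mask

    def subset_like(self, raw: ExpressionMatrix) -> ExpressionMatrix:
        """Restrict a raw matrix to the cells/genes the fitted chain kept."""
        cidx = [raw.cell_ids.index(c) for c in self.cell_ids_]
        gidx = [raw.gene_ids.index(g) for g in self.gene_ids_]
        return raw.copy(
            values=raw.values[np.ix_(cidx, gidx)],
            cell_ids=list(self.cell_ids_),
            gene_ids=list(self.gene_ids_),
        )

    def inverse_transform(self, values: np.ndarray) -> np.ndarray:
        """Map model-space values back to the count scale.

        Un-scales, un-logs (if the log fired) and un-normalizes using the
        parameters recorded during :meth:`fit_transform`. Output is clipped
        at zero: counts cannot be negative.
        """
        if not self.fitted_:
            raise ValidationError("Preprocessor is not fitted")
        x = np.asarray(values, dtype=float)
        if self.config.scale:
            safe = np.where(self.gene_sds_ == 0, 1.0, self.gene_sds_)
            x = x * safe + self.gene_means_
        if self.log_fired_:
            x = np.exp2(x) - 1.0
        x = x / self.median_total_ * self.cell_totals_[:, None]
        return np.clip(x, 0.0, None)
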