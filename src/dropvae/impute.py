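"""Producing the imputed matrix from a trained model.

The default policy is conservative: only entries whose *raw* count is zero
(the dropout candidates) are replaced by the model reconstruction; observed
nonzero values pass through bit-exactly. ``full`` mode returns the complete
reconstruction instead, for comparison with methods that rewrite every
entry. The latent code is the deterministic posterior mean unless
``sample_latent`` is set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_io import ExpressionMatrix, ValidationError, save_matrix
from .vae import ModelParams, decode, encode, reparameterize

__all__ = ["ImputePolicy", "impute_matrix", "export_imputed"]


@dataclass
class ImputePolicy:
    """Which entries the reconstruction replaces.

    mode ``zeros_only`` — replace only where the raw count is 0; ``full`` —
    return the whole reconstruction. ``sample_latent`` draws b = mu + sigma*eps
    instead of using b = mu (off by default for reproducibility).
    """

    mode: str = "zeros_only"
    sample_latent: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("zeros_only", "full"):
            raise ValidationError(f"unknown impute mode {self.mode!r}")


def impute_matrix(
    mat: ExpressionMatrix,
    raw: ExpressionMatrix,
    model: ModelParams,
    policy: ImputePolicy | None = None,
) -> ExpressionMatrix:
    """Impute on the model-input layer; returns a matrix with layer ``imputed``.

    ``mat`` is the scaled matrix the model was trained on; ``raw`` the
    pre-scaling counts used to locate zeros. Both must share identifiers.
    """
    policy = policy or ImputePolicy()
    if mat.cell_ids != raw.cell_ids or mat.gene_ids != raw.gene_ids:
        raise ValidationError("mat and raw must share cell and gene identifiers")
    if mat.n_genes != model.n_genes:
        raise ValidationError(
            f"matrix has {mat.n_genes} genes, model expects {model.n_genes}"
        )
    mu, sigma = encode(mat.values, model)
    if policy.sample_latent:
        eps = np.random.default_rng(policy.seed).standard_normal(mu.shape)
        b = reparameterize(mu, sigma, eps)
    else:
        b = mu
    recon = decode(b, model)
    if policy.mode == "full":
        values = recon
    else:
        values = np.where(raw.values == 0, recon, mat.values)
    out = mat.copy(values=values, layer="imputed")
    out.meta["impute_mode"] = policy.mode
    return out


def export_imputed(mat: ExpressionMatrix, path, format: str = "csv") -> None:
    """Write the imputed matrix plus a JSON sidecar recording the layer tag."""
    save_matrix(mat, path, format=format)
    path = Path(path)
    meta_path = (path / "meta.json") if format == "mtx" else path.with_suffix(
        path.suffix + ".meta.json"
    )
    meta = {"layer": mat.layer, "n_cells": mat.n_cells, "n_genes": mat.n_genes}
    meta.update({k: v for k, v in mat.meta.items() if isinstance(v, (str, int, float))})
    meta_path.write_text(json.dumps(meta, indent=1) + "\n")
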