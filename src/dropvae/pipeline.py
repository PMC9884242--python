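"""End-to-end pipeline: preprocess → train → impute → evaluate.

A single global seed deterministically derives one sub-seed per stage via
``numpy.random.SeedSequence([global_seed, stage_index])`` (stage indices are
fixed and documented in ``STAGES``), so any stage can be re-run in isolation
and still match a full run. Every run writes its resolved configuration, a
manifest of artifacts, the per-epoch loss history and the metric reports
into the output directory.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .data_io import ExpressionMatrix, ValidationError, load_labels, load_matrix, save_matrix
from .downstream import classify_benchmark, cluster_cells, clustering_metrics
from .impute import ImputePolicy, export_imputed
from .preprocess import PreprocessConfig
from .vae import DropoutVAE

logger = logging.getLogger("dropvae")

__all__ = ["RunConfig", "stage_seed", "run_pipeline", "STAGES"]

#: Fixed stage indices used for per-stage seed derivation.
STAGES = {"simulate": 0, "preprocess": 1, "train": 2, "impute": 3, "evaluate": 4}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed, always below 2**31."""
    if stage not in STAGES:
        raise ValidationError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([int(global_seed), STAGES[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Composite configuration of a full pipeline run."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    learning_rate: float = 1e-3
    batch_size: int = 100
    n_epochs: int = 50
    beta: float = 1.0
    hidden_dims: tuple[int, ...] = (512, 128)
    latent_dim: int = 32
    impute_mode: str = "zeros_only"
    n_pcs: int = 30
    n_neighbors: int = 15
    resolution: float = 0.8
    algorithms: tuple[str, ...] = ("LR", "SVM", "RF", "NB", "KNN", "DT", "GB")
    seed: int = 0
    output_format: str = "csv"

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["preprocess"] = asdict(self.preprocess)
        d["hidden_dims"] = list(self.hidden_dims)
        d["algorithms"] = list(self.algorithms)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        prep = PreprocessConfig(**d.pop("preprocess", {}))
        if "hidden_dims" in d:
            d["hidden_dims"] = tuple(d["hidden_dims"])
        if "algorithms" in d:
            d["algorithms"] = tuple(d["algorithms"])
        return cls(preprocess=prep, **d)


def _write_tsv_report(path: Path, rows: dict) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        for key, val in rows.items():
            fh.write(f"{key}\t{val}\n")


def run_pipeline(
    config: RunConfig,
    input_path,
    output_dir,
    labels_path=None,
    evaluate: bool = True,
) -> dict:
    """Run the full chain on a raw count matrix file; returns the manifest."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"input": str(input_path), "artifacts": [], "stages": {}}

    def _stage(name):
        t0 = time.perf_counter()
        logger.info("stage %s: started", name)
        return t0

    def _done(name, t0):
        dt = time.perf_counter() - t0
        manifest["stages"][name] = round(dt, 3)
        logger.debug("stage %s: %.2fs", name, dt)

    raw = load_matrix(input_path)
    labels = (
        load_labels(labels_path, raw.cell_ids) if labels_path is not None else None
    )

    t0 = _stage("preprocess")
    model = DropoutVAE.from_counts(
        raw,
        preprocess_config=config.preprocess,
        hidden_dims=config.hidden_dims,
        latent_dim=config.latent_dim,
    )
    save_matrix(model.data, out / "preprocessed.csv", "csv")
    manifest["artifacts"].append("preprocessed.csv")
    _done("preprocess", t0)

    t0 = _stage("train")
    results = model.fit(
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        n_epochs=config.n_epochs,
        beta=config.beta,
        seed=stage_seed(config.seed, "train"),
    )
    np.savetxt(
        out / "loss_history.tsv",
        results.history,
        delimiter="\t",
        header="total\tgenerative\tbottleneck",
        comments="",
    )
    results.save(out / "model.npz")
    manifest["artifacts"] += ["loss_history.tsv", "model.npz"]
    for i, (tot, gen, bn) in enumerate(results.history, 1):
        logger.info("epoch %d/%d total=%.5f gen=%.5f kl=%.5f",
                    i, config.n_epochs, tot, gen, bn)
    _done("train", t0)

    t0 = _stage("impute")
    policy = ImputePolicy(mode=config.impute_mode)
    imputed = results.impute(policy)
    export_imputed(imputed, out / "imputed_scaled.csv", "csv")
    counts = results.imputed_counts(policy)
    save_matrix(counts, out / "imputed_counts.csv", "csv")
    manifest["artifacts"] += ["imputed_scaled.csv", "imputed_counts.csv"]
    _done("impute", t0)

    if evaluate:
        t0 = _stage("evaluate")
        eseed = stage_seed(config.seed, "evaluate")
        report: dict = {}
        for name, mat in (("raw", model.data), ("imputed", imputed)):
            res = cluster_cells(
                mat, n_pcs=config.n_pcs, n_neighbors=config.n_neighbors,
                resolution=config.resolution, seed=eseed,
            )
            for key, val in clustering_metrics(res, labels).items():
                report[f"{name}_{key}"] = val
            if labels is not None:
                cls = classify_benchmark(
                    mat, labels, algorithms=config.algorithms, seed=eseed
                )
                for alg in config.algorithms:
                    report[f"{name}_accuracy_{alg}"] = cls.accuracy[alg]
                    report[f"{name}_auc_{alg}"] = cls.auc[alg]
                report[f"{name}_mean_accuracy"] = cls.mean_accuracy()
        _write_tsv_report(out / "metrics.tsv", report)
        manifest["artifacts"].append("metrics.tsv")
        _done("evaluate", t0)

    config.to_yaml(out / "resolved_config.yaml")
    manifest["artifacts"].append("resolved_config.yaml")
    manifest["seed"] = config.seed
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest
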