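# Methods

## Problem

Single-cell RNA-seq count matrices are dominated by zeros. Some are
biological (the gene is simply not expressed in that cell); others are
*dropouts* — transcripts present in the cell that failed to be captured or
amplified, recorded as false zeros. Dropouts blur cluster structure and
degrade every downstream analysis. `dropvae` treats the zeros of a cell ×
gene count matrix as dropout candidates and fills them with values predicted
by a variational autoencoder (VAE) fitted to the observed entries.

## Model

Each preprocessed expression row x ∈ R^G (G genes, standardized per gene)
is mapped by a probabilistic encoder — a fully connected network with
rectifier hidden layers — to the mean μ(x) and log-variance of a diagonal
Gaussian over a latent code of dimension L. The code is sampled with the
reparameterization trick,

    b = μ + σ ⊙ ε,   ε ~ N(0, I),

so gradients flow through μ and σ despite the sampling, and decoded by a
mirrored network with a linear output layer into a reconstruction x̂.

Training minimizes the negative evidence lower bound, split into the two
components reported per epoch:

* **generative loss** — mean squared error between x and x̂, averaged over
  the entries a validity mask marks as observed. A Gaussian reconstruction
  likelihood on the standardized layer is used throughout; no
  negative-binomial or zero-inflated likelihood is attempted.
* **bottleneck loss** — the closed-form KL divergence
  ½ Σ_d (μ_d² + σ_d² − 1 − 2 ln σ_d) between the encoder's Gaussian and the
  standard-normal prior, averaged over the batch and weighted by a
  regularization coefficient β.

σ is a diagonal standard-deviation vector parameterized through the
log-variance for numerical stability; a full covariance is never formed.

**Masking.** The mask excludes entries from the generative loss. By default
the pipeline marks every raw zero invalid, so the model is fitted only to
observed (nonzero) expression; zeros are precisely the entries the model is
later asked to predict. Non-finite entries and user-supplied sentinel
values are always masked. A batch whose mask is entirely false is an error.

**Loss reduction.** Both components are means (per masked entry, per cell)
rather than sums. With mean reduction the KL term is strong relative to the
per-entry reconstruction term, and at the default β = 1 the bottleneck loss
converges close to zero while the reconstruction keeps improving: cell-
specific information passes through small-magnitude posterior means. The
reported per-epoch history makes this visible; lowering β trades prior
regularity for reconstruction fidelity.

## Optimization

Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) on shuffled mini-batches. Defaults:
learning rate 1e-3, batch size 100, 50 epochs, β = 1. The final partial
batch is used as-is; there is no early stopping or validation split. All
arithmetic is numpy, weight initialization is fan-in-scaled uniform from the
run seed, and mini-batch order and ε draws come from the same generator, so
a fixed seed reproduces training bitwise. Architecture defaults — hidden
layers (512, 128), latent dimension 32, rectifier activations, linear
μ/log-variance and output heads — are configurable; they were chosen as a
conventional funnel for matrices with a few hundred to a few thousand
retained genes.

## Preprocessing

Fixed order, enforced by layer tags on the matrix:

1. **Gene filtering** — "bad" genes are those detected (count > 0) in fewer
   than `min_cells_per_gene` cells (default 3, standard scRNA-seq practice).
2. **Library-size normalization** — x_ij → (x_ij / T_i) · median(T), where
   T_i is cell i's total count. Every cell total then equals the
   pre-operation median. Cells with zero total are an error.
3. **Log transform** — log2(1 + x) applied only when the maximum value
   exceeds `log_threshold` (default 100); the +1 pseudocount handles zeros.
   A flag records whether the transform fired.
4. **Highly-variable-gene selection** — keep the `n_top_genes` genes with
   the largest sample variance on the current (log) layer; ties resolved in
   favour of earlier columns; default 2000 (community default), a warning
   and no-op when fewer genes exist.
5. **Per-gene scaling** — center to mean 0 and divide by the population
   standard deviation; constant genes are centered only.

The `Preprocessor` records the kept gene set, per-cell totals, the median,
the log flag and the per-gene moments, so model-space output can be mapped
back to the count scale exactly (clipped at zero). An optional
median-absolute-deviation filter on library size (off by default, k = 5)
can exclude outlier cells before the chain.

## Imputation policy

Default `zeros_only`: the reconstruction (decoded from the posterior mean,
ε = 0) replaces only entries whose raw count is zero; observed nonzero
values pass through bit-exactly. `full` mode returns the complete
reconstruction for comparison with methods that rewrite every entry.
Observed entries are a fixed point of repeated imputation; the filled
entries are not exactly, because re-encoding a filled matrix changes the
reconstruction — a property of any nonlinear encoder, so strict idempotence
is not claimed.

## Downstream evaluation

Cluster identification: PCA (default 30 components, deterministic sign
convention), symmetrized k-nearest-neighbor graph in PC space (default
k = 15, Euclidean), Louvain modularity optimization (igraph's multilevel
algorithm) at resolution 0.8 — inside the commonly working 0.6–1.2 band;
raising resolution does not decrease the cluster count. ARI, FMI and the
silhouette coefficient are computed by this package's own metric
implementations; silhouette is evaluated in the PC space used for
clustering (a fixed, reproducible choice — 2-D visualization embeddings
such as t-SNE/UMAP are not used for any quantitative metric).

Classification: stratified 70/30 split, then per algorithm (LR, SVM, RF,
NB, KNN, DT, GB) a small grid search by 3-fold cross-validated accuracy on
the training portion — regularization strength over 3–4 decades for LR/SVM,
tree count {100, 300} for RF, k ∈ {3, 5, 11} for KNN, depth {None, 10} for
DT, {50, 100} boosting stages for GB, and var-smoothing {1e-9, 1e-7} for
NB. Held-out accuracy uses the confusion-count formula
(TP + TN)/(TP + TN + FP + FN); AUC is one-vs-rest with midrank tie
handling, macro-averaged (unweighted) over classes.

## Synthetic data

The simulator emulates the structure of real droplet/plate count matrices:
a log-normal baseline of gene means (meanlog 0.5, sdlog 1.0 — medians of a
few counts, a long right tail); k balanced clusters, each shifting a
`de_fraction` of genes half up, half down by 2^±`log_fold_change`;
log-normal library-size factors with mean exactly 1 (so programmed fold
changes survive averaging); negative-binomial counts with variance
μ + φμ² (dispersion φ); and a dropout step that zeroes nonzero entries —
uniformly, or with probability ∝ exp(−λ log(1+x)) with λ solved by root
finding so the expected zeroed fraction matches the requested rate
(low-expression entries drop out preferentially). Dropout touches only
nonzero truth, so the returned indicator cleanly separates false zeros
from biological zeros.

Defaults — 600 cells × 300 genes, 4 clusters, de_fraction 0.1,
log_fold_change 1 (2-fold), dispersion 0.15, library sigma 0.35, dropout
rate 0.6 — give a corrupted zero fraction around 0.7 and a problem size on
which the full pipeline (training included) runs in seconds on one CPU.
The generator does not model batch effects, trajectories, gene–gene
correlation beyond the cluster shifts, or ambient RNA; passing tests on it
demonstrates that the machinery recovers planted structure under NB noise
and dropout, not that it handles every pathology of real data.

## Numerical choices and edge cases

* ARI uses the contingency pair-counting identity; when the adjustment
  denominator is zero (both partitions trivial) the score is defined as 1.
* FMI returns 1 for partitions identical up to relabeling (including
  all-singletons vs all-singletons) before the zero-denominator rule, which
  otherwise yields 0 with a warning.
* Silhouette of a singleton-cluster point is 0; a single cluster overall is
  an error.
* Scaling uses the population (n) standard-deviation denominator; HVG
  selection uses the sample (n−1) variance. Both documented so tests are
  exact.
* Count-scale output of the inverse transform is clipped at zero.
* A run's global seed derives one sub-seed per stage via
  `SeedSequence([seed, stage_index])`, so stages rerun in isolation match a
  full run.

## Limitations

The Gaussian reconstruction on standardized data ignores the mean-variance
relationship of counts; heavily expressed genes dominate neither loss nor
imputation only because of per-gene scaling. The zeros-only policy cannot
revise observed values distorted by partial capture. No uncertainty is
attached to imputed values. Whether a zero is biological or technical is
not modelled explicitly (no mixture model); all zeros are candidates, and
the decoder's pooled reconstruction decides what they become.
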