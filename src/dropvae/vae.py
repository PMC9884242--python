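"""Variational autoencoder for dropout imputation of expression matrices.

The model maps each cell's (preprocessed, gene-scaled) expression row x
through a probabilistic encoder to a diagonal Gaussian over a low-dimensional
bottleneck code, samples the code with the reparameterization trick

    b = mu + sigma * eps,    eps ~ N(0, I),

and decodes b back to a reconstruction x_hat. Training minimizes the
negative evidence lower bound written as two components:

* generative loss — mean squared error between x and x_hat over the entries
  the mask marks valid (masked-out entries, e.g. suspected dropouts,
  contribute nothing);
* bottleneck loss — the closed-form KL divergence between the encoder's
  Gaussian and the standard-normal prior, weighted by ``kl_weight`` (beta).

Optimization is Adam over shuffled mini-batches. Everything is plain numpy,
so a fixed seed gives bitwise-reproducible training.

Two surfaces are offered: module-level functions (``encode``, ``decode``,
``reparameterize``, ``kl_divergence``, ``loss``, ``train``) operating on
:class:`ModelParams`, and the :class:`DropoutVAE` model class whose
:meth:`DropoutVAE.fit` returns a :class:`DropoutVAEResults` carrying the
fitted parameters, the per-epoch loss history and imputation helpers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .data_io import ExpressionMatrix, ValidationError
from .preprocess import Mask, PreprocessConfig, Preprocessor

__all__ = [
    "ModelParams",
    "TrainingConfig",
    "init_params",
    "encode",
    "reparameterize",
    "decode",
    "kl_divergence",
    "loss",
    "train",
    "DropoutVAE",
    "DropoutVAEResults",
]


@dataclass
class ModelParams:
    """Weights of the encoder (psi) and decoder (delta) networks.

    ``encoder`` / ``decoder`` are ordered lists of (W, b) pairs; hidden
    layers use a rectifier, the final layers are linear. The encoder's last
    layer emits ``2 * latent_dim`` values: the per-cell mean vector and the
    log-variance of the diagonal Gaussian.
    """

    encoder: list[tuple[np.ndarray, np.ndarray]]
    decoder: list[tuple[np.ndarray, np.ndarray]]
    hidden_dims: tuple[int, ...]
    latent_dim: int

    @property
    def n_genes(self) -> int:
        return self.encoder[0][0].shape[0]

    def flat(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for W, b in [*self.encoder, *self.decoder]:
            out.extend((W, b))
        return out


@dataclass
class TrainingConfig:
    """Optimization settings (optimizer is Adam, fixed)."""

    learning_rate: float = 1e-3
    batch_size: int = 100
    n_epochs: int = 50
    kl_weight: float = 1.0
    seed: int = 0
    hidden_dims: tuple[int, ...] = (512, 128)
    latent_dim: int = 32

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.n_epochs <= 0:
            raise ValidationError("learning_rate, batch_size, n_epochs must be positive")
        if self.kl_weight < 0:
            raise ValidationError("kl_weight must be non-negative")
        if self.latent_dim <= 0 or any(h <= 0 for h in self.hidden_dims):
            raise ValidationError("hidden_dims and latent_dim must be positive")


def _init_layer(fan_in: int, fan_out: int, rng: np.random.Generator):
    # fan-in-scaled uniform; biases start at zero
    limit = 1.0 / np.sqrt(fan_in)
    W = rng.uniform(-limit, limit, size=(fan_in, fan_out))
    b = np.zeros(fan_out)
    return W, b


def init_params(
    n_genes: int,
    hidden_dims: tuple[int, ...] = (512, 128),
    latent_dim: int = 32,
    rng: np.random.Generator | None = None,
) -> ModelParams:
    """Initialize encoder/decoder weights; the decoder mirrors the encoder."""
    rng = rng or np.random.default_rng()
    enc_sizes = [n_genes, *hidden_dims, 2 * latent_dim]
    dec_sizes = [latent_dim, *reversed(hidden_dims), n_genes]
    encoder = [
        _init_layer(a, b, rng) for a, b in zip(enc_sizes[:-1], enc_sizes[1:])
    ]
    decoder = [
        _init_layer(a, b, rng) for a, b in zip(dec_sizes[:-1], dec_sizes[1:])
    ]
    return ModelParams(encoder, decoder, tuple(hidden_dims), latent_dim)


def _mlp_forward(x: np.ndarray, layers) -> tuple[np.ndarray, list, list]:
    """Hidden layers with rectifier, final layer linear; returns caches."""
    acts = [x]
    zs = []
    for W, b in layers[:-1]:
        z = acts[-1] @ W + b
        zs.append(z)
        acts.append(np.maximum(z, 0.0))
    W, b = layers[-1]
    out = acts[-1] @ W + b
    return out, acts, zs


def _mlp_backward(layers, acts, zs, dout):
    """Gradients of all (W, b) plus the gradient w.r.t. the input."""
    grads = [None] * len(layers)
    W, _ = layers[-1]
    grads[-1] = (acts[-1].T @ dout, dout.sum(axis=0))
    da = dout @ W.T
    for i in range(len(layers) - 2, -1, -1):
        dz = da * (zs[i] > 0)
        W, _ = layers[i]
        grads[i] = (acts[i].T @ dz, dz.sum(axis=0))
        da = dz @ W.T
    return grads, da


def _as_rows(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return x[None, :], True
    return x, False


def encode(x: np.ndarray, params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """Map expression rows to the per-cell Gaussian (mu, sigma).

    sigma = exp(logvar / 2) is strictly positive; deterministic given params.
    """
    rows, squeeze = _as_rows(x)
    if rows.shape[1] != params.n_genes:
        raise ValidationError(
            f"input has {rows.shape[1]} genes, model expects {params.n_genes}"
        )
    stats, _, _ = _mlp_forward(rows, params.encoder)
    mu = stats[:, : params.latent_dim]
    logvar = stats[:, params.latent_dim:]
    sigma = np.exp(0.5 * logvar)
    if squeeze:
        return mu[0], sigma[0]
    return mu, sigma


def reparameterize(mu: np.ndarray, sigma: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """b = mu + sigma * eps, elementwise; randomness enters only through eps."""
    mu, sigma, eps = (np.asarray(a, dtype=float) for a in (mu, sigma, eps))
    if mu.shape != sigma.shape or mu.shape != eps.shape:
        raise ValidationError("mu, sigma, eps must share a shape")
    if np.any(sigma <= 0):
        raise ValidationError("sigma must be strictly positive")
    return mu + sigma * eps


def decode(b: np.ndarray, params: ModelParams) -> np.ndarray:
    """Map bottleneck codes back to expression rows (final layer linear)."""
    rows, squeeze = _as_rows(b)
    if rows.shape[1] != params.latent_dim:
        raise ValidationError(
            f"code has dim {rows.shape[1]}, model expects {params.latent_dim}"
        )
    out, _, _ = _mlp_forward(rows, params.decoder)
    return out[0] if squeeze else out


def kl_divergence(mu: np.ndarray, sigma: np.ndarray) -> np.ndarray | float:
    """KL( N(mu, diag sigma^2) || N(0, I) ), closed form.

    0.5 * sum_d (mu_d^2 + sigma_d^2 - 1 - 2 ln sigma_d); non-negative, zero
    iff mu = 0 and sigma = 1. Vector input gives a scalar; a 2-D array gives
    one value per row.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if mu.shape != sigma.shape:
        raise ValidationError("mu and sigma must share a shape")
    if np.any(sigma <= 0):
        raise ValidationError("sigma must be strictly positive")
    kl = 0.5 * np.sum(mu**2 + sigma**2 - 1.0 - 2.0 * np.log(sigma), axis=-1)
    return float(kl) if kl.ndim == 0 else kl


def loss(
    x: np.ndarray,
    x_hat: np.ndarray,
    mu: np.ndarray,
    sigma: np.ndarray,
    mask: np.ndarray,
    beta: float = 1.0,
) -> tuple[float, float, float]:
    """Composite objective: (total, generative, bottleneck).

    generative = mean over mask-true entries of (x - x_hat)^2;
    bottleneck = mean over rows of the KL divergence;
    total = generative + beta * bottleneck.
    """
    x, _ = _as_rows(x)
    x_hat, _ = _as_rows(x_hat)
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim == 1:
        mask = mask[None, :]
    if x.shape != x_hat.shape or x.shape != mask.shape:
        raise ValidationError("x, x_hat, mask must share a shape")
    n_valid = int(mask.sum())
    if n_valid == 0:
        raise ValidationError("mask is all-false: no valid entries to fit")
    gen = float(np.sum(((x - x_hat) ** 2) * mask) / n_valid)
    kl = kl_divergence(np.atleast_2d(mu), np.atleast_2d(sigma))
    bn = float(np.mean(kl))
    return gen + beta * bn, gen, bn


class _Adam:
    """Adam optimizer over a flat list of parameter arrays (in-place)."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


def _train_step(x, mask_rows, params, adam, beta, rng):
    """One forward/backward/update on a mini-batch; returns loss components."""
    B = x.shape[0]
    L = params.latent_dim
    n_valid = int(mask_rows.sum())
    if n_valid == 0:
        raise ValidationError("mask is all-false: no valid entries to fit")

    stats, e_acts, e_zs = _mlp_forward(x, params.encoder)
    mu = stats[:, :L]
    logvar = stats[:, L:]
    sigma = np.exp(0.5 * logvar)
    eps = rng.standard_normal((B, L))
    b = mu + sigma * eps
    x_hat, d_acts, d_zs = _mlp_forward(b, params.decoder)

    diff = (x_hat - x) * mask_rows
    gen = float(np.sum(diff**2) / n_valid)
    kl_rows = 0.5 * np.sum(mu**2 + np.exp(logvar) - 1.0 - logvar, axis=1)
    bn = float(np.mean(kl_rows))
    total = gen + beta * bn

    # generative term back through the decoder to the code b
    dxhat = 2.0 * diff / n_valid
    dec_grads, db = _mlp_backward(params.decoder, d_acts, d_zs, dxhat)
    # through the reparameterization into mu / logvar, plus the KL term
    dmu = db + beta * mu / B
    dlogvar = db * eps * 0.5 * sigma + beta * 0.5 * (np.exp(logvar) - 1.0) / B
    dstats = np.concatenate([dmu, dlogvar], axis=1)
    enc_grads, _ = _mlp_backward(params.encoder, e_acts, e_zs, dstats)

    flat_grads: list[np.ndarray] = []
    for gW, gb in [*enc_grads, *dec_grads]:
        flat_grads.extend((gW, gb))
    adam.step(flat_grads)
    return total, gen, bn


def train(
    mat: ExpressionMatrix | np.ndarray,
    mask: Mask | np.ndarray | None,
    config: TrainingConfig | None = None,
    params: ModelParams | None = None,
) -> tuple[ModelParams, np.ndarray]:
    """Fit the VAE with Adam over shuffled mini-batches.

    Returns the trained parameters and a history array of shape
    (n_epochs, 3) with per-epoch (total, generative, bottleneck) losses,
    each a cell-weighted mean over the epoch's batches. Fully reproducible
    given ``config.seed``.
    """
    config = config or TrainingConfig()
    if isinstance(mat, ExpressionMatrix):
        if mat.layer != "scaled":
            raise ValidationError(f"train expects a 'scaled' layer matrix, got {mat.layer!r}")
        x_all = mat.values
    else:
        x_all = np.asarray(mat, dtype=float)
    flags = np.ones_like(x_all, dtype=bool) if mask is None else (
        mask.flags if isinstance(mask, Mask) else np.asarray(mask, dtype=bool)
    )
    if flags.shape != x_all.shape:
        raise ValidationError("mask shape does not match matrix shape")

    n = x_all.shape[0]
    rng = np.random.default_rng(config.seed)
    if params is None:
        params = init_params(
            x_all.shape[1], config.hidden_dims, config.latent_dim, rng
        )
    adam = _Adam(params.flat(), config.learning_rate)

    history = np.zeros((config.n_epochs, 3))
    for epoch in range(config.n_epochs):
        order = rng.permutation(n)
        sums = np.zeros(3)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            comps = _train_step(
                x_all[idx], flags[idx], params, adam, config.kl_weight, rng
            )
            if not np.all(np.isfinite(comps)):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch + 1}, "
                    f"batch starting at {start}: {comps}"
                )
            sums += np.array(comps) * len(idx)
        history[epoch] = sums / n
    return params, history


class DropoutVAE:
    """VAE imputation model over a preprocessed expression matrix.

    Parameters
    ----------
    data
        A ``scaled``-layer :class:`ExpressionMatrix` (or a plain array of
        already-standardized values).
    mask
        Optional validity mask; entries marked False are excluded from the
        generative loss. Defaults to all-valid.
    hidden_dims, latent_dim
        Encoder architecture (the decoder mirrors it).

    Use :meth:`from_counts` to build the model directly from raw counts: it
    runs the preprocessing chain, keeps the fitted :class:`Preprocessor`
    so results can be mapped back to the count scale, and by default masks
    raw zeros out of the loss (they are the dropout candidates).
    """

    def __init__(
        self,
        data: ExpressionMatrix | np.ndarray,
        mask: Mask | np.ndarray | None = None,
        hidden_dims: tuple[int, ...] = (512, 128),
        latent_dim: int = 32,
    ):
        if isinstance(data, ExpressionMatrix):
            if data.layer != "scaled":
                raise ValidationError(
                    f"DropoutVAE expects a 'scaled' layer matrix, got {data.layer!r}"
                )
            self.data = data
        else:
            values = np.asarray(data, dtype=float)
            self.data = ExpressionMatrix(
                values,
                [f"cell{i}" for i in range(values.shape[0])],
                [f"gene{j}" for j in range(values.shape[1])],
                layer="scaled",
            )
        if mask is None:
            self.mask = Mask(np.ones(self.data.shape, dtype=bool))
        else:
            self.mask = mask if isinstance(mask, Mask) else Mask(np.asarray(mask))
        if self.mask.shape != self.data.shape:
            raise ValidationError("mask shape does not match data shape")
        self.hidden_dims = tuple(hidden_dims)
        self.latent_dim = int(latent_dim)
        self.preprocessor_: Preprocessor | None = None
        self.raw_: ExpressionMatrix | None = None

    @staticmethod
    def load_params(path) -> ModelParams:
        """Load a parameter archive written by :meth:`DropoutVAEResults.save`."""
        with np.load(path) as npz:
            header = json.loads(bytes(npz["__header__"]).decode())
            if header.get("format") != "dropvae-model":
                raise ValidationError(f"{path} is not a dropvae model archive")
            encoder = [
                (npz[f"encoder_{i}_W"], npz[f"encoder_{i}_b"])
                for i in range(header["n_encoder_layers"])
            ]
            decoder = [
                (npz[f"decoder_{i}_W"], npz[f"decoder_{i}_b"])
                for i in range(header["n_decoder_layers"])
            ]
        return ModelParams(
            encoder, decoder, tuple(header["hidden_dims"]), header["latent_dim"]
        )

    @classmethod
    def from_counts(
        cls,
        raw: ExpressionMatrix,
        preprocess_config: PreprocessConfig | None = None,
        hidden_dims: tuple[int, ...] = (512, 128),
        latent_dim: int = 32,
    ) -> "DropoutVAE":
        prep = Preprocessor(preprocess_config)
        scaled, mask = prep.fit_transform(raw)
        model = cls(scaled, mask, hidden_dims, latent_dim)
        model.preprocessor_ = prep
        model.raw_ = prep.raw_subset_
        return model

    def fit(
        self,
        learning_rate: float = 1e-3,
        batch_size: int = 100,
        n_epochs: int = 50,
        beta: float = 1.0,
        seed: int = 0,
    ) -> "DropoutVAEResults":
        """Train and return a results object with params and loss history."""
        config = TrainingConfig(
            learning_rate=learning_rate,
            batch_size=batch_size,
            n_epochs=n_epochs,
            kl_weight=beta,
            seed=seed,
            hidden_dims=self.hidden_dims,
            latent_dim=self.latent_dim,
        )
        params, history = train(self.data, self.mask, config)
        return DropoutVAEResults(self, params, history, config)


@dataclass
class DropoutVAEResults:
    """Fitted VAE: parameters, loss history and imputation helpers."""

    model: DropoutVAE
    params: ModelParams
    history: np.ndarray  # (n_epochs, 3): total, generative, bottleneck
    config: TrainingConfig
    _latent_cache: dict = field(default_factory=dict, repr=False)

    @property
    def loss_history(self) -> np.ndarray:
        return self.history

    def encode(self, x: np.ndarray | None = None):
        """Latent (mu, sigma) for rows of x (default: the training data)."""
        if x is None:
            x = self.model.data.values
        return encode(x, self.params)

    def reconstruct(self, x: np.ndarray | None = None) -> np.ndarray:
        """Deterministic reconstruction decode(mu) (noise eps = 0)."""
        mu, _ = self.encode(x)
        return decode(mu, self.params)

    def impute(self, policy=None) -> ExpressionMatrix:
        """Imputed matrix on the model-input (scaled) layer.

        Requires the model to know its raw counts (built via ``from_counts``
        or with ``model.raw_`` set) so the zeros-only policy can identify
        dropout candidates.
        """
        from .impute import ImputePolicy, impute_matrix

        if self.model.raw_ is None:
            raise ValidationError(
                "no raw counts attached; build the model with from_counts() "
                "or set model.raw_"
            )
        return impute_matrix(
            self.model.data, self.model.raw_, self.params, policy or ImputePolicy()
        )

    def imputed_counts(self, policy=None) -> ExpressionMatrix:
        """Imputed matrix mapped back to the count scale."""
        prep = self.model.preprocessor_
        if prep is None:
            raise ValidationError("count-scale output needs a fitted Preprocessor")
        imp = self.impute(policy)
        counts = prep.inverse_transform(imp.values)
        out = imp.copy(values=counts)
        out.meta["scale"] = "counts"
        return out

    def summary(self) -> str:
        """Plain-text fit summary."""
        first, last = self.history[0], self.history[-1]
        lines = [
            "Dropout VAE imputation — fit summary",
            "=" * 52,
            f"cells: {self.model.data.n_cells}    genes: {self.model.data.n_genes}",
            f"architecture: {list(self.config.hidden_dims)} -> {self.config.latent_dim}"
            f" -> {list(reversed(self.config.hidden_dims))}",
            f"optimizer: Adam  lr={self.config.learning_rate}  "
            f"batch={self.config.batch_size}  epochs={self.config.n_epochs}  "
            f"beta={self.config.kl_weight}  seed={self.config.seed}",
            f"mask: {int(self.model.mask.flags.sum())} valid "
            f"of {self.model.mask.flags.size} entries",
            "-" * 52,
            f"{'':12s}{'total':>12s}{'generative':>12s}{'bottleneck':>12s}",
            f"{'epoch 1':12s}{first[0]:12.5f}{first[1]:12.5f}{first[2]:12.5f}",
            f"{'epoch %d' % len(self.history):12s}"
            f"{last[0]:12.5f}{last[1]:12.5f}{last[2]:12.5f}",
            "=" * 52,
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        """Serialize parameters to a single .npz archive with a version header."""
        arrays = {}
        for side in ("encoder", "decoder"):
            for i, (W, b) in enumerate(getattr(self.params, side)):
                arrays[f"{side}_{i}_W"] = W
                arrays[f"{side}_{i}_b"] = b
        header = json.dumps(
            {
                "format": "dropvae-model",
                "version": 1,
                "hidden_dims": list(self.params.hidden_dims),
                "latent_dim": self.params.latent_dim,
                "n_encoder_layers": len(self.params.encoder),
                "n_decoder_layers": len(self.params.decoder),
            }
        )
        np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8),
                 **arrays)
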