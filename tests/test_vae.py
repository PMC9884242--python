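"""Encoder/decoder arithmetic, KL divergence, loss masking and training."""

import numpy as np
import pytest

from dropvae.data_io import ValidationError
from dropvae.vae import (
    DropoutVAE,
    ModelParams,
    TrainingConfig,
    decode,
    encode,
    init_params,
    kl_divergence,
    loss,
    reparameterize,
    train,
)


def zero_params(n_genes=2, hidden=(3,), latent=2):
    enc_sizes = [n_genes, *hidden, 2 * latent]
    dec_sizes = [latent, *reversed(hidden), n_genes]
    enc = [(np.zeros((a, b)), np.zeros(b)) for a, b in zip(enc_sizes, enc_sizes[1:])]
    dec = [(np.zeros((a, b)), np.zeros(b)) for a, b in zip(dec_sizes, dec_sizes[1:])]
    return ModelParams(enc, dec, tuple(hidden), latent)


# ------------------------------------------------------------- encode / decode


def test_encode_zero_params_gives_standard_gaussian():
    mu, sigma = encode(np.array([1.0, -2.0]), zero_params())
    np.testing.assert_array_equal(mu, [0.0, 0.0])
    np.testing.assert_array_equal(sigma, [1.0, 1.0])


def test_encode_deterministic_on_identical_rows(rng):
    params = init_params(5, (4,), 2, rng)
    x = np.tile(rng.normal(size=5), (3, 1))
    mu, sigma = encode(x, params)
    assert (mu == mu[0]).all() and (sigma == sigma[0]).all()


def test_encode_matches_hand_propagation():
    # one hidden layer of width 2 on a 2-gene toy; hand-set weights
    W1 = np.array([[1.0, -1.0], [0.5, 2.0]])
    b1 = np.array([0.1, -0.2])
    W2 = np.array([[1.0, 0.0, 2.0, 0.0], [0.0, 1.0, 0.0, -1.0]])
    b2 = np.zeros(4)
    params = ModelParams([(W1, b1), (W2, b2)], [], (2,), 2)
    x = np.array([1.0, 2.0])
    h = np.maximum(x @ W1 + b1, 0)  # [2.1, 3.0] before relu -> positive
    stats = h @ W2 + b2
    mu, sigma = encode(x, params)
    np.testing.assert_allclose(mu, stats[:2])
    np.testing.assert_allclose(sigma, np.exp(0.5 * stats[2:]))


def test_decode_zero_params_gives_zero_row():
    out = decode(np.array([1.0, 1.0]), zero_params())
    np.testing.assert_array_equal(out, [0.0, 0.0])


def test_decode_matches_hand_affine():
    W = np.array([[1.0, 2.0], [-1.0, 0.5]])
    b = np.array([0.5, -0.5])
    params = ModelParams([], [(W, b)], (), 2)
    out = decode(np.array([2.0, 4.0]), params)
    np.testing.assert_allclose(out, np.array([2.0, 4.0]) @ W + b)


def test_dimension_mismatch_rejected(rng):
    params = init_params(5, (4,), 2, rng)
    with pytest.raises(ValidationError):
        encode(np.zeros(4), params)
    with pytest.raises(ValidationError):
        decode(np.zeros(3), params)


# ------------------------------------------------------------- reparameterize


def test_reparameterize_arithmetic():
    assert reparameterize(np.array([0.5]), np.array([2.0]), np.array([1.0]))[0] == 2.5
    mu = np.array([1.0, -1.0])
    np.testing.assert_array_equal(reparameterize(mu, np.ones(2), np.zeros(2)), mu)


def test_reparameterize_rejects_nonpositive_sigma():
    with pytest.raises(ValidationError):
        reparameterize(np.zeros(2), np.array([1.0, 0.0]), np.zeros(2))


def test_reparameterize_moments(rng):
    eps = rng.standard_normal(100_000)
    b = reparameterize(np.full_like(eps, 1.0), np.full_like(eps, 2.0), eps)
    assert b.mean() == pytest.approx(1.0, abs=0.02)
    assert b.std() == pytest.approx(2.0, abs=0.02)


def test_reparameterize_affine_in_eps(rng):
    mu, sigma = rng.normal(size=4), np.abs(rng.normal(size=4)) + 0.1
    e1, e2 = rng.normal(size=4), rng.normal(size=4)
    lhs = reparameterize(mu, sigma, 0.3 * e1 + 0.7 * e2)
    rhs = 0.3 * reparameterize(mu, sigma, e1) + 0.7 * reparameterize(mu, sigma, e2)
    np.testing.assert_allclose(lhs, rhs + (1 - 0.3 - 0.7) * mu, atol=1e-12)


# ------------------------------------------------------------- KL divergence


def test_kl_standard_normal_is_zero():
    assert kl_divergence(np.zeros(6), np.ones(6)) == 0.0


def test_kl_unit_mean_shift():
    assert kl_divergence(np.array([1.0]), np.array([1.0])) == pytest.approx(0.5)


def test_kl_monte_carlo_agreement(rng):
    for _ in range(5):
        d = int(rng.integers(1, 9))
        mu = rng.normal(size=d)
        sigma = np.abs(rng.normal(size=d)) + 0.3
        z = mu + sigma * rng.standard_normal((200_000, d))
        log_q = -0.5 * np.sum(((z - mu) / sigma) ** 2 + np.log(2 * np.pi * sigma**2), axis=1)
        log_p = -0.5 * np.sum(z**2 + np.log(2 * np.pi), axis=1)
        samples = log_q - log_p
        se = samples.std(ddof=1) / np.sqrt(samples.size)
        assert kl_divergence(mu, sigma) == pytest.approx(samples.mean(), abs=3 * se)


def test_kl_rejects_nonpositive_sigma():
    with pytest.raises(ValidationError):
        kl_divergence(np.zeros(2), np.zeros(2))


# ------------------------------------------------------------- loss


def test_loss_perfect_reconstruction_is_zero():
    x = np.array([[1.0, 2.0]])
    total, gen, bn = loss(x, x, np.zeros((1, 2)), np.ones((1, 2)), np.ones((1, 2), bool))
    assert total == gen == bn == 0.0


def test_loss_beta_zero_is_masked_mse(rng):
    x, xh = rng.normal(size=(3, 4)), rng.normal(size=(3, 4))
    mask = rng.random((3, 4)) > 0.4
    total, gen, _ = loss(x, xh, rng.normal(size=(3, 2)), np.ones((3, 2)), mask, beta=0.0)
    assert total == gen == pytest.approx(((x - xh) ** 2)[mask].mean())


def test_loss_masked_entries_excluded():
    x = np.array([[1.0, 2.0]])
    xh = np.array([[1.0, 0.0]])
    mask = np.array([[True, False]])
    total, gen, bn = loss(x, xh, np.zeros((1, 1)), np.ones((1, 1)), mask, beta=1.0)
    assert gen == 0.0 and total == 0.0


def test_loss_all_false_mask_rejected():
    with pytest.raises(ValidationError):
        loss(np.ones((1, 2)), np.ones((1, 2)), np.zeros((1, 1)), np.ones((1, 1)),
             np.zeros((1, 2), bool))


def test_loss_invariant_to_cell_permutation(rng):
    x, xh = rng.normal(size=(6, 5)), rng.normal(size=(6, 5))
    mu, sigma = rng.normal(size=(6, 3)), np.abs(rng.normal(size=(6, 3))) + 0.1
    mask = rng.random((6, 5)) > 0.3
    perm = rng.permutation(6)
    a = loss(x, xh, mu, sigma, mask)
    b = loss(x[perm], xh[perm], mu[perm], sigma[perm], mask[perm])
    np.testing.assert_allclose(a, b)


# ------------------------------------------------------------- training


def test_train_same_seed_bitwise_identical(rng):
    x = rng.normal(size=(40, 12))
    cfg = TrainingConfig(n_epochs=3, batch_size=16, hidden_dims=(8,), latent_dim=3, seed=7)
    _, h1 = train(x, None, cfg)
    _, h2 = train(x, None, cfg)
    assert (h1 == h2).all()


def test_train_degenerate_fixed_point():
    # beta=0, one cell with value 0, zero-init params: loss 0 at epoch 1
    x = np.zeros((1, 1))
    params = zero_params(n_genes=1, hidden=(2,), latent=1)
    cfg = TrainingConfig(n_epochs=1, batch_size=1, kl_weight=0.0,
                         hidden_dims=(2,), latent_dim=1)
    _, hist = train(x, None, cfg, params=params)
    assert hist[0, 0] == 0.0


def test_train_autoencodes_noiseless_matrix(rng):
    # beta=0 and latent >= rank: reconstruction error collapses
    x = rng.normal(size=(10, 5))
    x = (x - x.mean(0)) / x.std(0)
    cfg = TrainingConfig(learning_rate=0.01, batch_size=10, n_epochs=500,
                         kl_weight=0.0, hidden_dims=(32,), latent_dim=5, seed=3)
    _, hist = train(x, None, cfg)
    assert hist[-1, 0] < 0.1 * hist[0, 0]


def test_fit_loss_decreases_on_benchmark(bench_fit):
    _, results = bench_fit
    assert results.history.shape == (50, 3)
    assert results.history[-1, 0] < results.history[0, 0]


def test_results_summary_mentions_architecture(bench_fit):
    _, results = bench_fit
    text = results.summary()
    assert "epoch 50" in text and "Adam" in text


def test_model_save_load_round_trip(tmp_path, bench_fit):
    _, results = bench_fit
    results.save(tmp_path / "model.npz")
    params = DropoutVAE.load_params(tmp_path / "model.npz")
    x = results.model.data.values[:5]
    np.testing.assert_array_equal(results.reconstruct(x),
                                  decode(encode(x, params)[0], params))


def test_train_rejects_wrong_layer(bench_sim):
    with pytest.raises(ValidationError):
        train(bench_sim.corrupted_matrix(), None, TrainingConfig(n_epochs=1))
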