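"""Tests for the conditional VAE: loss closed forms, encode/decode
contracts, training dynamics, and generation."""

import numpy as np
import pytest

from sigdesign.chemio import SmilesRecord, build_vocabulary, one_hot_encode
from sigdesign.cvae import (
    CvaeConfig,
    build_cvae,
    cvae_loss,
    decode,
    decode_batch,
    decoder_probabilities,
    encode,
    gaussian_kl,
    sample_designs,
    train_cvae,
)

CORPUS = [
    SmilesRecord("a", "CCO"),
    SmilesRecord("b", "CC=O"),
    SmilesRecord("c", "CCN"),
    SmilesRecord("d", "CCCO"),
    SmilesRecord("e", "OCCO"),
    SmilesRecord("f", "CC(C)O"),
]


def tiny_model(seq_len=10, latent=4, cond=3, hidden=16, seed=0, **kw):
    cfg = CvaeConfig(
        seq_len=seq_len,
        latent_dim=latent,
        condition_dim=cond,
        hidden_width=hidden,
        batch_size=4,
        seed=seed,
        **kw,
    )
    vocab = build_vocabulary(CORPUS, seq_len)
    return build_cvae(cfg, vocab), vocab, cfg


def corpus_with_conditions(cond_dim=3, seed=0):
    rng = np.random.default_rng(seed)
    return [(rec, rng.standard_normal(cond_dim)) for rec in CORPUS]


class TestGaussianKl:
    def test_prior_to_itself_is_zero(self):
        assert gaussian_kl(np.zeros((1, 5)), np.ones((1, 5)))[0] == 0.0

    def test_unit_mean_shift_is_half(self):
        mean = np.array([[1.0, 0.0, 0.0]])
        assert gaussian_kl(mean, np.ones((1, 3)))[0] == pytest.approx(0.5)

    def test_matches_closed_form_on_random_inputs(self):
        rng = np.random.default_rng(3)
        mu = rng.standard_normal((8, 6))
        sigma = np.exp(rng.standard_normal((8, 6)) * 0.3)
        expected = 0.5 * np.sum(mu**2 + sigma**2 - 1 - np.log(sigma**2), axis=1)
        assert np.allclose(gaussian_kl(mu, sigma), expected, atol=1e-8)

    def test_matches_monte_carlo_estimate(self):
        # KL(q||p) = E_q[log q(z) - log p(z)] by simulation at 1e5 draws
        rng = np.random.default_rng(4)
        mu, sigma = np.array([0.7, -0.3]), np.array([1.4, 0.6])
        z = mu + sigma * rng.standard_normal((100_000, 2))
        log_q = -0.5 * ((z - mu) / sigma) ** 2 - np.log(sigma) - 0.5 * np.log(2 * np.pi)
        log_p = -0.5 * z**2 - 0.5 * np.log(2 * np.pi)
        mc = np.mean(np.sum(log_q - log_p, axis=1))
        exact = gaussian_kl(mu[None], sigma[None])[0]
        assert exact == pytest.approx(mc, abs=0.02)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_kl(np.zeros((1, 2)), np.array([[1.0, 0.0]]))


class TestCvaeLoss:
    def test_perfect_prediction_at_prior_is_zero(self):
        model, vocab, cfg = tiny_model()
        X = one_hot_encode("CCO", vocab, cfg.seq_len)[None]
        loss = cvae_loss(X, X.copy(), np.zeros((1, 4)), np.ones((1, 4)))
        assert loss == pytest.approx(0.0)

    def test_kl_weight_scales_kl_term(self):
        model, vocab, cfg = tiny_model()
        X = one_hot_encode("CCO", vocab, cfg.seq_len)[None]
        mean, sigma = np.full((1, 4), 0.5), np.ones((1, 4))
        kl = gaussian_kl(mean, sigma)[0]
        l1 = cvae_loss(X, X.copy(), mean, sigma, kl_weight=1.0)
        l2 = cvae_loss(X, X.copy(), mean, sigma, kl_weight=2.0)
        assert l2 - l1 == pytest.approx(kl)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            cvae_loss(
                np.zeros((1, 3, 4)), np.zeros((1, 3, 5)), np.zeros((1, 2)), np.ones((1, 2))
            )


class TestEncodeDecode:
    def test_encode_deterministic_given_seed(self):
        model, vocab, cfg = tiny_model()
        X = one_hot_encode("CCO", vocab, cfg.seq_len)
        c = np.array([0.1, -0.2, 0.5])
        m1, s1, z1 = encode(model, X, c, seed=42)
        m2, s2, z2 = encode(model, X, c, seed=42)
        assert np.array_equal(z1, z2)
        assert np.array_equal(m1, m2)
        assert np.all(s1 > 0) and np.all(np.isfinite(m1))

    def test_sigma_zero_limit_gives_mean(self):
        # as sigma -> 0, z -> mean; emulate by shrinking the log-sigma head
        model, vocab, cfg = tiny_model()
        model.log_sigma_head.W.data[:] = 0.0
        model.log_sigma_head.b.data[:] = -30.0  # sigma = e^-30
        X = one_hot_encode("CCO", vocab, cfg.seq_len)
        m, s, z = encode(model, X, np.zeros(3), seed=0)
        assert np.allclose(z, m, atol=1e-10)

    def test_decode_deterministic_and_bounded(self):
        model, vocab, cfg = tiny_model()
        z, c = np.ones(4), np.zeros(3)
        s1, s2 = decode(model, z, c), decode(model, z, c)
        assert s1 == s2
        assert len(s1) <= cfg.seq_len

    def test_decoder_rows_are_probability_vectors(self):
        model, _, _ = tiny_model()
        probs = decoder_probabilities(
            model, np.random.default_rng(0).standard_normal((5, 4)), np.zeros(3)
        )
        assert probs.shape[2] == len(model.vocab)
        assert np.allclose(probs.sum(axis=2), 1.0, atol=1e-6)
        assert np.all(probs >= 0)

    def test_dimension_contracts(self):
        model, vocab, cfg = tiny_model()
        with pytest.raises(ValueError):
            decode(model, np.zeros(9), np.zeros(3))
        with pytest.raises(ValueError):
            decode(model, np.zeros(4), np.zeros(9))
        with pytest.raises(ValueError):
            encode(model, np.zeros((3, len(vocab))), np.zeros(3))


class TestTraining:
    def test_loss_improves(self):
        model, _, _ = tiny_model(epochs_max=20, seed=1)
        train_cvae(model, corpus_with_conditions())
        log = model.training_log
        assert log[-1]["loss"] < log[0]["loss"]
        assert model.trained

    def test_same_seed_identical_loss_curves(self):
        m1, _, _ = tiny_model(epochs_max=6, seed=2)
        m2, _, _ = tiny_model(epochs_max=6, seed=2)
        train_cvae(m1, corpus_with_conditions())
        train_cvae(m2, corpus_with_conditions())
        assert m1.training_log == m2.training_log

    def test_empty_corpus_rejected(self):
        model, _, _ = tiny_model()
        with pytest.raises(ValueError):
            train_cvae(model, [])

    def test_unencodable_record_named(self):
        model, _, _ = tiny_model()
        bad = [(SmilesRecord("bad_one", "CBr"), np.zeros(3))]
        with pytest.raises(ValueError, match="bad_one"):
            train_cvae(model, bad)

    def test_condition_length_checked(self):
        model, _, _ = tiny_model()
        with pytest.raises(ValueError, match="condition length"):
            train_cvae(model, [(CORPUS[0], np.zeros(7))])

    def test_overfit_single_molecule_reproduces_it_from_prior(self):
        cfg = CvaeConfig(
            seq_len=6,
            latent_dim=2,
            condition_dim=2,
            hidden_width=24,
            batch_size=4,
            epochs_max=150,
            learning_rate=1e-2,
            seed=3,
        )
        corpus = [SmilesRecord("only", "CCO")]
        vocab = build_vocabulary(corpus, cfg.seq_len)
        model = build_cvae(cfg, vocab)
        cond = np.array([0.5, -0.5])
        train_cvae(model, [(corpus[0], cond)] * 8)
        draws = sample_designs(model, cond, 50, seed=9)
        assert sum(s == "CCO" for s in draws) >= 45


class TestSampling:
    def test_zero_draws(self):
        model, _, _ = tiny_model()
        assert sample_designs(model, np.zeros(3), 0) == []

    def test_negative_rejected(self):
        model, _, _ = tiny_model()
        with pytest.raises(ValueError):
            sample_designs(model, np.zeros(3), -1)

    def test_count_and_reproducibility(self):
        model, _, _ = tiny_model(seed=5)
        a = sample_designs(model, np.zeros(3), 100, seed=11)
        b = sample_designs(model, np.zeros(3), 100, seed=11)
        assert len(a) == 100
        assert a == b

    def test_checkpoint_round_trip(self, tmp_path):
        from sigdesign.cvae import CvaeModel

        model, _, _ = tiny_model(epochs_max=4, seed=8)
        train_cvae(model, corpus_with_conditions())
        model.save(tmp_path / "ckpt")
        loaded = CvaeModel.load(tmp_path / "ckpt")
        assert loaded.trained
        assert sample_designs(loaded, np.zeros(3), 20, seed=4) == sample_designs(
            model, np.zeros(3), 20, seed=4
        )

    def test_batch_decode_matches_single(self):
        model, _, _ = tiny_model(seed=6)
        rng = np.random.default_rng(0)
        z = rng.standard_normal((4, 4))
        c = np.array([0.3, 0.1, -0.4])
        batch = decode_batch(model, z, c)
        singles = [decode(model, z[i], c) for i in range(4)]
        assert batch == singles
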