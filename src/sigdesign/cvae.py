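"""Conditional variational autoencoder over one-hot SMILES.

Architecture
------------
The encoder consumes a one-hot SMILES matrix with the condition vector
(the reduced interaction signature) appended to every sequence position,
runs it through a stack of LSTM cells, and maps the final hidden state to
parallel mean and standard-deviation heads of the latent code z. The
decoder is an autoregressive LSTM stack: at every time step it receives
the previous token's one-hot vector with [z, c] re-appended (teacher
forcing at train time, greedy feedback at generation time) and emits
per-position token probabilities; argmax per position yields the output
SMILES.

The training objective is the conditional ELBO: per-token cross-entropy
reconstruction error plus kl_weight times the closed-form KL divergence of
the diagonal Gaussian posterior N(mean, sigma^2) from the standard normal
prior, averaged over the batch. kl_weight warms up linearly over the first
fraction of epochs (a common stabilization for small corpora) and is 1 at
its plateau by default.

At generation time, z is sampled from the prior and the condition is the
reduced signature of the objective compound.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chemio import SmilesRecord, SmilesVocabulary, one_hot_decode, one_hot_encode
from .nn import (
    Adam,
    Dense,
    LSTMStack,
    Tensor,
    concat,
    softmax,
    softmax_cross_entropy,
)


@dataclass
class CvaeConfig:
    seq_len: int = 40
    latent_dim: int = 16
    condition_dim: int = 16
    n_recurrent_cells: int = 1
    hidden_width: int = 64
    epochs_max: int = 30
    batch_size: int = 64
    learning_rate: float = 3e-3
    kl_weight: float = 1.0
    kl_warmup_fraction: float = 0.1
    patience: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "seq_len",
            "latent_dim",
            "condition_dim",
            "n_recurrent_cells",
            "hidden_width",
            "batch_size",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.kl_weight < 0:
            raise ValueError("kl_weight must be nonnegative")

    @classmethod
    def paper2021(cls, **kw) -> "CvaeConfig":
        """Full-scale preset: 200-dim latent and condition, 3 LSTM cells."""
        kw.setdefault("seq_len", 120)
        kw.setdefault("latent_dim", 200)
        kw.setdefault("condition_dim", 200)
        kw.setdefault("n_recurrent_cells", 3)
        kw.setdefault("hidden_width", 256)
        return cls(**kw)

    @classmethod
    def desk(cls, **kw) -> "CvaeConfig":
        return cls(**kw)


@dataclass
class CvaeModel:
    config: CvaeConfig
    vocab: SmilesVocabulary
    encoder_rnn: LSTMStack = field(repr=False)
    mean_head: Dense = field(repr=False)
    log_sigma_head: Dense = field(repr=False)
    decoder_rnn: LSTMStack = field(repr=False)
    token_head: Dense = field(repr=False)
    training_log: list[dict] = field(default_factory=list)
    trained: bool = False
    # condition standardization recorded at train time, identity before
    cond_mean: np.ndarray | None = None
    cond_std: np.ndarray | None = None

    def parameters(self):
        return (
            self.encoder_rnn.parameters()
            + self.mean_head.parameters()
            + self.log_sigma_head.parameters()
            + self.decoder_rnn.parameters()
            + self.token_head.parameters()
        )

    def _norm_condition(self, c: np.ndarray) -> np.ndarray:
        c = np.atleast_2d(np.asarray(c, dtype=np.float64))
        if c.shape[1] != self.config.condition_dim:
            raise ValueError(
                f"condition length {c.shape[1]} != condition_dim "
                f"{self.config.condition_dim}"
            )
        if self.cond_mean is None:
            return c
        return (c - self.cond_mean) / self.cond_std

    def save(self, checkpoint_dir) -> None:
        """Write a checkpoint: manifest JSON (config, vocab, training log,
        condition statistics) + parameter blob."""
        out = Path(checkpoint_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "manifest.json").write_text(
            json.dumps(
                {
                    "config": vars(self.config),
                    "vocab": {"tokens": list(self.vocab.tokens), "seq_len": self.vocab.seq_len},
                    "trained": self.trained,
                    "training_log": self.training_log,
                    "cond_mean": None if self.cond_mean is None else self.cond_mean.tolist(),
                    "cond_std": None if self.cond_std is None else self.cond_std.tolist(),
                },
                indent=2,
            )
        )
        np.savez(
            out / "parameters.npz",
            **{f"p{i}": p.data for i, p in enumerate(self.parameters())},
        )

    @classmethod
    def load(cls, checkpoint_dir) -> "CvaeModel":
        out = Path(checkpoint_dir)
        manifest = json.loads((out / "manifest.json").read_text())
        vocab = SmilesVocabulary(
            tokens=tuple(manifest["vocab"]["tokens"]),
            seq_len=int(manifest["vocab"]["seq_len"]),
        )
        model = build_cvae(CvaeConfig(**manifest["config"]), vocab)
        blob = np.load(out / "parameters.npz")
        for i, p in enumerate(model.parameters()):
            p.data = blob[f"p{i}"]
        model.trained = manifest["trained"]
        model.training_log = manifest["training_log"]
        if manifest["cond_mean"] is not None:
            model.cond_mean = np.asarray(manifest["cond_mean"])
            model.cond_std = np.asarray(manifest["cond_std"])
        return model

    def _encode_batch(self, X: np.ndarray, c_norm: np.ndarray) -> tuple[Tensor, Tensor]:
        """X: (B x T x V) one-hot; c_norm: (B x C) standardized condition."""
        B, T, _ = X.shape
        xs = [
            Tensor(np.concatenate([X[:, t, :], c_norm], axis=1)) for t in range(T)
        ]
        hidden = self.encoder_rnn.run(xs, batch=B)[-1]
        mean = self.mean_head(hidden)
        log_sigma = self.log_sigma_head(hidden)
        return mean, log_sigma

    def _decode_teacher_t(
        self, z: Tensor, c_norm: np.ndarray, X: np.ndarray
    ) -> list[Tensor]:
        """Teacher-forced per-step token logits (training path).

        Step t's input is the ground-truth token at t-1 (the pad token at
        t=0 acts as the start symbol) with [z, c] re-appended; z stays in
        the autodiff graph.
        """
        B, T, V = X.shape
        c_t = Tensor(c_norm)
        start = np.zeros((B, V))
        start[:, self.vocab.pad_index] = 1.0
        states = self.decoder_rnn.init_states(B)
        logits: list[Tensor] = []
        for t in range(T):
            prev = start if t == 0 else X[:, t - 1, :]
            step_in = concat([Tensor(prev), z, c_t])
            h, states = self.decoder_rnn.step(step_in, states)
            logits.append(self.token_head(h))
        return logits

    def _decode_greedy(self, z: np.ndarray, c_norm: np.ndarray) -> np.ndarray:
        """Greedy autoregressive decoding (inference path, no gradients).

        Returns the (B x T x V) stack of per-position probability rows;
        the argmax token is fed back as the next step's input.
        """
        B, T, V = z.shape[0], self.config.seq_len, len(self.vocab)
        states = [
            (np.zeros((B, self.decoder_rnn.n_hidden)), np.zeros((B, self.decoder_rnn.n_hidden)))
            for _ in self.decoder_rnn.cells
        ]
        prev = np.zeros((B, V))
        prev[:, self.vocab.pad_index] = 1.0
        probs = np.zeros((B, T, V))
        for t in range(T):
            step_in = np.concatenate([prev, z, c_norm], axis=1)
            h, states = self.decoder_rnn.step_numpy(step_in, states)
            logits = h @ self.token_head.W.data + self.token_head.b.data
            p = softmax(logits)
            probs[:, t, :] = p
            prev = np.zeros((B, V))
            prev[np.arange(B), p.argmax(axis=1)] = 1.0
        return probs


def build_cvae(config: CvaeConfig, vocab: SmilesVocabulary) -> CvaeModel:
    rng = np.random.default_rng(config.seed)
    V, C, H, Z = len(vocab), config.condition_dim, config.hidden_width, config.latent_dim
    return CvaeModel(
        config=config,
        vocab=vocab,
        encoder_rnn=LSTMStack(V + C, H, config.n_recurrent_cells, rng),
        mean_head=Dense(H, Z, rng),
        log_sigma_head=Dense(H, Z, rng),
        decoder_rnn=LSTMStack(V + Z + C, H, config.n_recurrent_cells, rng),
        token_head=Dense(H, V, rng),
    )


def gaussian_kl(mean: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Closed-form KL( N(mean, sigma^2) || N(0, I) ) per batch row:
    0.5 * sum(mean^2 + sigma^2 - 1 - ln sigma^2)."""
    mean = np.atleast_2d(mean)
    sigma = np.atleast_2d(sigma)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    return 0.5 * np.sum(mean**2 + sigma**2 - 1.0 - 2.0 * np.log(sigma), axis=1)


def cvae_loss(
    X: np.ndarray,
    decoder_probs: np.ndarray,
    mean: np.ndarray,
    sigma: np.ndarray,
    kl_weight: float = 1.0,
) -> float:
    """ELBO-style loss on arrays: reconstruction + kl_weight * KL.

    X and decoder_probs are (B x T x V); the reconstruction term is the
    per-token cross-entropy -sum_t log p_t[true token], and both terms are
    averaged over the batch.
    """
    X = np.atleast_3d(np.asarray(X, dtype=np.float64))
    P = np.atleast_3d(np.asarray(decoder_probs, dtype=np.float64))
    if X.shape != P.shape:
        raise ValueError(f"shape mismatch: X {X.shape} vs probs {P.shape}")
    p_true = np.sum(X * P, axis=2)
    recon = -np.sum(np.log(np.maximum(p_true, 1e-300)), axis=1)
    kl = gaussian_kl(mean, sigma)
    return float(np.mean(recon + kl_weight * kl))


def encode(
    model: CvaeModel, X: np.ndarray, c: np.ndarray, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Posterior (mean, sigma) and a seeded reparameterized sample z."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 2:
        X = X[None]
    if X.shape[1] != model.config.seq_len or X.shape[2] != len(model.vocab):
        raise ValueError(
            f"one-hot shape {X.shape[1:]} incompatible with seq_len "
            f"{model.config.seq_len} and vocab {len(model.vocab)}"
        )
    c_norm = model._norm_condition(c)
    if c_norm.shape[0] == 1 and X.shape[0] > 1:
        c_norm = np.repeat(c_norm, X.shape[0], axis=0)
    mean_t, log_sigma_t = model._encode_batch(X, c_norm)
    mean, sigma = mean_t.data, np.exp(log_sigma_t.data)
    eps = np.random.default_rng(seed).standard_normal(mean.shape)
    z = mean + sigma * eps
    return mean.squeeze(0) if mean.shape[0] == 1 else mean, \
        sigma.squeeze(0) if sigma.shape[0] == 1 else sigma, \
        z.squeeze(0) if z.shape[0] == 1 else z


def decode(model: CvaeModel, z: np.ndarray, c: np.ndarray) -> str:
    """Argmax-decode a single latent under a condition."""
    return decode_batch(model, np.atleast_2d(z), c)[0]


def decode_batch(model: CvaeModel, z: np.ndarray, c: np.ndarray) -> list[str]:
    z = np.atleast_2d(np.asarray(z, dtype=np.float64))
    if z.shape[1] != model.config.latent_dim:
        raise ValueError(
            f"latent length {z.shape[1]} != latent_dim {model.config.latent_dim}"
        )
    c_norm = model._norm_condition(c)
    if c_norm.shape[0] == 1 and z.shape[0] > 1:
        c_norm = np.repeat(c_norm, z.shape[0], axis=0)
    probs = model._decode_greedy(z, c_norm)
    return [one_hot_decode(probs[i], model.vocab) for i in range(z.shape[0])]


def decoder_probabilities(model: CvaeModel, z: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Per-position token probability rows (each row sums to 1)."""
    z = np.atleast_2d(np.asarray(z, dtype=np.float64))
    c_norm = model._norm_condition(c)
    if c_norm.shape[0] == 1 and z.shape[0] > 1:
        c_norm = np.repeat(c_norm, z.shape[0], axis=0)
    return model._decode_greedy(z, c_norm)


def train_cvae(
    model: CvaeModel,
    corpus: list[tuple[SmilesRecord, np.ndarray]],
) -> CvaeModel:
    """Train on (compound, condition) pairs until plateau or epochs_max.

    Loss is logged per epoch; training stops early when the relative
    improvement of the epoch loss is below 1e-4 for ``patience``
    consecutive epochs. Deterministic for a fixed config seed.
    """
    if not corpus:
        raise ValueError("empty training corpus")
    cfg = model.config
    V = len(model.vocab)
    X = np.zeros((len(corpus), cfg.seq_len, V))
    C = np.zeros((len(corpus), cfg.condition_dim))
    for i, (rec, cond) in enumerate(corpus):
        try:
            X[i] = one_hot_encode(rec.smiles, model.vocab, cfg.seq_len)
        except (KeyError, ValueError) as exc:
            raise ValueError(
                f"record {rec.compound_id!r} not encodable: {exc}"
            ) from exc
        cond = np.asarray(cond, dtype=np.float64).ravel()
        if cond.shape[0] != cfg.condition_dim:
            raise ValueError(
                f"record {rec.compound_id!r}: condition length {cond.shape[0]} "
                f"!= condition_dim {cfg.condition_dim}"
            )
        C[i] = cond
    targets = X.argmax(axis=2)  # B x T token indices

    model.cond_mean = C.mean(axis=0)
    model.cond_std = np.maximum(C.std(axis=0), 1e-8)
    C_norm = (C - model.cond_mean) / model.cond_std

    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    warmup_epochs = max(1, int(np.ceil(cfg.kl_warmup_fraction * cfg.epochs_max)))
    model.training_log = []
    plateau = 0
    prev_loss = np.inf
    for epoch in range(cfg.epochs_max):
        klw = cfg.kl_weight * min(1.0, (epoch + 1) / warmup_epochs)
        order = rng.permutation(len(corpus))
        losses = []
        for start in range(0, len(corpus), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            B = len(idx)
            mean_t, log_sigma_t = model._encode_batch(X[idx], C_norm[idx])
            eps = rng.standard_normal((B, cfg.latent_dim))
            sigma_t = log_sigma_t.exp()
            z_t = mean_t + sigma_t * Tensor(eps)
            logits = model._decode_teacher_t(z_t, C_norm[idx], X[idx])
            recon = None
            for t, logit_t in enumerate(logits):
                ce = softmax_cross_entropy(logit_t, targets[idx, t])
                recon = ce if recon is None else recon + ce
            kl = (
                (mean_t.square() + sigma_t.square() - 1.0 - log_sigma_t * 2.0) * 0.5
            ).sum()
            loss = (recon + kl * klw) * (1.0 / B)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        epoch_loss = float(np.mean(losses))
        model.training_log.append(
            {"epoch": epoch + 1, "loss": epoch_loss, "kl_weight": klw}
        )
        if epoch >= warmup_epochs:
            rel = (prev_loss - epoch_loss) / max(abs(prev_loss), 1e-12)
            if rel < 1e-4:
                plateau += 1
                if plateau >= cfg.patience:
                    break
            else:
                plateau = 0
        prev_loss = epoch_loss
    model.trained = True
    return model


def sample_designs(
    model: CvaeModel, c: np.ndarray, n: int, seed: int = 0
) -> list[str]:
    """n raw SMILES strings decoded from prior latent draws under c."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return []
    z = np.random.default_rng(seed).standard_normal((n, model.config.latent_dim))
    return decode_batch(model, z, c)
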