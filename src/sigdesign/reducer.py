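"""Dense autoencoder that compresses interaction signatures.

Full-length signatures (one score per protein) are highly redundant:
proteins share binding-site ligands, so signature columns are correlated.
The autoencoder exploits this to compress a signature to a short latent
vector — the condition vector fed to the generative model. The loss is the
RMSD between input and reconstructed signatures. Training stops when
validation loss has risen for ``patience`` consecutive epochs, and the
best-validation checkpoint is restored ("train until over-fitting is
observed").

Hidden layers use ReLU; the latent and output layers are linear. The
full-scale preset ``paper2021`` keeps the published schedule (input 14606,
encoder widths 10000 ... 200); the ``desk`` preset is a small geometric
schedule suitable for laptop-scale experiments and tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nn import Adam, Dense, Tensor
from .signatures import InteractionSignature, SignatureMatrix


@dataclass
class ReducerConfig:
    input_dim: int
    encoder_widths: list[int]
    epochs_max: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-3
    validation_fraction: float = 1.0 / 6.0
    patience: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.encoder_widths or any(w <= 0 for w in self.encoder_widths):
            raise ValueError("encoder widths must be positive")
        if not (0 < self.validation_fraction < 1):
            raise ValueError("validation_fraction must lie in (0, 1)")

    @property
    def latent_dim(self) -> int:
        return self.encoder_widths[-1]

    @classmethod
    def paper2021(cls, **kw) -> "ReducerConfig":
        """Full-scale preset: 14606-protein signatures reduced to 200 dims."""
        return cls(
            input_dim=14606,
            encoder_widths=[10000, 7750, 5500, 2250, 2000, 1250, 1000, 500, 250, 200],
            **kw,
        )

    @classmethod
    def desk(cls, input_dim: int = 100, latent_dim: int = 16, **kw) -> "ReducerConfig":
        """Small geometric schedule for desk-scale runs (default 100 -> 16)."""
        widths = []
        w = input_dim
        while w // 2 > latent_dim:
            w //= 2
            widths.append(w)
        widths.append(latent_dim)
        return cls(input_dim=input_dim, encoder_widths=widths, **kw)


@dataclass
class TrainedReducer:
    """Autoencoder with its config, parameters, and per-epoch loss log."""

    config: ReducerConfig
    encoder: list[Dense] = field(repr=False)
    decoder: list[Dense] = field(repr=False)
    training_log: list[dict] = field(default_factory=list)
    trained: bool = False

    def parameters(self):
        return [p for layer in self.encoder + self.decoder for p in layer.parameters()]

    def _encode_t(self, x: Tensor) -> Tensor:
        for layer in self.encoder[:-1]:
            x = layer(x).relu()
        return self.encoder[-1](x)

    def _decode_t(self, z: Tensor) -> Tensor:
        for layer in self.decoder[:-1]:
            z = layer(z).relu()
        return self.decoder[-1](z)

    def encode_array(self, x: np.ndarray) -> np.ndarray:
        return self._encode_t(Tensor(np.atleast_2d(x))).data

    def decode_array(self, z: np.ndarray) -> np.ndarray:
        return self._decode_t(Tensor(np.atleast_2d(z))).data

    def autoencode_array(self, x: np.ndarray) -> np.ndarray:
        return self.decode_array(self.encode_array(x))

    def save(self, checkpoint_dir: str | Path) -> None:
        """Write a checkpoint: manifest JSON + parameter blob."""
        out = Path(checkpoint_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "manifest.json").write_text(
            json.dumps(
                {
                    "config": vars(self.config),
                    "trained": self.trained,
                    "training_log": self.training_log,
                },
                indent=2,
            )
        )
        np.savez(
            out / "parameters.npz",
            **{f"p{i}": p.data for i, p in enumerate(self.parameters())},
        )

    @classmethod
    def load(cls, checkpoint_dir: str | Path) -> "TrainedReducer":
        out = Path(checkpoint_dir)
        manifest = json.loads((out / "manifest.json").read_text())
        reducer = build_reducer(ReducerConfig(**manifest["config"]))
        blob = np.load(out / "parameters.npz")
        for i, p in enumerate(reducer.parameters()):
            p.data = blob[f"p{i}"]
        reducer.trained = manifest["trained"]
        reducer.training_log = manifest["training_log"]
        return reducer


@dataclass
class ReducedSignature:
    """Latent (condition) vector for one compound."""

    compound_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("reduced signature must be finite")


def build_reducer(config: ReducerConfig) -> TrainedReducer:
    """Realize the architecture with seeded parameter initialization."""
    rng = np.random.default_rng(config.seed)
    dims_enc = [config.input_dim] + list(config.encoder_widths)
    dims_dec = list(reversed(config.encoder_widths)) + [config.input_dim]
    encoder = [Dense(a, b, rng) for a, b in zip(dims_enc[:-1], dims_enc[1:])]
    decoder = [Dense(a, b, rng) for a, b in zip(dims_dec[:-1], dims_dec[1:])]
    return TrainedReducer(config=config, encoder=encoder, decoder=decoder)


def reducer_loss(batch: np.ndarray, reconstruction: np.ndarray) -> float:
    """RMSD over all entries of a batch of signatures."""
    batch = np.asarray(batch, dtype=np.float64)
    reconstruction = np.asarray(reconstruction, dtype=np.float64)
    if batch.shape != reconstruction.shape:
        raise ValueError(
            f"shape mismatch: {batch.shape} vs {reconstruction.shape}"
        )
    return float(np.sqrt(np.mean((batch - reconstruction) ** 2)))


def _rmsd_loss_t(x: Tensor, xhat: Tensor) -> Tensor:
    return (x - xhat).square().mean().sqrt()


def train_reducer(reducer: TrainedReducer, matrix: SignatureMatrix) -> TrainedReducer:
    """Train with Adam on minibatches; early-stop on validation loss.

    Stops at ``epochs_max`` or when validation loss has risen for
    ``patience`` consecutive epochs; the best-validation checkpoint is
    restored. Deterministic for a fixed config seed.
    """
    cfg = reducer.config
    data = matrix.values
    if data.shape[0] < 10:
        raise ValueError("need at least 10 signatures to train")
    if data.shape[1] != cfg.input_dim:
        raise ValueError(
            f"matrix row length {data.shape[1]} != input_dim {cfg.input_dim}"
        )
    rng = np.random.default_rng(cfg.seed + 1)
    perm = rng.permutation(data.shape[0])
    n_val = max(1, int(round(data.shape[0] * cfg.validation_fraction)))
    val, train = data[perm[:n_val]], data[perm[n_val:]]

    opt = Adam(reducer.parameters(), lr=cfg.learning_rate)
    best_val = np.inf
    best_state: list[np.ndarray] | None = None
    rises = 0
    reducer.training_log = []
    for epoch in range(cfg.epochs_max):
        order = rng.permutation(train.shape[0])
        epoch_losses = []
        for start in range(0, train.shape[0], cfg.batch_size):
            xb = Tensor(train[order[start : start + cfg.batch_size]])
            xhat = reducer._decode_t(reducer._encode_t(xb))
            loss = _rmsd_loss_t(xb, xhat)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        val_loss = reducer_loss(val, reducer.autoencode_array(val))
        reducer.training_log.append(
            {
                "epoch": epoch + 1,
                "train_loss": float(np.mean(epoch_losses)),
                "val_loss": val_loss,
            }
        )
        if val_loss < best_val:
            best_val = val_loss
            best_state = [p.data.copy() for p in reducer.parameters()]
            rises = 0
        else:
            rises += 1
            if rises >= cfg.patience:
                break
    if best_state is not None:
        for p, s in zip(reducer.parameters(), best_state):
            p.data = s
    reducer.trained = True
    return reducer


def reduce_signature(reducer: TrainedReducer, sig: InteractionSignature) -> ReducedSignature:
    if len(sig) != reducer.config.input_dim:
        raise ValueError(
            f"signature length {len(sig)} != reducer input_dim {reducer.config.input_dim}"
        )
    return ReducedSignature(
        compound_id=sig.compound_id,
        values=reducer.encode_array(sig.scores)[0],
    )


def reduce_matrix(reducer: TrainedReducer, matrix: SignatureMatrix) -> np.ndarray:
    """Latent vectors for every row of a signature matrix (batched)."""
    if matrix.values.shape[1] != reducer.config.input_dim:
        raise ValueError("matrix row length does not match reducer input_dim")
    return reducer.encode_array(matrix.values)


def reconstruct_signature(reducer: TrainedReducer, red: ReducedSignature) -> np.ndarray:
    if red.values.shape[0] != reducer.config.latent_dim:
        raise ValueError(
            f"latent length {red.values.shape[0]} != latent_dim {reducer.config.latent_dim}"
        )
    return reducer.decode_array(red.values)[0]
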