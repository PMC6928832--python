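"""Recurrent sequence-autoencoder feature extraction.

Each multichannel sensor recording (channels x time) is compressed to a
short feature vector z by an encoder-decoder pair of gated recurrent
layers.  The encoder consumes the recording time-step by time-step — each
step is the vector of all channel values at that instant — and its final
hidden state is z.  The decoder, conditioned on z (as both its initial
hidden state and its per-step input), re-emits the sequence in forward
time order through a linear readout.  Training minimises the mean squared
reconstruction error

    MSE = (1/D) * sum_m (x_m - x~_m)^2,   D = n_channels * n_timesteps,

by full backprop-through-time with Adam.  Channels are standardised to
zero mean / unit variance over the training set before fitting, and the
same scaler is applied at encode time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._gru import Adam, GRULayer
from .synthetic import SensorSample

__all__ = [
    "TrainConfig",
    "AutoencoderModel",
    "reconstruction_error",
    "fit_autoencoder",
    "encode",
    "encode_all",
    "reconstruct",
    "save_model",
    "load_model",
    "write_feature_csv",
    "read_feature_csv",
]


@dataclass
class TrainConfig:
    """Autoencoder training configuration.

    Defaults suit the small sample sizes typical of clinical e-nose
    studies: a 16-dimensional latent code, 100 epochs of full-sequence
    Adam at 1e-2.  ``latent_dim`` must stay below the flattened input
    dimensionality (the model is a compression).
    """

    latent_dim: int = 16
    epochs: int = 100
    learning_rate: float = 1e-2
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("latent_dim, epochs and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class AutoencoderModel:
    """Fitted encoder/decoder pair and the training-set channel scaler."""

    latent_dim: int
    input_dims: tuple[int, int]
    encoder: GRULayer
    decoder: GRULayer
    Wo: np.ndarray
    bo: np.ndarray
    channel_mean: np.ndarray
    channel_std: np.ndarray
    training_history: list[float] = field(default_factory=list)

    @property
    def fitted(self) -> bool:
        return len(self.training_history) > 0


def reconstruction_error(x: np.ndarray, x_rec: np.ndarray) -> float:
    """Mean squared reconstruction error over all D scalar entries."""
    x = np.asarray(x, dtype=float)
    x_rec = np.asarray(x_rec, dtype=float)
    if x.shape != x_rec.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_rec.shape}")
    return float(np.mean((x - x_rec) ** 2))


def _as_signal_array(samples: list[SensorSample]) -> np.ndarray:
    shapes = {s.signal.shape for s in samples}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent sample shapes: {sorted(shapes)}")
    return np.stack([s.signal for s in samples])


def _standardize(signals: np.ndarray, mean: np.ndarray, std: np.ndarray) -> np.ndarray:
    # (n, C, T) -> time-major sequences (n, T, C)
    return ((signals - mean[None, :, None]) / std[None, :, None]).transpose(0, 2, 1)


def _forward(model: AutoencoderModel, x_seq: np.ndarray):
    B, T, _ = x_seq.shape
    H = model.latent_dim
    enc_hs, enc_cache = model.encoder.forward(x_seq, np.zeros((B, H)))
    z = enc_hs[:, -1]
    z_seq = np.broadcast_to(z[:, None, :], (B, T, H)).copy()
    dec_hs, dec_cache = model.decoder.forward(z_seq, z)
    y_seq = dec_hs @ model.Wo + model.bo
    return y_seq, z, dec_hs, enc_cache, dec_cache


def _train_step(model: AutoencoderModel, x_seq: np.ndarray,
                params: dict, optimizer: Adam) -> float:
    B, T, C = x_seq.shape
    y_seq, z, dec_hs, enc_cache, dec_cache = _forward(model, x_seq)
    resid = y_seq - x_seq
    loss = float(np.mean(resid ** 2))

    dy = 2.0 * resid / resid.size
    grads = {
        "Wo": np.einsum("bth,btc->hc", dec_hs, dy),
        "bo": dy.sum(axis=(0, 1)),
    }
    ddec_h = dy @ model.Wo.T
    dec_grads, dz_seq, dh0 = model.decoder.backward(dec_cache, dh_seq=ddec_h)
    dz = dz_seq.sum(axis=1) + dh0
    enc_grads, _, _ = model.encoder.backward(enc_cache, dh_last=dz)
    for k, g in dec_grads.items():
        grads[f"dec_{k}"] = g
    for k, g in enc_grads.items():
        grads[f"enc_{k}"] = g
    optimizer.step(params, grads)
    return loss


def fit_autoencoder(samples: list[SensorSample], config: TrainConfig) -> AutoencoderModel:
    """Train the sequence autoencoder on a set of samples.

    Raises a ``ValueError`` for fewer than two samples, inconsistent
    shapes, or a latent dimension that is not a compression.  Seeded
    initialisation and batch order make the training history reproducible.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to fit the autoencoder")
    signals = _as_signal_array(samples)
    n, C, T = signals.shape
    D = C * T
    if config.latent_dim >= D:
        raise ValueError(f"latent_dim={config.latent_dim} must be < input dim {D}")

    mean = signals.mean(axis=(0, 2))
    std = signals.std(axis=(0, 2))
    std = np.where(std < 1e-8, 1.0, std)
    x_all = _standardize(signals, mean, std)

    rng = np.random.default_rng(config.seed)
    model = AutoencoderModel(
        latent_dim=config.latent_dim,
        input_dims=(C, T),
        encoder=GRULayer(C, config.latent_dim, rng),
        decoder=GRULayer(config.latent_dim, config.latent_dim, rng),
        Wo=rng.uniform(-0.1, 0.1, size=(config.latent_dim, C)),
        bo=np.zeros(C),
        channel_mean=mean,
        channel_std=std,
    )
    params = {"Wo": model.Wo, "bo": model.bo}
    for prefix, layer in (("enc", model.encoder), ("dec", model.decoder)):
        for k, p in layer.params().items():
            params[f"{prefix}_{k}"] = p
    optimizer = Adam(params, lr=config.learning_rate)

    for _ in range(config.epochs):
        order = rng.permutation(n)
        total, count = 0.0, 0
        for start in range(0, n, config.batch_size):
            batch = order[start:start + config.batch_size]
            loss = _train_step(model, x_all[batch], params, optimizer)
            total += loss * len(batch)
            count += len(batch)
        model.training_history.append(total / count)
    return model


def encode(model: AutoencoderModel, sample: SensorSample | np.ndarray) -> np.ndarray:
    """Map one sample to its latent feature vector (length latent_dim)."""
    if not model.fitted:
        raise RuntimeError("model has not been fitted")
    signal = sample.signal if isinstance(sample, SensorSample) else np.asarray(sample, float)
    if signal.shape != model.input_dims:
        raise ValueError(f"sample shape {signal.shape} != model input {model.input_dims}")
    x_seq = _standardize(signal[None], model.channel_mean, model.channel_std)
    hs, _ = model.encoder.forward(x_seq, np.zeros((1, model.latent_dim)))
    return hs[0, -1].copy()


def encode_all(model: AutoencoderModel, samples: list[SensorSample]) -> np.ndarray:
    """Vectorised ``encode`` over a sample list; returns (n, latent_dim)."""
    if not model.fitted:
        raise RuntimeError("model has not been fitted")
    signals = _as_signal_array(samples)
    if signals.shape[1:] != model.input_dims:
        raise ValueError("sample shapes do not match the model's input dims")
    x_seq = _standardize(signals, model.channel_mean, model.channel_std)
    hs, _ = model.encoder.forward(x_seq, np.zeros((len(samples), model.latent_dim)))
    return hs[:, -1].copy()


def reconstruct(model: AutoencoderModel, sample: SensorSample | np.ndarray) -> np.ndarray:
    """Decode a sample back to signal space (de-standardised)."""
    if not model.fitted:
        raise RuntimeError("model has not been fitted")
    signal = sample.signal if isinstance(sample, SensorSample) else np.asarray(sample, float)
    x_seq = _standardize(signal[None], model.channel_mean, model.channel_std)
    y_seq, *_ = _forward(model, x_seq)
    rec = y_seq[0].T  # (C, T) in standardised units
    return rec * model.channel_std[:, None] + model.channel_mean[:, None]


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def save_model(model: AutoencoderModel, path: str | Path) -> None:
    arrays = {"Wo": model.Wo, "bo": model.bo,
              "channel_mean": model.channel_mean, "channel_std": model.channel_std,
              "training_history": np.asarray(model.training_history),
              "meta": np.array([model.latent_dim, *model.input_dims])}
    for prefix, layer in (("enc", model.encoder), ("dec", model.decoder)):
        for k, p in layer.params().items():
            arrays[f"{prefix}_{k}"] = p
    np.savez(path, **arrays)


def load_model(path: str | Path) -> AutoencoderModel:
    with np.load(path, allow_pickle=False) as data:
        latent_dim, C, T = (int(v) for v in data["meta"])
        rng = np.random.default_rng(0)
        enc = GRULayer(C, latent_dim, rng)
        dec = GRULayer(latent_dim, latent_dim, rng)
        for prefix, layer in (("enc", enc), ("dec", dec)):
            for k in layer.PARAM_NAMES:
                setattr(layer, k, data[f"{prefix}_{k}"])
        return AutoencoderModel(
            latent_dim=latent_dim, input_dims=(C, T), encoder=enc, decoder=dec,
            Wo=data["Wo"], bo=data["bo"],
            channel_mean=data["channel_mean"], channel_std=data["channel_std"],
            training_history=list(data["training_history"]),
        )


def write_feature_csv(path: str | Path, sample_ids: list[str], labels: np.ndarray,
                      features: np.ndarray) -> None:
    df = pd.DataFrame(features, columns=[f"f{i + 1}" for i in range(features.shape[1])])
    df.insert(0, "label", np.asarray(labels, dtype=int))
    df.insert(0, "sample_id", sample_ids)
    df.to_csv(path, index=False)


def read_feature_csv(path: str | Path) -> tuple[list[str], np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    ids = df["sample_id"].astype(str).tolist()
    labels = df["label"].to_numpy(dtype=int)
    features = df.drop(columns=["sample_id", "label"]).to_numpy(dtype=float)
    return ids, labels, features
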