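"""Synthetic electronic-nose data and vote-matrix generators.

Real breath-screening datasets are small, clinical, and rarely deposited,
so every downstream stage of this package (feature extraction, pool
training, pruning measures, evaluation) is exercised against two synthetic
substrates:

* labelled multichannel chemiresistor-style transient curves shaped like a
  gas-sensor-array recording (default 13 channels x 675 time steps per
  sample, two classes), and
* direct binary correctness ("vote") matrices with controllable
  per-classifier accuracy and inter-classifier correlation, the substrate
  on which margins and all pruning measures are defined.

Both generators are fully seeded: the same configuration always yields
bitwise-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SensorSample",
    "SimConfig",
    "VoteSimConfig",
    "generate_dataset",
    "generate_vote_matrix",
    "signals_to_matrix",
    "write_samples_csv",
    "read_samples_csv",
    "write_samples_npz",
    "read_samples_npz",
    "write_vote_csv",
    "read_vote_csv",
]


@dataclass
class SensorSample:
    """One subject's multichannel sensor response plus binary label.

    ``label`` follows the clinical convention used throughout the package:
    1 = positive / disease, 0 = negative / control.  ``signal`` has shape
    ``(n_channels, n_timesteps)`` in dimensionless response units.
    """

    sample_id: str
    label: int
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D (channels x time) matrix")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")

    @property
    def flattened(self) -> np.ndarray:
        """Row-major flattening; length n_channels * n_timesteps."""
        return self.signal.ravel()


@dataclass
class SimConfig:
    """Configuration of the sensor-curve generator.

    ``class_separation`` scales the gap between the two classes' mean
    amplitude vectors; ``positive_noise_inflation`` (>= 1) multiplies the
    noise standard deviation for positive-class samples only, providing a
    controllable ground truth for sensitivity experiments where the
    disease class is the harder one.
    """

    n_samples_per_class: int = 50
    n_channels: int = 13
    n_timesteps: int = 675
    class_separation: float = 1.0
    noise_sd: float = 0.1
    drift_sd: float = 0.05
    positive_noise_inflation: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_per_class < 1 or self.n_channels < 1 or self.n_timesteps < 1:
            raise ValueError("all counts must be >= 1")
        if self.class_separation < 0 or self.noise_sd < 0 or self.drift_sd < 0:
            raise ValueError("class_separation and noise/drift sd must be >= 0")
        if self.positive_noise_inflation < 1:
            raise ValueError("positive_noise_inflation must be >= 1")


@dataclass
class VoteSimConfig:
    """Configuration of the direct vote-matrix generator.

    ``per_classifier_accuracy`` may be a scalar (shared by all classifiers)
    or a length-``n_classifiers`` vector.  ``inter_classifier_correlation``
    in [0, 1) induces shared error patterns through a latent per-sample
    difficulty variable (Gaussian copula), emulating the correlated
    mistakes of bootstrapped trees.
    """

    n_samples: int = 100
    n_classifiers: int = 11
    per_classifier_accuracy: float | np.ndarray = 0.7
    inter_classifier_correlation: float = 0.0
    positive_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_classifiers < 1:
            raise ValueError("counts must be >= 1")
        if self.n_classifiers % 2 == 0:
            raise ValueError("n_classifiers must be odd to avoid voting ties")
        acc = np.atleast_1d(np.asarray(self.per_classifier_accuracy, dtype=float))
        if acc.size not in (1, self.n_classifiers):
            raise ValueError("per_classifier_accuracy must be scalar or per-classifier")
        if np.any(acc < 0) or np.any(acc > 1):
            raise ValueError("accuracies must lie in [0, 1]")
        if not 0 <= self.inter_classifier_correlation < 1:
            raise ValueError("inter_classifier_correlation must be in [0, 1)")
        if not 0 < self.positive_fraction < 1:
            raise ValueError("positive_fraction must be in (0, 1)")


def _kinetic_profile(n_timesteps: int) -> np.ndarray:
    # Canonical chemiresistor transient: saturating adsorption rise until
    # the gas is flushed, then exponential recovery toward baseline.
    t = np.arange(n_timesteps, dtype=float)
    tau_rise = max(n_timesteps / 6.0, 1.0)
    t_on = 0.6 * n_timesteps
    tau_rec = max(n_timesteps / 4.0, 1.0)
    rise = 1.0 - np.exp(-t / tau_rise)
    peak = 1.0 - np.exp(-t_on / tau_rise)
    profile = np.where(t <= t_on, rise, peak * np.exp(-(t - t_on) / tau_rec))
    return profile


def generate_dataset(config: SimConfig) -> list[SensorSample]:
    """Generate ``2 * n_samples_per_class`` labelled sensor samples.

    Each channel's curve is baseline + class-dependent amplitude x kinetic
    profile + i.i.d. Gaussian noise + a random slow (linear) baseline
    drift.  The positive class's noise is inflated by
    ``positive_noise_inflation``.
    """
    rng = np.random.default_rng(config.seed)
    C, T = config.n_channels, config.n_timesteps

    baseline = rng.uniform(0.5, 1.5, size=C)
    base_amp = rng.uniform(1.0, 3.0, size=C)
    # Per-channel direction of the class contrast; class_separation scales it.
    direction = rng.uniform(0.5, 1.5, size=C)
    profile = _kinetic_profile(T)

    samples: list[SensorSample] = []
    idx = 0
    for label in (0, 1):
        amp = base_amp + config.class_separation * (label - 0.5) * direction
        noise_sd = config.noise_sd * (config.positive_noise_inflation if label == 1 else 1.0)
        for _ in range(config.n_samples_per_class):
            noise = rng.normal(0.0, noise_sd, size=(C, T)) if noise_sd > 0 else 0.0
            if config.drift_sd > 0:
                w = rng.normal(0.0, config.drift_sd, size=(C, 2))
                drift = w[:, :1] + w[:, 1:] * (np.arange(T) / max(T - 1, 1))
            else:
                drift = 0.0
            signal = baseline[:, None] + amp[:, None] * profile[None, :] + noise + drift
            samples.append(SensorSample(f"sample_{idx:04d}", label, signal))
            idx += 1
    return samples


def generate_vote_matrix(config: VoteSimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Generate a binary correctness matrix and a label vector.

    Returns ``(votes, labels)`` where ``votes[i, j] = 1`` iff classifier j
    is correct on sample i.  Marginal correctness of column j equals the
    configured accuracy; a Gaussian copula with a shared per-sample latent
    difficulty induces the configured inter-classifier correlation.
    """
    from scipy.stats import norm

    rng = np.random.default_rng(config.seed)
    N, M = config.n_samples, config.n_classifiers
    acc = np.broadcast_to(
        np.atleast_1d(np.asarray(config.per_classifier_accuracy, dtype=float)), (M,)
    )
    rho = config.inter_classifier_correlation

    difficulty = rng.standard_normal((N, 1))
    idio = rng.standard_normal((N, M))
    z = np.sqrt(rho) * difficulty + np.sqrt(1.0 - rho) * idio
    # P(z < Phi^-1(a)) = a marginally; thresholds +/-inf handle a in {0, 1}.
    with np.errstate(divide="ignore"):
        thresh = norm.ppf(acc)
    votes = (z < thresh[None, :]).astype(np.int8)

    n_pos = int(round(N * config.positive_fraction))
    n_pos = min(max(n_pos, 1), N - 1)
    labels = np.zeros(N, dtype=np.int8)
    labels[rng.choice(N, size=n_pos, replace=False)] = 1
    return votes, labels


def signals_to_matrix(samples: list[SensorSample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack samples into ``(X, y)``: flattened signals and labels."""
    X = np.stack([s.flattened for s in samples])
    y = np.array([s.label for s in samples], dtype=int)
    return X, y


# ---------------------------------------------------------------------------
# round-trip I/O
# ---------------------------------------------------------------------------

def write_samples_csv(samples: list[SensorSample], path: str | Path) -> None:
    """Write samples to a long-format CSV: sample_id, label, channel, t, value."""
    frames = []
    for s in samples:
        C, T = s.signal.shape
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": np.repeat(s.sample_id, C * T),
                    "label": np.repeat(s.label, C * T),
                    "channel": np.repeat(np.arange(C), T),
                    "t": np.tile(np.arange(T), C),
                    "value": s.signal.ravel(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_samples_csv(path: str | Path) -> list[SensorSample]:
    df = pd.read_csv(path)
    samples = []
    for sid, grp in df.groupby("sample_id", sort=False):
        C = int(grp["channel"].max()) + 1
        T = int(grp["t"].max()) + 1
        signal = np.empty((C, T))
        signal[grp["channel"].to_numpy(), grp["t"].to_numpy()] = grp["value"].to_numpy()
        samples.append(SensorSample(str(sid), int(grp["label"].iloc[0]), signal))
    return samples


def write_samples_npz(samples: list[SensorSample], path: str | Path) -> None:
    """Compact binary container for large sample sets."""
    np.savez_compressed(
        path,
        signals=np.stack([s.signal for s in samples]),
        labels=np.array([s.label for s in samples], dtype=np.int8),
        sample_ids=np.array([s.sample_id for s in samples]),
    )


def read_samples_npz(path: str | Path) -> list[SensorSample]:
    with np.load(path, allow_pickle=False) as data:
        return [
            SensorSample(str(sid), int(lab), sig)
            for sid, lab, sig in zip(data["sample_ids"], data["labels"], data["signals"])
        ]


def write_vote_csv(votes: np.ndarray, labels: np.ndarray, path: str | Path) -> None:
    """Headerless CSV of 0/1: first column is the label, the rest votes."""
    out = np.column_stack([np.asarray(labels, dtype=int), np.asarray(votes, dtype=int)])
    np.savetxt(path, out, fmt="%d", delimiter=",")


def read_vote_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    data = np.loadtxt(path, delimiter=",", dtype=np.int8, ndmin=2)
    return data[:, 1:], data[:, 0]
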