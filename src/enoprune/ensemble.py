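"""Overproduce-and-vote ensemble machinery.

A pool of M CART decision trees is trained on independent bootstrap
sub-samples of the training split (sampling with replacement, default 30%
of N_Tr, which is what makes the trees diverse).  On the held-out pruning
split the pool yields a binary correctness ("vote") matrix, from which the
per-sample voting margin

    margin(x_i) = (#correct votes - #incorrect votes) / M  in [-1, 1]

is computed.  Margins and the vote matrix are the substrate of every
pruning measure in :mod:`enoprune.measures`.  Prediction is plain majority
voting over an odd-sized (sub-)ensemble; the fraction of learners voting
for the positive class doubles as a ranking score for AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "DatasetSplit",
    "EnsemblePool",
    "VoteMatrix",
    "MarginVector",
    "PrunedEnsemble",
    "train_pool",
    "compute_vote_matrix",
    "compute_margins",
    "predict",
]


@dataclass
class DatasetSplit:
    """Disjoint train / prune / test partition of a feature table."""

    X_train: np.ndarray
    y_train: np.ndarray
    X_prune: np.ndarray
    y_prune: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray


@dataclass
class EnsemblePool:
    """Ordered list of M trained base classifiers plus their bootstrap seeds."""

    learners: list[DecisionTreeClassifier]
    bootstrap_seeds: list[int]
    bootstrap_sizes: list[int]

    @property
    def size(self) -> int:
        return len(self.learners)


@dataclass
class VoteMatrix:
    """Correctness indicators of the pool on the pruning set.

    ``correct[i, j] = 1`` iff learner j's prediction on sample i equals
    the true label y_i.
    """

    correct: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.correct = np.asarray(self.correct, dtype=np.int8)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.correct.ndim != 2:
            raise ValueError("vote matrix must be 2-D (samples x classifiers)")
        if self.correct.shape[0] != self.labels.shape[0]:
            raise ValueError("labels length must match the number of rows")
        if not np.isin(self.correct, (0, 1)).all():
            raise ValueError("vote matrix entries must be 0/1")

    @property
    def n_samples(self) -> int:
        return self.correct.shape[0]

    @property
    def n_classifiers(self) -> int:
        return self.correct.shape[1]


@dataclass
class MarginVector:
    """Per-sample voting margins and pool-wide incorrect fractions NF^H."""

    margin: np.ndarray
    nf_pool: np.ndarray


@dataclass
class PrunedEnsemble:
    """Indices of the T selected learners under a given measure."""

    selected: np.ndarray
    measure_name: str
    marks: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.selected = np.asarray(self.selected, dtype=int)
        if len(np.unique(self.selected)) != len(self.selected):
            raise ValueError("selected indices must be distinct")


def _bootstrap_size(sample_fraction: float, n: int) -> int:
    # round-half-up of fraction * n, floor of 2 so a tree can always split
    return max(int(np.floor(sample_fraction * n + 0.5)), 2)


def train_pool(X: np.ndarray, y: np.ndarray, M: int = 101,
               sample_fraction: float = 0.3, seed: int = 0) -> EnsemblePool:
    """Train M CART trees on independent bootstrap sub-samples.

    Each bootstrap draws ``round(sample_fraction * N_Tr)`` samples with
    replacement.  A bootstrap that happens to contain a single class is
    redrawn (up to 10 attempts) since a one-class tree is degenerate.
    Trees use Gini impurity with unlimited depth.  All randomness derives
    deterministically from ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if M % 2 == 0:
        raise ValueError("M must be odd to avoid voting ties")
    if X.shape[0] < 2 or len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes and >= 2 samples")
    if not 0 < sample_fraction <= 1:
        raise ValueError("sample_fraction must be in (0, 1]")

    n = X.shape[0]
    size = _bootstrap_size(sample_fraction, n)
    rng = np.random.default_rng(seed)
    learners, seeds = [], []
    for _ in range(M):
        tree_seed = int(rng.integers(2 ** 31 - 1))
        for _attempt in range(10):
            idx = rng.integers(0, n, size=size)
            if len(np.unique(y[idx])) == 2:
                break
        else:
            raise ValueError("could not draw a two-class bootstrap in 10 attempts")
        tree = DecisionTreeClassifier(criterion="gini", random_state=tree_seed)
        tree.fit(X[idx], y[idx])
        learners.append(tree)
        seeds.append(tree_seed)
    return EnsemblePool(learners, seeds, [size] * M)


def _prediction_matrix(learners, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return np.column_stack([lrn.predict(X) for lrn in learners]).astype(np.int8)


def compute_vote_matrix(pool: EnsemblePool, X: np.ndarray, y: np.ndarray) -> VoteMatrix:
    """Correctness indicators of every learner on the pruning set."""
    y = np.asarray(y, dtype=int)
    preds = _prediction_matrix(pool.learners, X)
    return VoteMatrix((preds == y[:, None]).astype(np.int8), y)


def compute_margins(votes: VoteMatrix) -> MarginVector:
    """Per-sample margins (in [-1, 1]) and pool incorrect fractions."""
    if votes.n_samples == 0:
        raise ValueError("empty vote matrix")
    frac_correct = votes.correct.mean(axis=1)
    return MarginVector(margin=2.0 * frac_correct - 1.0, nf_pool=1.0 - frac_correct)


def predict(pool: EnsemblePool, subset: np.ndarray | list[int] | None,
            X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Majority-vote labels and positive-vote-fraction scores.

    ``subset`` selects learner indices (None = the full pool); its size
    must be odd so no tie can occur.
    """
    if subset is None:
        learners = pool.learners
    else:
        subset = np.asarray(subset, dtype=int)
        if subset.size == 0:
            raise ValueError("subset must be non-empty")
        learners = [pool.learners[j] for j in subset]
    if len(learners) % 2 == 0:
        raise ValueError("subset size must be odd to avoid voting ties")
    preds = _prediction_matrix(learners, X)
    scores = preds.mean(axis=1)
    labels = (scores > 0.5).astype(int)
    return labels, scores
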