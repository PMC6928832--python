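"""Ensemble-pruning measures: MSM/MEP, UMEP, MDM, and greedy SDAcc.

All measures score base classifiers from the same substrate — the binary
correctness (vote) matrix on the pruning set and the induced per-sample
voting margins — and differ only in how they weight a correct decision.

MSM (margin and sensitivity based measure), the measure this package is
built around, gives classifier h the mark

    MSM(h) = (1/N_Pr) * sum_i  I(h(x_i) = y_i)
                               * I(margin(x_i) > theta)
                               * exp(y_i * NF_i^H)
                               * exp(-margin(x_i))

where NF_i^H is the fraction of the full pool that misclassifies x_i.
The exp(-margin) factor pays more for correct decisions on hard (low or
negative margin) samples; the exp(y * NF) "bonus" factor additionally
rewards correct decisions on positive (disease) samples, which is what
pushes the pruned ensemble toward high sensitivity.  theta in [-1, 0]
excludes near-unanimously misclassified samples as presumed outliers.
Disabling the bonus factor yields the MEP ablation.

UMEP weights a correct decision by -ln(margin), ignoring samples with
non-positive margin entirely.  MDM blends a margin term
-ln(max(|margin|, eps)) with a diversity term -ln(fraction of pool
correct), trade-off alpha.  SDAcc is a greedy forward-selection mark
based on the four (classifier correct?, sub-ensemble correct?) events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble import MarginVector, PrunedEnsemble, VoteMatrix, compute_margins

__all__ = [
    "MSMConfig",
    "MDMConfig",
    "MeasureRanking",
    "EVENT_CODES",
    "msm_scores",
    "umep_scores",
    "mdm_scores",
    "sdacc_mark",
    "sdacc_greedy_select",
]

EVENT_CODES = ("e00", "e01", "e10", "e11")


@dataclass
class MSMConfig:
    """MSM parameters.

    ``theta``: margin threshold in [-1, 0] below which (inclusive) a
    sample is treated as an outlier and contributes nothing.  The default
    -0.8 retains hard samples while excluding near-unanimous errors.
    ``bonus_enabled=False`` turns MSM into its MEP ablation (no
    sensitivity bonus).
    """

    theta: float = -0.8
    bonus_enabled: bool = True

    def __post_init__(self) -> None:
        if not -1.0 <= self.theta <= 0.0:
            raise ValueError(f"theta must lie in [-1, 0], got {self.theta}")


@dataclass
class MDMConfig:
    """MDM parameters: margin/diversity trade-off ``alpha`` in [0, 1] and
    the clamp ``epsilon_clamp`` keeping the log of |margin| finite
    (defaults to 1/M when None)."""

    alpha: float = 0.5
    epsilon_clamp: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.epsilon_clamp is not None and self.epsilon_clamp <= 0:
            raise ValueError("epsilon_clamp must be positive")


@dataclass
class MeasureRanking:
    """Per-classifier marks and the induced descending ordering.

    Ties are broken by ascending classifier index (stable sort) so the
    ordering is deterministic.
    """

    marks: np.ndarray
    order: np.ndarray
    measure_name: str
    config: object = None

    def top(self, T: int) -> PrunedEnsemble:
        if T > len(self.order):
            raise ValueError(f"T={T} exceeds pool size {len(self.order)}")
        sel = self.order[:T]
        return PrunedEnsemble(sel, self.measure_name, self.marks[sel])


def _ranking(marks: np.ndarray, name: str, config=None) -> MeasureRanking:
    order = np.argsort(-marks, kind="stable")
    return MeasureRanking(np.asarray(marks, float), order, name, config)


def _check_dims(votes: VoteMatrix, margins: MarginVector) -> None:
    if margins.margin.shape[0] != votes.n_samples:
        raise ValueError("margin vector length must match vote-matrix rows")


def msm_scores(votes: VoteMatrix, margins: MarginVector | None = None,
               config: MSMConfig | None = None) -> MeasureRanking:
    """Margin and sensitivity based marks for every classifier.

    With ``config.bonus_enabled=False`` the bonus factor exp(y*NF) is
    replaced by 1, giving the MEP ablation.  The threshold comparison is
    strict (margin > theta).
    """
    config = config or MSMConfig()
    margins = margins if margins is not None else compute_margins(votes)
    _check_dims(votes, margins)
    keep = margins.margin > config.theta
    weight = np.exp(-margins.margin) * keep
    if config.bonus_enabled:
        weight = weight * np.exp(votes.labels * margins.nf_pool)
    marks = votes.correct.T @ weight / votes.n_samples
    name = "msm" if config.bonus_enabled else "mep"
    return _ranking(marks, name, config)


def umep_scores(votes: VoteMatrix, margins: MarginVector | None = None) -> MeasureRanking:
    """Unsupervised-margin marks: -ln(margin) summed over each
    classifier's correct decisions; samples with margin <= 0 are ignored
    entirely; normalised by N_Pr."""
    margins = margins if margins is not None else compute_margins(votes)
    _check_dims(votes, margins)
    positive = margins.margin > 0
    weight = np.zeros_like(margins.margin)
    weight[positive] = -np.log(margins.margin[positive])
    marks = votes.correct.T @ weight / votes.n_samples
    return _ranking(marks, "umep")


def mdm_scores(votes: VoteMatrix, margins: MarginVector | None = None,
               config: MDMConfig | None = None) -> MeasureRanking:
    """Margin-and-diversity marks: alpha * f_m + (1-alpha) * f_d summed
    over each classifier's correct decisions, with
    f_m = -ln(max(|margin|, eps)) and f_d = -ln(fraction of pool correct)."""
    config = config or MDMConfig()
    margins = margins if margins is not None else compute_margins(votes)
    _check_dims(votes, margins)
    M = votes.n_classifiers
    eps = config.epsilon_clamp if config.epsilon_clamp is not None else 1.0 / M
    f_m = -np.log(np.maximum(np.abs(margins.margin), eps))
    frac_correct = np.maximum(1.0 - margins.nf_pool, 1.0 / M)
    f_d = -np.log(frac_correct)
    weight = config.alpha * f_m + (1.0 - config.alpha) * f_d
    marks = votes.correct.T @ weight
    return _ranking(marks, "mdm", config)


def sdacc_mark(event: str, nt_sub: float, nf_sub: float, *, tol: float = 1e-8) -> float:
    """Per-sample SDAcc mark for one (classifier, sub-ensemble) event.

    ``nt_sub``/``nf_sub`` are the fractions of the current sub-ensemble
    voting correctly/incorrectly on the sample (they must sum to 1).
    A correct classifier earns +NF whether the sub-ensemble is right
    (e11) or wrong (e10); a wrong classifier loses NF if the sub-ensemble
    is right (e01) and NT if it is also wrong (e00).
    """
    if event not in EVENT_CODES:
        raise ValueError(f"event must be one of {EVENT_CODES}, got {event!r}")
    if not (0.0 <= nt_sub <= 1.0 and 0.0 <= nf_sub <= 1.0):
        raise ValueError("nt_sub and nf_sub must lie in [0, 1]")
    if abs(nt_sub + nf_sub - 1.0) > tol:
        raise ValueError(f"nt_sub + nf_sub must equal 1, got {nt_sub + nf_sub}")
    if event in ("e10", "e11"):
        return nf_sub
    if event == "e01":
        return -nf_sub
    return -nt_sub  # e00


def sdacc_greedy_select(votes: VoteMatrix, T: int) -> PrunedEnsemble:
    """Greedy forward selection under the SDAcc mark.

    Seeds the sub-ensemble with the individually most accurate classifier
    on the pruning set (ties -> lowest index), then repeatedly adds the
    candidate maximising the summed event marks against the *current*
    sub-ensemble until T members are selected.  A majority-vote tie of an
    even-sized sub-ensemble counts as an incorrect sub-ensemble decision.
    """
    if T > votes.n_classifiers:
        raise ValueError(f"T={T} exceeds pool size {votes.n_classifiers}")
    if T < 1 or T % 2 == 0:
        raise ValueError("T must be a positive odd integer")
    correct = votes.correct.astype(float)
    accuracies = correct.mean(axis=0)
    selected = [int(np.argmax(accuracies))]
    remaining = set(range(votes.n_classifiers)) - set(selected)

    while len(selected) < T:
        sub = correct[:, selected]
        cnt = sub.sum(axis=1)
        s = len(selected)
        nt = cnt / s
        nf = 1.0 - nt
        sub_correct = cnt > s / 2.0  # strict majority; tie -> incorrect
        # correct candidate: +nf (e10/e11); wrong: -nf if sub right else -nt
        wrong_penalty = np.where(sub_correct, -nf, -nt)
        best_j, best_gain = -1, -np.inf
        for j in sorted(remaining):
            h = correct[:, j]
            gain = float(np.sum(h * nf + (1.0 - h) * wrong_penalty))
            if gain > best_gain:
                best_j, best_gain = j, gain
        selected.append(best_j)
        remaining.discard(best_j)
    return PrunedEnsemble(np.array(selected), "sdacc")
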