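import numpy as np
import pandas as pd
import pytest

import enoprune as ep
from enoprune.ensemble import compute_margins, compute_vote_matrix, train_pool
from enoprune.evaluation import (ExperimentConfig, auc_score,
                                 confusion_metrics, cross_validate,
                                 rank_scores, run_msep, stratified_split)
from enoprune.measures import MSMConfig, msm_scores


class TestStratifiedSplit:
    def test_disjoint_and_complete(self):
        y = np.r_[np.zeros(70, dtype=int), np.ones(30, dtype=int)]
        rng = np.random.default_rng(0)
        tr, pr, te = stratified_split(y, (7, 2, 1), rng)
        all_idx = np.concatenate([tr, pr, te])
        assert len(all_idx) == 100
        assert len(np.unique(all_idx)) == 100
        # largest-remainder at 7:2:1 per class
        assert len(tr) == 70 and len(pr) == 20 and len(te) == 10

    def test_stratification_preserves_class_ratio(self):
        y = np.r_[np.zeros(70, dtype=int), np.ones(30, dtype=int)]
        tr, pr, te = stratified_split(y, (7, 2, 1), np.random.default_rng(1))
        assert y[tr].sum() == 21 and y[pr].sum() == 6 and y[te].sum() == 3

    def test_tiny_class_cannot_fill_parts(self):
        y = np.r_[np.zeros(50, dtype=int), np.ones(2, dtype=int)]
        with pytest.raises(ValueError):
            stratified_split(y, (7, 2, 1), np.random.default_rng(0))


class TestConfusionMetrics:
    def test_perfect_prediction(self):
        y = np.array([0, 1, 1, 0])
        m = confusion_metrics(y, y)
        assert m["acc"] == m["sen"] == m["spe"] == 1.0

    def test_missing_negatives_spe_undefined(self):
        y_true = np.array([1, 1, 1, 1])
        y_pred = np.array([1, 1, 1, 0])
        m = confusion_metrics(y_true, y_pred)
        assert m["sen"] == 0.75
        assert np.isnan(m["spe"])

    def test_worked_counts(self):
        y_true = np.r_[np.ones(50, dtype=int), np.zeros(50, dtype=int)]
        y_pred = np.r_[np.ones(50, dtype=int), np.ones(10, dtype=int),
                       np.zeros(40, dtype=int)]
        m = confusion_metrics(y_true, y_pred)
        c = m["counts"]
        assert (c.TP, c.FP, c.TN, c.FN) == (50, 10, 40, 0)
        assert m["acc"] == 0.9 and m["sen"] == 1.0 and m["spe"] == 0.8
        assert m["acc"] == (c.TP + c.TN) / c.total

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(np.array([]), np.array([]))


class TestAUC:
    def test_perfect_separation(self):
        assert auc_score(np.array([0, 0, 1, 1]), np.array([0.1, 0.2, 0.8, 0.9])) == 1.0

    def test_constant_scores_chance_level(self):
        assert auc_score(np.array([0, 1, 0, 1]), np.full(4, 0.5)) == 0.5

    def test_worked_example(self):
        assert auc_score(np.array([0, 0, 1, 1]),
                         np.array([0.1, 0.4, 0.35, 0.8])) == pytest.approx(0.75)

    def test_matches_bruteforce_pair_counting(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        s = rng.choice(np.linspace(0, 1, 11), size=40)  # forces ties
        pos, neg = s[y == 1], s[y == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert auc_score(y, s) == pytest.approx(wins / (len(pos) * len(neg)))

    def test_single_class_flagged(self):
        assert np.isnan(auc_score(np.ones(5, dtype=int), np.linspace(0, 1, 5)))


def _rerun_ordering_pipeline(X, y, config, seed):
    """Independent re-execution of the ordering pipeline for one split."""
    rng = np.random.default_rng(seed)
    tr, pr, te = stratified_split(y, config.split_ratio, rng)
    pool_seed = int(rng.integers(2 ** 31 - 1))
    pool = train_pool(X[tr], y[tr], M=config.M,
                      sample_fraction=config.sample_fraction, seed=pool_seed)
    votes = compute_vote_matrix(pool, X[pr], y[pr])
    margins = compute_margins(votes)
    # explicit per-classifier mark accumulation, then top-T
    N = votes.n_samples
    marks = np.zeros(config.M)
    for j in range(config.M):
        for i in range(N):
            if votes.correct[i, j] and margins.margin[i] > config.msm.theta:
                marks[j] += (np.exp(votes.labels[i] * margins.nf_pool[i])
                             * np.exp(-margins.margin[i]))
    marks /= N
    return np.argsort(-marks, kind="stable")[:config.T]


class TestRunMSEP:
    def test_default_selects_eleven_from_101(self, small_dataset):
        _, X, y = small_dataset
        pruned, metrics = run_msep(X, y, ExperimentConfig(seed=7))
        assert len(pruned.selected) == 11
        assert 0.0 <= metrics["acc"] <= 1.0

    def test_M_equals_T_keeps_whole_pool(self, small_dataset):
        _, X, y = small_dataset
        cfg = ExperimentConfig(M=11, T=11, seed=1)
        pruned, _ = run_msep(X, y, cfg)
        assert sorted(pruned.selected.tolist()) == list(range(11))

    def test_matches_stepwise_reexecution(self, small_dataset):
        _, X, y = small_dataset
        cfg = ExperimentConfig(M=15, T=5, seed=9)
        pruned, _ = run_msep(X, y, cfg, seed=9)
        expected = _rerun_ordering_pipeline(X, y, cfg, seed=9)
        np.testing.assert_array_equal(pruned.selected, expected)

    @pytest.mark.parametrize("measure", ["mep", "umep", "mdm", "sdacc", "full"])
    def test_all_measures_run(self, small_dataset, measure):
        _, X, y = small_dataset
        cfg = ExperimentConfig(M=15, T=5, measure=measure, seed=2)
        pruned, metrics = run_msep(X, y, cfg)
        expected_size = 15 if measure == "full" else 5
        assert len(pruned.selected) == expected_size
        assert np.isfinite(metrics["acc"])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ExperimentConfig(M=10)
        with pytest.raises(ValueError):
            ExperimentConfig(T=102)
        with pytest.raises(ValueError):
            ExperimentConfig(measure="nope")


class TestCrossValidate:
    def test_single_repetition_zero_std(self, small_dataset):
        _, X, y = small_dataset
        cfg = ExperimentConfig(M=11, T=3, repetitions=1, seed=4)
        rep = cross_validate(X, y, cfg)
        assert len(rep.per_repetition) == 1
        assert rep.std["acc"] == 0.0
        assert rep.mean["acc"] == rep.per_repetition[0]["acc"]

    def test_master_seed_reproducibility(self, small_dataset):
        _, X, y = small_dataset
        cfg = ExperimentConfig(M=11, T=3, repetitions=3, seed=5)
        r1 = cross_validate(X, y, cfg)
        r2 = cross_validate(X, y, cfg)
        assert r1.mean == r2.mean and r1.std == r2.std

    def test_easy_data_high_accuracy(self, easy_dataset):
        _, X, y = easy_dataset
        cfg = ExperimentConfig(M=21, T=5, repetitions=10, seed=6)
        rep = cross_validate(X, y, cfg)
        assert rep.mean["acc"] > 0.95

    def test_pruned_beats_random_subset_on_heterogeneous_pool(self):
        """Pruning sanity: when classifier quality genuinely varies, the
        MSM-selected sub-ensemble beats a random size-T subset on an
        independent realisation of the same classifiers, on average over
        50 seeds.  (With perfectly exchangeable classifiers there is
        nothing to select and the comparison is a coin flip.)"""
        from enoprune.ensemble import VoteMatrix
        from enoprune.measures import msm_scores
        diffs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            acc = rng.uniform(0.55, 0.85, 21)

            def realise(s):
                votes, _ = ep.generate_vote_matrix(ep.VoteSimConfig(
                    n_samples=60, n_classifiers=21, per_classifier_accuracy=acc,
                    inter_classifier_correlation=0.3, seed=s))
                return votes

            v_prune = realise(2 * seed + 1)
            v_test = realise(2 * seed + 100001)
            labels = rng.integers(0, 2, size=60)
            sel = msm_scores(VoteMatrix(v_prune, labels)).top(5).selected
            acc_sel = (v_test[:, sel].sum(axis=1) >= 3).mean()
            rand_accs = [
                (v_test[:, np.random.default_rng(1000 * seed + k)
                        .choice(21, 5, replace=False)].sum(axis=1) >= 3).mean()
                for k in range(10)
            ]
            diffs.append(acc_sel - np.mean(rand_accs))
        assert np.mean(diffs) >= 0.0


class TestRankScores:
    def test_rank_pattern_7763_averages_675(self):
        # model A best in three metrics, second in one -> (7+7+6+7)/4 = 6.75
        table = pd.DataFrame({
            "acc": [93.5, 93.3, 90.5, 91.4, 89.9, 89.8, 91.0],
            "sen": [94.2, 93.4, 89.9, 90.7, 89.0, 90.8, 91.8],
            "spe": [92.8, 93.1, 91.0, 91.7, 90.7, 88.5, 91.2],
            "auc": [0.924, 0.921, 0.910, 0.912, 0.900, 0.901, 0.913],
        }, index=list("ABCDEFG"))
        points = rank_scores(table)
        assert points.loc["A", ["acc", "sen", "spe", "auc"]].tolist() == [7, 7, 6, 7]
        assert points.loc["A", "average"] == pytest.approx(6.75)

    def test_distinct_values_give_permutation(self):
        table = pd.DataFrame({"m": [0.3, 0.9, 0.5, 0.7]}, index=list("abcd"))
        pts = rank_scores(table)["m"]
        assert sorted(pts.tolist()) == [1, 2, 3, 4]

    def test_two_way_tie_shares_mean(self):
        table = pd.DataFrame({"m": [0.5, 0.5]}, index=["a", "b"])
        pts = rank_scores(table)["m"]
        assert pts.tolist() == [1.5, 1.5]

    def test_missing_values_excluded_with_warning(self):
        table = pd.DataFrame({"m1": [0.2, 0.4, 0.6], "m2": [0.1, np.nan, 0.3]},
                             index=list("xyz"))
        with pytest.warns(UserWarning):
            pts = rank_scores(table)
        assert np.isnan(pts.loc["y", "m2"])
        assert pts.loc["y", "average"] == pts.loc["y", "m1"]

    def test_single_model_rejected(self):
        with pytest.raises(ValueError):
            rank_scores(pd.DataFrame({"m": [1.0]}, index=["only"]))
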