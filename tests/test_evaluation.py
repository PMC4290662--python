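import numpy as np
import pandas as pd
import pytest

from linkerrf import (
    ConfusionCounts,
    ForestConfig,
    PipelineConfig,
    ablate_by_ig,
    cross_validate,
    f_measure,
    information_gain,
    score,
    sweep_trees,
    sweep_window,
)
from linkerrf.evaluation import group_information_gain, metrics_from_counts


def brute_force_score(truth, predicted):
    tp = tn = fp = fn = 0
    for t_vec, p_vec in zip(truth, predicted):
        for t, p in zip(t_vec, p_vec):
            if t and p:
                tp += 1
            elif t and not p:
                fn += 1
            elif not t and p:
                fp += 1
            else:
                tn += 1
    return tp, tn, fp, fn


FAST_PIPE = PipelineConfig(forest=ForestConfig(n_trees=8), window=5)


class TestScore:
    def test_hand_built_confusion_matrix(self):
        truth = [np.array([1] * 10 + [0] * 90)]
        pred = [np.array([1] * 7 + [0] * 3 + [1] * 1 + [0] * 89)]
        rep = score(truth, pred)
        assert rep.counts == ConfusionCounts(TP=7, TN=89, FP=1, FN=3)
        assert rep.accuracy == pytest.approx(0.96)
        assert rep.recall == pytest.approx(0.7)
        assert rep.precision == pytest.approx(0.875)
        assert rep.f1 == pytest.approx(0.77778, abs=5e-6)

    def test_perfect_prediction(self):
        truth = [np.array([0, 1, 1, 0]), np.array([1, 0])]
        rep = score(truth, truth)
        assert rep.accuracy == rep.recall == rep.precision == rep.f1 == 1.0

    def test_zero_denominators_flagged_as_zero(self):
        rep = score([np.zeros(5)], [np.zeros(5)])
        assert rep.recall == 0.0 and rep.precision == 0.0 and rep.f1 == 0.0
        assert {"recall", "precision", "f1"} <= set(rep.zero_division_flags)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            score([np.zeros(5)], [np.zeros(4)])

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        truth = [rng.integers(0, 2, size=rng.integers(1, 50)) for _ in range(8)]
        pred = [rng.integers(0, 2, size=len(t)) for t in truth]
        rep = score(truth, pred)
        tp, tn, fp, fn = brute_force_score(truth, pred)
        assert rep.counts == ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)
        assert rep.counts.total == sum(len(t) for t in truth)

    def test_f1_is_harmonic_mean_of_own_p_and_r(self):
        rng = np.random.default_rng(23)
        truth = [rng.integers(0, 2, 60)]
        pred = [rng.integers(0, 2, 60)]
        rep = score(truth, pred)
        assert rep.f1 == pytest.approx(f_measure(rep.recall, rep.precision))
        assert min(rep.precision, rep.recall) <= rep.f1 <= max(
            rep.precision, rep.recall
        )


class TestFMeasure:
    @pytest.mark.parametrize(
        "r, p, f1, printed_ulp",
        [
            (0.675, 0.987, 0.802, 5e-4),
            (0.71, 0.98, 0.82, 5e-3),
            (0.54, 0.50, 0.52, 5e-3),
            (0.169, 0.204, 0.185, 5e-4),
        ],
    )
    def test_published_identities(self, r, p, f1, printed_ulp):
        """F1 values round-trip from their published recall/precision pairs
        to the precision at which each F1 was printed."""
        assert f_measure(r, p) == pytest.approx(f1, abs=printed_ulp)

    def test_degenerate_zero(self):
        assert f_measure(0.0, 0.0) == 0.0


class TestCrossValidate:
    def test_k_bounds_rejected(self, small_synthetic_corpus):
        with pytest.raises(ValueError, match="k must be"):
            cross_validate(small_synthetic_corpus, k=1)
        with pytest.raises(ValueError, match="k must be"):
            cross_validate(small_synthetic_corpus, k=99)

    def test_same_seed_reproduces_metrics(self, small_synthetic_corpus):
        a = cross_validate(small_synthetic_corpus, 3, FAST_PIPE, seed=5)
        b = cross_validate(small_synthetic_corpus, 3, FAST_PIPE, seed=5)
        assert (a.recall, a.precision, a.f1) == (b.recall, b.precision, b.f1)
        assert a.counts == b.counts

    def test_leave_one_sequence_out_boundary(self, small_synthetic_corpus):
        rep = cross_validate(
            small_synthetic_corpus, k=len(small_synthetic_corpus), pipeline=FAST_PIPE
        )
        assert len(rep.per_fold) == len(small_synthetic_corpus)

    def test_pooled_counts_equal_fold_sums(self, small_synthetic_corpus):
        rep = cross_validate(small_synthetic_corpus, 4, FAST_PIPE, seed=2)
        summed = ConfusionCounts()
        for fold in rep.per_fold:
            summed = summed + fold.counts
        assert summed == rep.counts
        total = sum(len(s) for s in small_synthetic_corpus.sequences)
        assert rep.counts.total == total

    def test_fold_mean_aggregation_reported(self, small_synthetic_corpus):
        rep = cross_validate(small_synthetic_corpus, 3, FAST_PIPE, seed=1)
        assert rep.aggregation == "fold_mean"
        assert rep.recall == pytest.approx(
            np.mean([f.recall for f in rep.per_fold])
        )
        pooled = rep.pooled_metrics()
        assert pooled.aggregation == "pooled"
        assert 0 <= pooled.f1 <= 1

    def test_packaged_index_mode_runs(self, small_synthetic_corpus):
        from linkerrf import EncodingConfig

        pipe = PipelineConfig(
            encoding=EncodingConfig(linker_index_source="packaged_table"),
            forest=ForestConfig(n_trees=8),
            window=5,
        )
        rep = cross_validate(small_synthetic_corpus, 3, pipe, seed=0)
        assert rep.counts.total > 0


class TestSweeps:
    def test_single_window_matches_direct_cv(self, small_synthetic_corpus):
        table = sweep_window(
            small_synthetic_corpus, [5], subset_size=len(small_synthetic_corpus),
            pipeline=FAST_PIPE, k=3, seed=4,
        )
        direct = cross_validate(small_synthetic_corpus, 3, FAST_PIPE, seed=4)
        assert len(table) == 1
        assert table.loc[0, "f1"] == pytest.approx(direct.f1)

    def test_one_row_per_size(self, small_synthetic_corpus):
        table = sweep_window(
            small_synthetic_corpus, [3, 5, 7], subset_size=6,
            pipeline=FAST_PIPE, k=2, seed=0,
        )
        assert table["window"].tolist() == [3, 5, 7]

    def test_even_window_rejected(self, small_synthetic_corpus):
        with pytest.raises(ValueError, match="odd"):
            sweep_window(small_synthetic_corpus, [8], subset_size=4)

    def test_oversized_subset_rejected(self, small_synthetic_corpus):
        with pytest.raises(ValueError, match="subset_size"):
            sweep_window(small_synthetic_corpus, [5], subset_size=10**4)

    def test_tree_sweep_rows_and_duplicates(self, small_synthetic_corpus):
        table = sweep_trees(
            small_synthetic_corpus, [4, 8], subset_size=6,
            pipeline=FAST_PIPE, k=2, seed=0,
        )
        assert table["n_trees"].tolist() == [4, 8]
        with pytest.raises(ValueError, match="duplicate"):
            sweep_trees(small_synthetic_corpus, [10, 10], subset_size=4)


class TestInformationGain:
    def test_perfect_predictor_gains_full_entropy(self):
        y = np.array([0, 1] * 50)
        ig = information_gain(y[:, None].astype(float), y)
        assert ig[0] == pytest.approx(1.0)  # H(y) = 1 bit for balanced y

    def test_unbalanced_perfect_predictor(self):
        y = np.array([0] * 75 + [1] * 25)
        h = -(0.75 * np.log2(0.75) + 0.25 * np.log2(0.25))
        ig = information_gain(y[:, None].astype(float), y)
        assert ig[0] == pytest.approx(h)

    def test_independent_feature_gains_nothing(self):
        rng = np.random.default_rng(31)
        n = 10**4
        y = rng.integers(0, 2, n)
        x = rng.normal(size=(n, 1))
        assert information_gain(x, y)[0] < 0.01

    def test_four_instance_hand_enumeration(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([0, 0, 1, 1])
        assert information_gain(X, y)[0] == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(400, 1))
        y = (x[:, 0] + rng.normal(scale=0.8, size=400) > 0).astype(int)
        ig_raw = information_gain(x, y)[0]
        ig_exp = information_gain(np.exp(x), y)[0]
        assert ig_raw == pytest.approx(ig_exp, abs=1e-12)

    def test_constant_labels_warn_and_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            ig = information_gain(np.random.default_rng(0).normal(size=(10, 3)),
                                  np.zeros(10, dtype=int))
        np.testing.assert_array_equal(ig, 0.0)

    def test_constant_feature_has_zero_gain(self):
        y = np.array([0, 1] * 10)
        X = np.column_stack([np.ones(20), y.astype(float)])
        ig = information_gain(X, y)
        assert ig[0] == 0.0 and ig[1] > 0.9

    def test_group_aggregation(self):
        y = np.array([0, 1] * 20)
        X = np.column_stack([y.astype(float), np.ones(40)])
        groups = {"good": [0], "flat": [1]}
        gig = group_information_gain(X, y, groups)
        assert gig["good"] > gig["flat"] == 0.0


class TestAblation:
    def test_row_zero_matches_unablated_cv(self, small_synthetic_corpus):
        table = ablate_by_ig(small_synthetic_corpus, FAST_PIPE, k=3, seed=6)
        direct = cross_validate(small_synthetic_corpus, 3, FAST_PIPE, seed=6)
        assert table.loc[0, "removed"] == "none"
        assert table.loc[0, "f1"] == pytest.approx(direct.f1)

    def test_cumulative_ablation_covers_six_removals(self, small_synthetic_corpus):
        table = ablate_by_ig(small_synthetic_corpus, FAST_PIPE, k=2, seed=1)
        # seven groups; the last removal would empty the feature set unless
        # it still leaves columns, so at most 7 removals after the full row
        assert 6 <= len(table) - 1 <= 7
        assert table.loc[1:, "group_ig"].is_monotonic_increasing

    def test_single_group_mode_removes_one_group_per_row(
        self, small_synthetic_corpus
    ):
        table = ablate_by_ig(
            small_synthetic_corpus, FAST_PIPE, k=2, seed=1, cumulative=False
        )
        removed = set(table.loc[1:, "removed"])
        assert "linker_index" in removed and "polarity" in removed
        assert all("+" not in r for r in removed)


class TestMetricsFromCounts:
    def test_all_metrics_in_unit_interval(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            c = ConfusionCounts(*rng.integers(0, 100, 4))
            ac, r, p, f1, _ = metrics_from_counts(c)
            for v in (ac, r, p, f1):
                assert 0.0 <= v <= 1.0
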