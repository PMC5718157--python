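"""Welch t-test, ROC/AUC, threshold diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as scipy_stats

import dopplerwss as dw


def mann_whitney_auc(scores, labels, direction):
    """Brute-force pairwise oracle: P(pos more disease-like than neg) + 1/2 ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = ties = 0
    for p in pos:
        for n in neg:
            beat = p < n if direction == "low_positive" else p > n
            wins += beat
            ties += p == n
    return (wins + 0.5 * ties) / (pos.size * neg.size)


class TestWelch:
    def test_identical_samples(self):
        r = dw.welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == 0.0
        assert r.p == pytest.approx(1.0)

    def test_total_separation(self):
        r = dw.welch_t_test([1, 2, 3], [11, 12, 13])
        assert r.p < 0.001
        assert r.t < 0

    def test_sign_flips_on_swap(self):
        a, b = [1.0, 2.0, 4.0], [5.0, 6.0, 9.0]
        r1 = dw.welch_t_test(a, b)
        r2 = dw.welch_t_test(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            a = rng.normal(0, 1, rng.integers(2, 30))
            b = rng.normal(0.3, 2, rng.integers(2, 30))
            mine = dw.welch_t_test(a, b)
            ref = scipy_stats.ttest_ind(a, b, equal_var=False)
            assert mine.t == pytest.approx(ref.statistic, abs=1e-10)
            assert mine.p == pytest.approx(ref.pvalue, abs=1e-10)
            assert mine.df == pytest.approx(ref.df, abs=1e-10)

    def test_pooled_variant_matches_reference(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 12)
        b = rng.normal(1, 1, 15)
        mine = dw.welch_t_test(a, b, pooled=True)
        ref = scipy_stats.ttest_ind(a, b, equal_var=True)
        assert mine.t == pytest.approx(ref.statistic, abs=1e-10)
        assert mine.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_variance_conventions(self):
        r = dw.welch_t_test([2.0, 2.0], [2.0, 2.0])
        assert r.p == 1.0
        with pytest.raises(ValueError):
            dw.welch_t_test([2.0, 2.0], [3.0, 3.0])
        with pytest.raises(ValueError):
            dw.welch_t_test([1.0], [1.0, 2.0])

    def test_study_week1_group_difference(self):
        # groups drawn at the published week-1 WSS summaries separate strongly
        rng = np.random.default_rng(12)
        a = rng.normal(1.90, 0.31, 20)
        b = rng.normal(2.54, 0.09, 20)
        assert dw.welch_t_test(a, b).p < 0.01


class TestROC:
    def test_perfect_separation(self):
        scores = [1.0, 1.2, 3.0, 3.5]
        labels = [True, True, False, False]
        roc = dw.roc_curve(scores, labels, "low_positive")
        assert roc.auc == 1.0
        thr = dw.youden_optimal_threshold(roc)
        sens, spec = dw.threshold_performance(scores, labels, thr, "low_positive")
        assert sens + spec - 1 == pytest.approx(1.0)

    def test_interleaved_pairs_value(self):
        # pos {1, 3}, neg {2, 4}, high_positive:
        # pairs (1,2)(1,4)(3,4) lose, (3,2) wins -> AUC 0.25
        roc = dw.roc_curve([1, 3, 2, 4], [1, 1, 0, 0], "high_positive")
        assert roc.auc == 0.25

    def test_direction_swap_mirrors_auc(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=60)
        labels = rng.random(60) < 0.4
        a1 = dw.roc_curve(scores, labels, "low_positive").auc
        a2 = dw.roc_curve(scores, labels, "high_positive").auc
        assert a1 + a2 == pytest.approx(1.0)

    def test_random_labels_auc_near_half(self):
        rng = np.random.default_rng(15)
        n = 4000
        scores = rng.normal(size=n)
        labels = rng.random(n) < 0.5
        roc = dw.roc_curve(scores, labels, "low_positive")
        n_pos = labels.sum()
        n_neg = n - n_pos
        se = np.sqrt((n_pos + n_neg + 1) / (12 * n_pos * n_neg))
        assert abs(roc.auc - 0.5) <= 3 * se

    def test_monotone_sens_spec_tradeoff(self):
        rng = np.random.default_rng(21)
        scores = np.round(rng.normal(size=80), 1)  # force ties
        labels = scores + rng.normal(scale=1.0, size=80) < 0
        roc = dw.roc_curve(scores, labels, "low_positive")
        assert np.all(np.diff(roc.sens) >= 0)  # loosening the cut only adds calls
        assert np.all(np.diff(roc.spec) <= 0)

    def test_auc_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(31)
        scores = rng.normal(size=50)
        labels = rng.random(50) < 0.5
        a1 = dw.roc_curve(scores, labels, "low_positive").auc
        a2 = dw.roc_curve(np.exp(scores), labels, "low_positive").auc
        assert a1 == a2

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        st.lists(st.integers(0, 9), min_size=2, max_size=30),
        st.data(),
    )
    def test_auc_equals_pairwise_oracle(self, score_ints, data):
        n = len(score_ints)
        labels = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n).filter(
                lambda ls: any(ls) and not all(ls)
            )
        )
        scores = np.asarray(score_ints, dtype=float) / 2.0
        for direction in ("low_positive", "high_positive"):
            roc = dw.roc_curve(scores, labels, direction)
            assert roc.auc == mann_whitney_auc(scores, labels, direction)

    def test_matches_sklearn_cross_check(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(44)
        for _ in range(10):
            scores = np.round(rng.normal(size=40), 1)
            labels = (scores + rng.normal(scale=2, size=40)) > 0
            if labels.all() or not labels.any():
                continue
            mine = dw.roc_curve(scores, labels, "high_positive").auc
            ref = roc_auc_score(labels, scores)
            assert mine == pytest.approx(ref, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            dw.roc_curve([1.0, 2.0], [True, True])


class TestThresholdPerformance:
    def test_extreme_thresholds(self):
        scores = [1.0, 2.0, 3.0]
        labels = [True, False, True]
        assert dw.threshold_performance(scores, labels, 0.5, "low_positive") == (0.0, 1.0)
        assert dw.threshold_performance(scores, labels, 9.0, "low_positive") == (1.0, 0.0)

    def test_published_style_operating_point(self):
        # diseased WSS {1.0, 1.1}, healthy {2.0}: threshold 1.198 separates
        sens, spec = dw.threshold_performance(
            [1.0, 1.1, 2.0], [True, True, False], 1.198, "low_positive"
        )
        assert (sens, spec) == (1.0, 1.0)

    def test_consistency_with_roc_points(self):
        rng = np.random.default_rng(77)
        scores = np.round(rng.normal(size=60), 1)
        labels = (scores + rng.normal(scale=1, size=60)) < 0.3
        for direction in ("low_positive", "high_positive"):
            roc = dw.roc_curve(scores, labels, direction)
            for i, t in enumerate(roc.thresholds):
                sens, spec = dw.threshold_performance(scores, labels, t, direction)
                assert sens == roc.sens[i]
                assert spec == roc.spec[i]


class TestYouden:
    def test_flat_roc_gives_zero_j(self):
        scores = [1.0, 1.0, 1.0, 1.0]
        labels = [True, False, True, False]
        roc = dw.roc_curve(scores, labels, "low_positive")
        thr = dw.youden_optimal_threshold(roc)
        sens, spec = dw.threshold_performance(scores, labels, thr, "low_positive")
        assert sens + spec - 1 == pytest.approx(0.0)

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            scores = np.round(rng.normal(size=30), 1)
            labels = (scores + rng.normal(scale=1, size=30)) > 0
            if labels.all() or not labels.any():
                continue
            for direction in ("low_positive", "high_positive"):
                roc = dw.roc_curve(scores, labels, direction)
                best_j = max(
                    sum(dw.threshold_performance(scores, labels, t, direction)) - 1
                    for t in np.unique(scores)
                )
                thr = dw.youden_optimal_threshold(roc)
                sens, spec = dw.threshold_performance(scores, labels, thr, direction)
                assert sens + spec - 1 == pytest.approx(best_j, abs=1e-12)


class TestCohortHelpers:
    def test_compare_groups_matches_direct_test(self):
        df = dw.generate_cohort(dw.CohortSpec(seed=5))
        r = dw.compare_groups(df, "wss", 1)
        sub = df[df.week == 1]
        direct = dw.welch_t_test(
            sub[sub.group == "experimental"].wss_dyne_cm2,
            sub[sub.group == "control"].wss_dyne_cm2,
        )
        assert r.t == direct.t and r.p == direct.p

    def test_stage_binary_labels(self):
        stages = ["normal", "fatty_streak", "fibrous_plaque", "dense_fibrous_plaque"]
        np.testing.assert_array_equal(
            dw.stage_labels_to_binary(stages, "fatty_streak"),
            [False, True, True, True],
        )
        np.testing.assert_array_equal(
            dw.stage_labels_to_binary(stages, "fibrous_plaque"),
            [False, False, True, True],
        )

    def test_cohort_roc_detects_low_wss_disease(self):
        df = dw.generate_cohort(dw.CohortSpec(seed=2))
        labels = dw.stage_labels_to_binary(df.stage, "fatty_streak")
        roc = dw.roc_curve(df.wss_dyne_cm2.to_numpy(), labels, "low_positive")
        assert roc.auc > 0.9  # diseased weeks have clearly lower WSS
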