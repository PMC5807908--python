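"""Ranking criteria: exclusion rules, hand-computed scores, estimator
equivalence with a brute-force oracle, and invariances."""

import collections
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spikedecode as sd
from spikedecode.feature_selection import (
    MIEstimatorConfig,
    discretize,
    relative_importance_scores,
)


def _table(X, baseline, y):
    X = np.asarray(X, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    return sd.FeatureTable(
        X=X,
        baseline_X=baseline,
        y=np.asarray(y),
        feature_ids=[f"f{i}" for i in range(X.shape[1])],
        mode="single-unit",
    )


def brute_force_mi(values, labels, n_bins=10) -> float:
    """Independent plug-in MI: explicit double sum over the joint table.

    I(C;Y) = sum_c sum_y p(c,y) * log2( p(c,y) / (p(c) p(y)) )
    """
    codes = discretize(np.asarray(values, float), MIEstimatorConfig(n_bins=n_bins))
    n = len(labels)
    joint = collections.Counter(zip(codes.tolist(), list(labels)))
    pc = collections.Counter(codes.tolist())
    py = collections.Counter(list(labels))
    total = 0.0
    for (c, y), k in joint.items():
        p_cy = k / n
        total += p_cy * math.log2(p_cy / ((pc[c] / n) * (py[y] / n)))
    return total


class TestWilcoxon:
    def test_unmodulated_feature_excluded(self):
        rng = np.random.default_rng(0)
        base = rng.normal(10, 1, (60, 2))
        X = base.copy()
        X[:, 1] += 5.0  # only feature 1 modulates
        r = sd.rank_wilcoxon(_table(X, base, np.ones(60, dtype=int)))
        assert r.order.tolist() == [1]

    def test_identically_zero_difference_excluded(self):
        X = np.full((30, 1), 7.0)
        r = sd.rank_wilcoxon(_table(X, X.copy(), np.ones(30, dtype=int)))
        assert len(r) == 0

    def test_negative_median_difference_excluded(self):
        """Significant suppression below baseline is not kept."""
        rng = np.random.default_rng(1)
        base = rng.normal(10, 0.5, (80, 1))
        X = base - 4.0
        r = sd.rank_wilcoxon(_table(X, base, np.ones(80, dtype=int)))
        assert len(r) == 0

    def test_planted_shift_ranked_first(self):
        """+5 sp/s planted among 20 null features wins the top rank."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            base = rng.normal(10, 1, (100, 21))
            X = base + rng.normal(0, 1, base.shape)
            X[:, 7] += 5.0
            r = sd.rank_wilcoxon(_table(X, base, np.ones(100, dtype=int)))
            wins += int(len(r) > 0 and r.order[0] == 7)
        assert wins == 20

    def test_scores_non_increasing(self, tiny_table):
        r = sd.rank_wilcoxon(tiny_table)
        if len(r) > 1:
            assert np.all(np.diff(r.scores) <= 0)


class TestRelativeImportance:
    def test_identical_class_means_score_zero(self):
        X = np.tile([[3.0, 5.0]], (12, 1))
        base = np.zeros_like(X)
        y = np.repeat([1, 2, 3], 4)
        scores = relative_importance_scores(_table(X, base, y))
        np.testing.assert_allclose(scores, 0.0, atol=1e-12)

    def test_two_class_hand_computed_score(self):
        """Class means 4 and 10 -> variance about grand mean 7 is 18."""
        X = np.array([[4.0], [4.0], [10.0], [10.0]])
        base = np.zeros_like(X)
        y = np.array([1, 1, 2, 2])
        scores = relative_importance_scores(_table(X, base, y))
        assert scores[0] == pytest.approx(((4 - 7) ** 2 + (10 - 7) ** 2) / (2 - 1))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            relative_importance_scores(
                _table(np.ones((4, 1)), np.zeros((4, 1)), [1, 1, 1, 1])
            )

    def test_tuned_unit_outranks_untuned(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            y = np.repeat([1, 2, 3], 30)
            base = rng.normal(10, 1, (90, 6))
            X = base + rng.normal(0, 1, base.shape)
            X[:, 2] += 4.0 * (y - 2)  # strong class-dependent modulation
            scores = relative_importance_scores(_table(X, base, y))
            wins += int(np.argmax(scores) == 2)
        assert wins >= 20 * 0.99


class TestMutualInformation:
    def test_deterministic_function_of_labels(self):
        """A feature that is a deterministic function of 11 equiprobable
        labels carries exactly log2(11) bits."""
        y = np.repeat(np.arange(11), 20)
        values = y * 3.7 - 5.0
        mi = sd.mutual_information(values, y, MIEstimatorConfig(n_bins=11))
        assert mi == pytest.approx(np.log2(11), abs=1e-12)

    def test_bounded_by_marginal_entropies(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 4, 200)
        v = rng.normal(size=200)
        mi = sd.mutual_information(v, y)
        h_y = -sum(p * np.log2(p) for p in np.bincount(y) / 200 if p > 0)
        assert 0.0 <= mi <= h_y + 1e-12

    def test_independent_feature_below_permutation_null(self):
        rng = np.random.default_rng(4)
        y = np.repeat(np.arange(5), 60)
        v = rng.normal(size=300)
        mi = sd.mutual_information(v, y)
        null = [
            sd.mutual_information(v, rng.permutation(y)) for _ in range(200)
        ]
        assert mi < np.quantile(null, 0.95)

    def test_fewer_samples_than_bins_rejected(self):
        with pytest.raises(ValueError):
            sd.mutual_information(np.arange(5), np.arange(5), MIEstimatorConfig(n_bins=10))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        n=st.integers(12, 60),
        n_classes=st.integers(2, 5),
        seed=st.integers(0, 10_000),
    )
    def test_matches_brute_force_double_sum(self, n, n_classes, seed):
        """Plug-in estimator equals the explicit double-sum oracle."""
        rng = np.random.default_rng(seed)
        v = rng.normal(size=n) + rng.integers(0, 2, n) * rng.uniform(0, 3)
        y = rng.integers(0, n_classes, n)
        mi = sd.mutual_information(v, y)
        assert mi == pytest.approx(brute_force_mi(v, y), abs=1e-12)


class TestRankMim:
    def test_perfectly_coupled_feature_first(self):
        rng = np.random.default_rng(5)
        y = np.repeat(np.arange(4), 25)
        X = rng.normal(size=(100, 5))
        X[:, 3] = y.astype(float)
        r = sd.rank_mim(_table(X, np.zeros_like(X), y))
        assert r.order[0] == 3

    def test_ranking_deterministic(self, tiny_table):
        a = sd.rank_mim(tiny_table)
        b = sd.rank_mim(tiny_table)
        assert a.order.tolist() == b.order.tolist()
        np.testing.assert_array_equal(a.scores, b.scores)


class TestPCA:
    def test_dominant_coordinate_recovered(self):
        rng = np.random.default_rng(6)
        X = np.zeros((50, 3))
        X[:, 0] = rng.normal(0, 10, 50)
        X[:, 1:] = rng.normal(0, 0.01, (50, 2))
        r = sd.rank_pca(_table(X, np.zeros_like(X), np.ones(50, dtype=int)))
        loading = np.abs(r.transform.components_[0])
        assert np.argmax(loading) == 0
        assert r.scores[0] > 0.99

    def test_explained_fractions_sum_to_one(self, tiny_table):
        r = sd.rank_pca(tiny_table)
        assert np.sum(r.scores) == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(r.scores) <= 1e-12)

    def test_component_scores_uncorrelated(self, tiny_table):
        r = sd.rank_pca(tiny_table)
        Z = r.transform.transform(tiny_table.X)
        cov = np.cov(Z.T)
        off = cov - np.diag(np.diag(cov))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(cov))

    def test_zero_variance_rejected(self):
        X = np.ones((10, 3))
        with pytest.raises(ValueError):
            sd.rank_pca(_table(X, X.copy(), np.ones(10, dtype=int)))


class TestRandom:
    def test_reproducible_and_complete(self, tiny_table):
        a = sd.rank_random(tiny_table, seed=42)
        b = sd.rank_random(tiny_table, seed=42)
        assert a.order.tolist() == b.order.tolist()
        assert sorted(a.order.tolist()) == list(range(tiny_table.n_features))

    def test_first_position_uniform(self, tiny_table):
        """Each feature leads the permutation with frequency ~ 1/p."""
        p = tiny_table.n_features
        firsts = [sd.rank_random(tiny_table, seed=s).order[0] for s in range(5000)]
        counts = np.bincount(firsts, minlength=p)
        from scipy.stats import chisquare

        _, pval = chisquare(counts)
        assert pval > 0.001


class TestInvariances:
    @pytest.mark.parametrize("method", ["wilcoxon", "relative_importance", "mim"])
    def test_row_order_invariance(self, tiny_table, method):
        rng = np.random.default_rng(9)
        perm = rng.permutation(tiny_table.n_trials)
        shuffled = tiny_table.select_rows(perm)
        a = sd.rank_features(tiny_table, method, seed=0)
        b = sd.rank_features(shuffled, method, seed=0)
        assert a.order.tolist() == b.order.tolist()

    @pytest.mark.parametrize("method", ["wilcoxon", "relative_importance", "mim"])
    def test_column_order_invariance_up_to_relabeling(self, tiny_table, method):
        p = tiny_table.n_features
        rng = np.random.default_rng(10)
        perm = rng.permutation(p)
        permuted = tiny_table.select_columns(perm)
        a = sd.rank_features(tiny_table, method, seed=0)
        b = sd.rank_features(permuted, method, seed=0)
        # map permuted-table column indices back to original labels
        back = [perm[i] for i in b.order]
        # scores may tie; compare as score-sorted label sets per score value
        assert sorted(back) == sorted(a.order.tolist())
        np.testing.assert_allclose(np.sort(a.scores), np.sort(b.scores), atol=1e-12)
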