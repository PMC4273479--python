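"""CFS feature selection, Naïve Bayes CV, F-score, ward.D clustering."""

import numpy as np
import pytest

from aluscancnv.classify import (
    _ward_d_linkage,
    best_first_select,
    cfs_merit,
    f_score,
    hier_cluster,
    naive_bayes_cv,
    symmetrical_uncertainty,
)


def make_cohort(n_per_class=20, n_signal=10, n_noise=2000, pen_hi=0.9, pen_lo=0.1,
                noise_rate=0.1, seed=0):
    """Two-class binary CNV feature table with injected class-associated windows."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    y = np.repeat([0, 1], n_per_class)
    X = (rng.random((n, n_signal + n_noise)) < noise_rate).astype(float)
    for j in range(n_signal):
        pen = np.where(y == 1, pen_hi, pen_lo)
        X[:, j] = (rng.random(n) < pen).astype(float)
    return X, y.astype(float)


class TestSymmetricalUncertainty:
    def test_perfect_dependence_is_one(self):
        x = np.array([0, 0, 1, 1, 0, 1], float)
        assert symmetrical_uncertainty(x, x)[0] == pytest.approx(1.0)

    def test_constant_feature_is_zero(self):
        x = np.array([0, 1, 0, 1], float)
        assert symmetrical_uncertainty(x, np.ones(4))[0] == 0.0

    def test_independent_bits_near_zero(self):
        rng = np.random.default_rng(1)
        x = (rng.random(5000) < 0.5).astype(float)
        z = (rng.random(5000) < 0.5).astype(float)
        assert symmetrical_uncertainty(x, z)[0] < 0.01


class TestCFSMerit:
    def test_singleton_merit_is_class_correlation(self):
        X, y = make_cohort(seed=2)
        su = symmetrical_uncertainty(y, X[:, [0]])[0]
        assert cfs_merit([0], X, y) == pytest.approx(su)

    def test_duplicate_feature_never_increases_merit(self):
        X, y = make_cohort(seed=3)
        X2 = np.column_stack([X[:, 0], X[:, 0]])
        single = cfs_merit([0], X2, y)
        double = cfs_merit([0, 1], X2, y)
        assert double <= single + 1e-12

    def test_class_independent_feature_contributes_nothing(self):
        rng = np.random.default_rng(4)
        y = np.repeat([0.0, 1.0], 500)
        noise = (rng.random(1000) < 0.5).astype(float)
        X = np.column_stack([y, noise])  # feature 0 perfect, feature 1 junk
        assert cfs_merit([0], X, y) == pytest.approx(1.0)
        assert cfs_merit([1], X, y) < 0.01


class TestBestFirstSelect:
    def test_perfect_feature_among_noise_selected(self):
        rng = np.random.default_rng(5)
        y = np.repeat([0.0, 1.0], 20)
        X = (rng.random((40, 200)) < 0.2).astype(float)
        X[:, 57] = y
        selected = best_first_select(X, y)
        assert 57 in selected

    def test_all_noise_selects_small_fraction(self):
        # CFS merit grows ~ c*sqrt(k) for weak near-independent features, so a
        # pure-noise table still admits a handful of spurious features; the
        # selected set must stay a small fraction of the candidate pool
        rng = np.random.default_rng(6)
        y = np.repeat([0.0, 1.0], 20)
        X = (rng.random((40, 300)) < 0.2).astype(float)
        selected = best_first_select(X, y)
        assert len(selected) <= 30

    def test_duplicated_informative_feature_kept_once(self):
        rng = np.random.default_rng(7)
        y = np.repeat([0.0, 1.0], 25)
        signal = (rng.random(50) < np.where(y == 1, 0.9, 0.1)).astype(float)
        noise = (rng.random((50, 100)) < 0.2).astype(float)
        X = np.column_stack([signal, signal, noise])
        selected = best_first_select(X, y)
        assert not {0, 1}.issubset(selected)

    def test_merit_core_dominated_by_signal_features(self):
        # CFS seeks a minimal non-redundant subset, so it may keep only part
        # of a block of mutually correlated true features — but the
        # merit-optimal core must consist mostly of injected ones
        X, y = make_cohort(seed=8)
        core = best_first_select(X, y, locally_predictive=False)
        injected = set(core) & set(range(10))
        assert len(core) >= 1
        assert len(injected) >= 3
        assert len(injected) >= len(core) / 2


class TestFScore:
    @pytest.mark.parametrize(
        "tp, fp, fn, expected",
        [(5, 0, 0, 1.0), (0, 3, 4, 0.0), (2, 1, 1, 2 * 2 / (2 * 2 + 1 + 1))],
    )
    def test_formula(self, tp, fp, fn, expected):
        assert f_score(tp, fp, fn) == pytest.approx(expected)

    def test_undefined_when_all_zero(self):
        with pytest.raises(ValueError):
            f_score(0, 0, 0)

    def test_hand_counted_value(self):
        assert f_score(2, 1, 1) == pytest.approx(0.6667, abs=1e-4)


class TestNaiveBayesCV:
    def test_perfectly_separable(self):
        y = np.repeat([0, 1], 10)
        X = np.column_stack([y, 1 - y]).astype(float)
        rep = naive_bayes_cv(X, y, iterations=50, seed=0)
        assert rep.auc == pytest.approx(1.0)
        assert rep.f_score == pytest.approx(1.0)

    def test_shuffled_labels_auc_near_half(self):
        X, y = make_cohort(seed=9, n_noise=200)
        rng = np.random.default_rng(9)
        y_perm = rng.permutation(y)
        rep = naive_bayes_cv(X, y_perm.astype(int), features=list(range(10)), iterations=200, seed=1)
        assert abs(rep.auc - 0.5) < 0.12

    def test_deterministic_for_fixed_seed(self):
        X, y = make_cohort(seed=10, n_noise=50)
        a = naive_bayes_cv(X, y.astype(int), features=list(range(10)), iterations=20, seed=3)
        b = naive_bayes_cv(X, y.astype(int), features=list(range(10)), iterations=20, seed=3)
        assert a.auc == b.auc and a.f_score == b.f_score


class TestHierCluster:
    def test_ward_d_heights_match_R_hclust(self):
        # frozen oracle: R> hclust(dist(X), "ward.D")$height for the matrix
        # generated below (same generator, same seed)
        rng = np.random.default_rng(42)
        X = rng.integers(0, 2, size=(8, 12)).astype(float)
        Z = _ward_d_linkage(X)
        expect = [1.732051, 2.0, 2.236068, 2.314757, 2.476753, 2.571592, 3.746626]
        np.testing.assert_allclose(sorted(Z[:, 2]), expect, atol=1e-6)

    def test_two_classes_form_top_level_clusters(self):
        rng = np.random.default_rng(11)
        y = np.repeat([0, 1], 8)
        X = (rng.random((16, 40)) < np.where(y[:, None] == 1, 0.85, 0.15)).astype(float)
        res = hier_cluster(X, n_boot=100, seed=0)
        n = 16
        # the root's two children should match the class split
        top = res.linkage[-1]
        from aluscancnv.classify import _clades

        clades = _clades(res.linkage, n)
        left = clades[int(top[0]) - n] if top[0] >= n else frozenset([int(top[0])])
        assert left in (frozenset(range(8)), frozenset(range(8, 16)))

    def test_identical_samples_merge_first_at_height_zero(self):
        X = np.array([[1, 0, 1], [1, 0, 1], [0, 1, 0], [1, 1, 1]], float)
        Z = _ward_d_linkage(X)
        assert Z[0, 2] == pytest.approx(0.0)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_support_values_are_proportions(self):
        rng = np.random.default_rng(12)
        X = (rng.random((10, 30)) < 0.3).astype(float)
        res = hier_cluster(X, n_boot=50, seed=1)
        assert all(0.0 <= v <= 1.0 for v in res.support.values())
        assert res.newick.endswith(";")

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            hier_cluster(np.zeros((2, 5)), n_boot=10)
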