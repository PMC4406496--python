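import numpy as np
import pandas as pd
import pytest

import nocieeg as ng
from nocieeg.evaluation import TRIALS, LabeledDataset


def brute_force_pk(scores, labels):
    """Direct pair enumeration: concordant + half ties over all pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    r = scores[labels == 1]
    s = scores[labels == 0]
    num = n_pairs = 0.0
    for a in r:
        for b in s:
            n_pairs += 1
            if a > b:
                num += 1
            elif a == b:
                num += 0.5
    return num / n_pairs


class TestMannWhitney:
    def test_exact_separated_groups(self):
        u, p = ng.mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)

    def test_identical_groups(self):
        _, p = ng.mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert p > 0.9

    def test_swap_symmetry(self):
        x, y = [1, 5, 7, 2], [3, 8, 9, 10]
        ux, _ = ng.mann_whitney(x, y)
        uy, _ = ng.mann_whitney(y, x)
        assert ux + uy == len(x) * len(y)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ng.mann_whitney([], [1, 2])


class TestBonferroni:
    def test_cap_at_one(self):
        assert ng.bonferroni([0.01], 300)[0] == 1.0

    def test_arithmetic(self):
        assert ng.bonferroni([1e-4], 300)[0] == pytest.approx(0.03)

    def test_identity_m1(self):
        np.testing.assert_allclose(ng.bonferroni([0.2, 0.7], 1), [0.2, 0.7])


class TestPk:
    def test_perfect_separation(self):
        pk, _ = ng.pk_statistic([1, 2, 3, 4], [0, 0, 1, 1])
        assert pk == 1.0

    def test_tie_counted_half(self):
        pk, _ = ng.pk_statistic([1, 2, 2, 3], [0, 0, 1, 1])
        assert pk == pytest.approx(0.875)

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 200))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.standard_normal(n), 1)  # forces some ties
            pk, _ = ng.pk_statistic(scores, labels)
            assert pk == pytest.approx(brute_force_pk(scores, labels),
                                       abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.standard_normal(100)
        labels = rng.integers(0, 2, 100)
        pk1, _ = ng.pk_statistic(scores, labels)
        pk2, _ = ng.pk_statistic(np.exp(3 * scores), labels)
        assert pk1 == pytest.approx(pk2, abs=1e-12)

    def test_negation_complement(self, rng):
        scores = rng.permutation(200).astype(float)  # no ties
        labels = (np.arange(200) % 2).astype(int)
        pk_pos, _ = ng.pk_statistic(scores, labels)
        pk_neg, _ = ng.pk_statistic(-scores, labels)
        assert pk_pos + pk_neg == pytest.approx(1.0)

    def test_null_centering(self):
        rng = np.random.default_rng(99)
        scores = rng.standard_normal(1000)
        labels = rng.integers(0, 2, 1000)  # independent of scores
        pk, se = ng.pk_statistic(scores, labels)
        assert abs(pk - 0.5) < 0.05
        assert 0 < se < 0.05

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            ng.pk_statistic([1, 2, 3], [1, 1, 1])


class TestDiscriminant:
    def _clouds(self, rng, d=3.0, n=100):
        X0 = rng.standard_normal((n, 2))
        X1 = rng.standard_normal((n, 2)) + d
        X = np.vstack([X0, X1])
        y = np.r_[np.zeros(n, int), np.ones(n, int)]
        return X, y

    def test_separated_clouds_training_accuracy(self, rng):
        X, y = self._clouds(rng)
        model = ng.fit_discriminant(X, y)
        pred = model.predict(X)
        assert np.mean(pred[y == 1] == 1) > 0.95
        assert np.mean(pred[y == 0] == 0) > 0.95

    def test_label_swap_negates_weights(self, rng):
        X, y = self._clouds(rng)
        m1 = ng.fit_discriminant(X, y)
        m2 = ng.fit_discriminant(X, 1 - y)
        np.testing.assert_allclose(m1.weights, -m2.weights, rtol=1e-9)

    def test_single_measure_is_threshold(self, rng):
        X, y = self._clouds(rng)
        x1 = X[:, :1]
        model = ng.fit_discriminant(x1, y)
        cut = model.threshold / model.weights[0]
        np.testing.assert_array_equal(model.predict(x1),
                                      (x1[:, 0] > cut).astype(int))

    def test_matches_sklearn_lda(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X, y = self._clouds(rng, d=1.0)
        ours = ng.fit_discriminant(X, y)
        sk = LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(X, y)
        np.testing.assert_array_equal(ours.predict(X), sk.predict(X))

    def test_constant_measure_rejected(self, rng):
        X = np.column_stack([np.ones(40), rng.standard_normal(40)])
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        with pytest.raises(ValueError):
            ng.fit_discriminant(X, y)


def _dataset_from_arrays(X, y, names=None):
    names = names or [f"f{i}" for i in range(X.shape[1])]
    return LabeledDataset(pd.DataFrame(X, columns=names), y)


class TestLOO:
    def test_separable_data_perfect(self, rng):
        X = np.vstack([rng.standard_normal((30, 2)),
                       rng.standard_normal((30, 2)) + 10])
        y = np.r_[np.zeros(30, int), np.ones(30, int)]
        res = ng.loo_evaluate(_dataset_from_arrays(X, y), ["f0", "f1"])
        assert (res.pk, res.sen, res.spe) == (1.0, 100.0, 100.0)

    def test_null_data_chance_level(self):
        rng = np.random.default_rng(202)
        X = rng.standard_normal((200, 3))
        y = rng.integers(0, 2, 200)
        res = ng.loo_evaluate(_dataset_from_arrays(X, y), ["f0", "f1", "f2"])
        assert 0.4 <= res.pk <= 0.6

    def test_duplication_invariance(self, rng):
        X = np.vstack([rng.standard_normal((40, 2)),
                       rng.standard_normal((40, 2)) + 1.5])
        y = np.r_[np.zeros(40, int), np.ones(40, int)]
        r1 = ng.loo_evaluate(_dataset_from_arrays(X, y), ["f0", "f1"])
        r2 = ng.loo_evaluate(_dataset_from_arrays(np.vstack([X, X]),
                                                  np.r_[y, y]), ["f0", "f1"])
        assert r2.pk == pytest.approx(r1.pk, abs=0.05)

    def test_nan_rows_excluded_pairwise(self, rng):
        X = np.vstack([rng.standard_normal((30, 2)),
                       rng.standard_normal((30, 2)) + 10])
        y = np.r_[np.zeros(30, int), np.ones(30, int)]
        X[0, 0] = np.nan
        res = ng.loo_evaluate(_dataset_from_arrays(X, y), ["f0", "f1"])
        assert res.pk == 1.0


class TestComparePk:
    def test_identical_results(self):
        a = ng.EvalResult(0.8, 0.01, 70, 70, ("x",))
        assert ng.compare_pk(a, a) == pytest.approx(1.0)

    def test_clear_difference(self):
        a = ng.EvalResult(0.9, 0.01, 70, 70, ("x",))
        b = ng.EvalResult(0.5, 0.01, 50, 50, ("y",))
        assert ng.compare_pk(a, b) < 1e-6

    def test_symmetry(self):
        a = ng.EvalResult(0.7, 0.02, 60, 60, ("x",))
        b = ng.EvalResult(0.6, 0.03, 55, 55, ("y",))
        assert ng.compare_pk(a, b) == pytest.approx(ng.compare_pk(b, a))


class TestTrials:
    def test_trial_label_definitions(self):
        rss = lambda v: ng.EventAnnotation(100.0, "RSS", v)
        gag = lambda v: ng.EventAnnotation(100.0, "GAG", v)
        assert TRIALS["trial1"].label(rss(5)) == 1
        assert TRIALS["trial1"].label(rss(6)) == 0
        assert TRIALS["trial1"].label(rss(4)) is None
        assert TRIALS["trial2"].label(rss(2)) == 1
        assert TRIALS["trial3"].label(rss(5)) == 0
        assert TRIALS["trial4"].label(rss(4)) == 1
        assert TRIALS["trial5"].label(rss(5)) == 0
        assert TRIALS["gag"].label(gag(1)) == 1
        assert TRIALS["gag"].label(rss(5)) is None


class TestSubsetSearch:
    def _noise_dataset(self, seed=5, n=60, p=8):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, p))
        y = rng.integers(0, 2, n)
        return _dataset_from_arrays(X, y)

    def test_deterministic_given_seed(self, dataset_strong=None):
        rng = np.random.default_rng(17)
        X = np.vstack([rng.standard_normal((50, 6)),
                       rng.standard_normal((50, 6))
                       + np.r_[1.5, 1.5, np.zeros(4)]])
        y = np.r_[np.zeros(50, int), np.ones(50, int)]
        ds = _dataset_from_arrays(X, y)
        names = list(ds.measures.columns)
        r1 = ng.random_subset_search(ds, candidates=names, n_iter=50, seed=3)
        r2 = ng.random_subset_search(ds, candidates=names, n_iter=50, seed=3)
        assert [k for k, _ in r1] == [k for k, _ in r2]

    def test_all_noise_pool_yields_nothing(self):
        ds = self._noise_dataset()
        names = list(ds.measures.columns)
        ranked = ng.random_subset_search(ds, candidates=names, n_iter=40,
                                         seed=1)
        assert ranked == []

    def test_empty_pool_rejected(self):
        ds = self._noise_dataset()
        with pytest.raises(ValueError):
            ng.random_subset_search(ds, candidates=[], seed=0)

    def test_correlation_constraint_respected(self):
        rng = np.random.default_rng(8)
        base = rng.standard_normal(120)
        shift = np.r_[np.zeros(60), np.full(60, 2.0)]
        X = np.column_stack([base + shift,
                             base + shift + 0.01 * rng.standard_normal(120),
                             rng.standard_normal(120) + shift])
        y = np.r_[np.zeros(60, int), np.ones(60, int)]
        ds = _dataset_from_arrays(X, y)
        ranked = ng.random_subset_search(ds, candidates=["f0", "f1", "f2"],
                                         n_iter=50, seed=2)
        for subset, _ in ranked:
            assert not {"f0", "f1"} <= set(subset)  # near-duplicates


class TestScreening:
    def test_informative_measure_kept_noise_mostly_dropped(self):
        rng = np.random.default_rng(31)
        n = 120
        y = np.r_[np.zeros(60, int), np.ones(60, int)]
        X = rng.standard_normal((n, 5))
        X[:, 0] += 1.5 * y
        ds = _dataset_from_arrays(X, y)
        kept = ng.screen_measures([ds])
        assert "f0" in kept
        assert len(kept) < 5
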