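import numpy as np
import pytest
from scipy import stats as sps

from neuromea.classify import (
    PerceptronSpec,
    chi_square_recognition,
    cross_validate,
    fit_standardizer,
    standardize,
    train_perceptron,
    training_accuracy,
)


class TestStandardize:
    def test_self_reference_gives_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        X = rng.normal(3.0, 2.5, size=(30, 10))
        Z, sc = standardize(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0, ddof=1), 1.0, rtol=1e-12)
        assert sc.n_imputed == 0

    def test_constant_column_dropped_and_logged(self):
        X = np.column_stack([np.arange(10.0), np.full(10, 7.0)])
        Z, sc = standardize(X)
        assert Z.shape == (10, 1)
        assert not sc.kept[1]

    def test_held_out_row_uses_training_statistics(self):
        train = np.array([[0.0], [2.0], [4.0]])
        sc = fit_standardizer(train)
        held = sc.transform(np.array([[6.0]]))
        assert held[0, 0] == pytest.approx((6.0 - 2.0) / 2.0)

    def test_nan_imputed_by_reference_mean(self):
        train = np.array([[1.0], [3.0], [np.nan]])
        sc = fit_standardizer(train)
        assert sc.n_imputed == 1
        assert sc.transform(np.array([[np.nan]]))[0, 0] == pytest.approx(0.0)


class TestPerceptron:
    def test_linearly_separable_reaches_full_accuracy(self):
        rng = np.random.default_rng(1)
        X = np.concatenate([rng.normal(-1, 0.2, 10), rng.normal(1, 0.2, 10)])[:, None]
        y = np.array([0] * 10 + [1] * 10)
        W = train_perceptron(X, y, PerceptronSpec(n_inputs=1, seed=0))
        assert training_accuracy(W, X, y) == 1.0

    def test_separable_204dim_groups_fit_before_max_epochs(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(24, 204))
        X[12:, :20] += 2.0
        y = np.array([0] * 12 + [1] * 12)
        # cross-check separability with an independent linear classifier
        from sklearn.linear_model import LogisticRegression

        ref = LogisticRegression(C=np.inf, max_iter=2000).fit(X, y)
        assert ref.score(X, y) == 1.0
        Z, _ = standardize(X)
        W = train_perceptron(Z, y, PerceptronSpec(seed=0, max_epochs=500))
        assert training_accuracy(W, Z, y) == 1.0

    def test_no_signal_stays_near_chance(self):
        rng = np.random.default_rng(3)
        X = np.tile(rng.normal(size=(1, 20)), (20, 1))  # identical rows
        y = np.array([0] * 10 + [1] * 10)
        accs = [
            training_accuracy(
                train_perceptron(X, y, PerceptronSpec(n_inputs=20, seed=s)), X, y
            )
            for s in range(10)
        ]
        assert abs(np.mean(accs) - 0.5) < 0.1

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(16, 30))
        y = rng.integers(0, 2, 16)
        y[:2] = [0, 1]
        spec = PerceptronSpec(n_inputs=30, seed=11)
        W1 = train_perceptron(X, y, spec)
        W2 = train_perceptron(X, y, spec)
        np.testing.assert_array_equal(W1, W2)


class TestCrossValidate:
    def test_perfect_separation_diagonal_100(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(16, 10))
        X[8:, :] += 10.0
        labels = ["ctrl"] * 8 + ["expo"] * 8
        res = cross_validate(X, labels, PerceptronSpec(n_inputs=10, seed=0))
        np.testing.assert_array_equal(np.diag(res.recognition_pct), [100.0, 100.0])
        assert res.confusion.sum(axis=1).tolist() == [8, 8]

    def test_bit_reproducible(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 15))
        X[10:, :3] += 1.0
        labels = ["a"] * 10 + ["b"] * 10
        r1 = cross_validate(X, labels, PerceptronSpec(n_inputs=15, seed=9))
        r2 = cross_validate(X, labels, PerceptronSpec(n_inputs=15, seed=9))
        np.testing.assert_array_equal(r1.confusion, r2.confusion)
        assert r1.chi2_p == r2.chi2_p

    def test_fold_hygiene_outlier_excluded_from_fold_statistics(self):
        """Standardization inside a fold must not see the held-out sample."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(10, 3))
        X[0] = 1e6  # gross outlier
        sc_full = fit_standardizer(X)
        sc_fold = fit_standardizer(X[1:])  # the fold holding out row 0
        assert abs(sc_fold.mean[0]) < 10.0
        assert sc_full.mean[0] > 1e4

    def test_row_sums_equal_group_sizes(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(15, 5))
        labels = ["a"] * 7 + ["b"] * 8
        res = cross_validate(X, labels, PerceptronSpec(n_inputs=5, seed=1))
        assert res.confusion.sum(axis=1).tolist() == [7, 8]
        np.testing.assert_allclose(res.recognition_pct.sum(axis=1), [100.0, 100.0])


class TestChiSquare:
    def test_exact_chance_counts_give_zero(self):
        stat, p = chi_square_recognition(np.array([[10, 10], [7, 7]]))
        assert stat == 0.0
        assert p == 1.0

    def test_reference_case_matches_scipy(self):
        obs = np.array([[19, 6], [11, 14]])
        stat, p = chi_square_recognition(obs)
        ref_stat = 0.0
        for row in obs:
            r = sps.chisquare(row)
            ref_stat += r.statistic
        ref_p = sps.chi2.sf(ref_stat, 2)
        assert stat == pytest.approx(ref_stat, abs=1e-12)
        assert p == pytest.approx(ref_p, abs=1e-12)

    def test_doubling_counts_doubles_statistic(self):
        obs = np.array([[19, 6], [11, 14]])
        s1, _ = chi_square_recognition(obs)
        s2, _ = chi_square_recognition(2 * obs)
        assert s2 == pytest.approx(2 * s1)

    def test_zero_row_errors(self):
        with pytest.raises(ValueError):
            chi_square_recognition(np.array([[0, 0], [5, 5]]))

    def test_type_i_error_calibration(self):
        """Null rejection rate at alpha=0.05 stays within 5% +/- 3 pp."""
        rng = np.random.default_rng(12345)
        n_sims, rej = 1000, 0
        for _ in range(n_sims):
            a = rng.binomial(50, 0.5)
            b = rng.binomial(50, 0.5)
            _, p = chi_square_recognition(np.array([[a, 50 - a], [b, 50 - b]]))
            rej += p < 0.05
        assert 0.02 <= rej / n_sims <= 0.08
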