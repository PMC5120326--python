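"""Fisher discriminant, QDA log-probabilities, leave-one-out calibration."""

import numpy as np
import pytest
from scipy import stats

from raman_cellstate import ValidationError
from raman_cellstate.dapc import (
    DiscriminantModel,
    classify,
    fit_discriminant,
    lda_score,
    loo_error,
    qda_log_prob,
    qda_posterior,
)


def two_clouds(rng, n=200, delta=(6.0, 0.0), k=2, cov=None):
    cov = np.eye(k) if cov is None else cov
    a = rng.multivariate_normal(np.zeros(k), cov, size=n)
    b = rng.multivariate_normal(np.asarray(delta), cov, size=n)
    X = np.vstack([a, b])
    y = np.array(["naive"] * n + ["activated"] * n)
    return X, y


class TestFitDiscriminant:
    def test_isotropic_clouds_axis_parallel_to_mean_difference(self, rng):
        X, y = two_clouds(rng)
        m = fit_discriminant(X, y)
        d = np.array([6.0, 0.0])
        cos = abs(m.f1 @ d / np.linalg.norm(d))
        assert cos > 0.999

    def test_second_listed_class_has_higher_mean(self, rng):
        X, y = two_clouds(rng)
        m = fit_discriminant(X, y, class_order=("naive", "activated"))
        s = lda_score(m, X)
        assert s[y == "activated"].mean() > s[y == "naive"].mean()

    def test_label_swap_negates_axis_same_decisions(self, rng):
        X, y = two_clouds(rng)
        m1 = fit_discriminant(X, y, class_order=("naive", "activated"))
        m2 = fit_discriminant(X, y, class_order=("activated", "naive"))
        assert np.allclose(m1.f1, -m2.f1, atol=1e-12)
        assert np.array_equal(classify(m1, X), classify(m2, X))

    def test_closed_form_fisher_direction(self):
        # shared anisotropic covariance: w should align with inv(Sigma) @ dmu
        rng = np.random.default_rng(42)
        cov = np.array([[2.0, 0.8], [0.8, 1.0]])
        dmu = np.array([1.5, 0.5])
        X, y = two_clouds(rng, n=2000, delta=tuple(dmu), cov=cov)
        m = fit_discriminant(X, y)
        w_true = np.linalg.solve(cov, dmu)
        cos = abs(m.f1 @ w_true / np.linalg.norm(w_true))
        assert cos > 0.99

    def test_requires_two_classes(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValidationError):
            fit_discriminant(X, ["a"] * 10)
        with pytest.raises(ValidationError):
            fit_discriminant(X, ["a", "b", "c"] * 3 + ["a"])

    def test_priors_are_empirical_fractions(self, rng):
        X, y = two_clouds(rng, n=30)
        X, y = X[:50], y[:50]  # 30 naive, 20 activated
        m = fit_discriminant(X, y)
        assert np.allclose(m.priors, [0.6, 0.4])


class TestScoresAndClassification:
    def test_class_mean_projects_to_stored_projection(self, rng):
        X, y = two_clouds(rng)
        m = fit_discriminant(X, y)
        assert lda_score(m, m.means[0]) == pytest.approx(float(m.means[0] @ m.f1))

    def test_orthogonal_input_projects_to_zero(self, rng):
        X, y = two_clouds(rng)
        m = fit_discriminant(X, y)
        v = rng.normal(size=2)
        v -= (v @ m.f1) * m.f1
        assert lda_score(m, v) == pytest.approx(0.0, abs=1e-10)

    def test_batch_equals_per_row_loop(self, rng):
        X, y = two_clouds(rng, n=20)
        m = fit_discriminant(X, y)
        batch = lda_score(m, X)
        loop = [sum(X[i, j] * m.f1[j] for j in range(2)) for i in range(X.shape[0])]
        assert np.allclose(batch, loop, atol=1e-12)

    def test_training_means_classify_to_own_class(self, rng):
        X, y = two_clouds(rng)
        m = fit_discriminant(X, y, class_order=("naive", "activated"))
        assert classify(m, m.means[0]) == "naive"
        assert classify(m, m.means[1]) == "activated"

    def test_threshold_tie_goes_to_first_listed_with_equal_priors(self):
        m = DiscriminantModel(
            class_names=("naive", "activated"),
            f1=np.array([1.0, 0.0]),
            threshold=0.5,
            means=np.array([[0.0, 0.0], [1.0, 0.0]]),
            covs=np.stack([np.eye(2), np.eye(2)]),
            priors=np.array([0.5, 0.5]),
        )
        x = np.array([0.5, 3.0])  # exactly on the threshold along f1
        assert lda_score(m, x) == 0.5
        assert classify(m, x) == "naive"
        # higher prior wins the tie when priors differ
        m.priors = np.array([0.3, 0.7])
        assert classify(m, x) == "activated"

    def test_agrees_with_nearest_class_mean_rule_on_separable_data(self, rng):
        X, y = two_clouds(rng, n=100, delta=(8.0, 3.0))
        m = fit_discriminant(X, y)
        s = lda_score(m, X)
        mu_proj = m.means @ m.f1
        nearest = np.array(
            [m.class_names[int(np.argmin(np.abs(mu_proj - v)))] for v in s]
        )
        assert np.array_equal(classify(m, X), nearest)

    def test_rotation_invariance_of_lda_scores(self, rng):
        X, y = two_clouds(rng, n=150, k=3, delta=(4.0, 1.0, 0.0), cov=np.eye(3))
        m1 = fit_discriminant(X, y, class_order=("naive", "activated"))
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        m2 = fit_discriminant(X @ Q, y, class_order=("naive", "activated"))
        s1, s2 = lda_score(m1, X), lda_score(m2, X @ Q)
        assert np.allclose(np.abs(s1), np.abs(s2), atol=1e-8)


class TestQDA:
    def make_model(self, mu_a, mu_b, cov_a=None, cov_b=None, priors=(0.5, 0.5)):
        k = len(mu_a)
        return DiscriminantModel(
            class_names=("naive", "activated"),
            f1=np.eye(k)[0],
            threshold=0.0,
            means=np.vstack([mu_a, mu_b]),
            covs=np.stack([np.eye(k) if cov_a is None else cov_a,
                           np.eye(k) if cov_b is None else cov_b]),
            priors=np.asarray(priors, dtype=float),
        )

    def test_identical_class_stats_give_equal_log_probs(self, rng):
        mu = rng.normal(size=3)
        m = self.make_model(mu, mu)
        x = rng.normal(size=3)
        lp = qda_log_prob(m, x)
        assert lp[0] == pytest.approx(lp[1], abs=1e-12)

    def test_closed_form_log_ratio_at_class_mean(self):
        # identity covariances, equal priors, |dmu| = 4:
        # logP_A - logP_B at mu_A equals ||dmu||^2 / 2 = 8
        mu_a = np.zeros(2)
        mu_b = np.array([4.0, 0.0])
        m = self.make_model(mu_a, mu_b)
        lp = qda_log_prob(m, mu_a)
        assert lp[0] - lp[1] == pytest.approx(8.0, abs=1e-12)

    def test_matches_independent_cholesky_density(self, rng):
        # hand-coded Gaussian log-density via Cholesky solve as oracle
        A = rng.normal(size=(3, 3))
        cov = A @ A.T + 3 * np.eye(3)
        mu = rng.normal(size=3)
        m = self.make_model(mu, mu + 1.0, cov_a=cov, cov_b=np.eye(3), priors=(0.3, 0.7))
        x = rng.normal(size=3)

        L = np.linalg.cholesky(cov)
        z = np.linalg.solve(L, x - mu)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        oracle = -0.5 * (3 * np.log(2 * np.pi) + logdet + z @ z) + np.log(0.3)
        assert qda_log_prob(m, x)[0] == pytest.approx(oracle, abs=1e-9)

    def test_posteriors_sum_to_one(self, rng):
        m = self.make_model(np.zeros(2), np.ones(2))
        P = qda_posterior(m, rng.normal(size=(40, 2)))
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_equal_covariances_match_lda_threshold_rule(self, rng):
        X, y = two_clouds(rng, n=300, delta=(3.0, 1.0))
        m = fit_discriminant(X, y, class_order=("naive", "activated"))
        m.covs[1] = m.covs[0]  # force shared covariance, keep equal priors
        m.priors = np.array([0.5, 0.5])
        pts = rng.normal(scale=3.0, size=(500, 2)) + np.array([1.5, 0.5])
        qda_pick = np.array(
            [m.class_names[int(np.argmax(qda_log_prob(m, p)))] for p in pts]
        )
        # LDA rule with shared covariance: project on Sigma^-1 dmu direction
        w = np.linalg.solve(m.covs[0], m.means[1] - m.means[0])
        thr = 0.5 * (m.means[0] + m.means[1]) @ w
        lda_pick = np.where(pts @ w > thr, m.class_names[1], m.class_names[0])
        assert np.array_equal(qda_pick, lda_pick)

    def test_non_finite_input_rejected(self):
        m = self.make_model(np.zeros(2), np.ones(2))
        with pytest.raises(ValidationError):
            qda_log_prob(m, np.array([np.nan, 0.0]))


class TestLooError:
    def test_perfectly_separated_data_has_zero_error(self, rng):
        X, y = two_clouds(rng, n=20, delta=(50.0, 0.0))
        assert loo_error(X, y, k=2) == 0.0

    def test_coincident_distributions_near_half(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 10))
        y = np.array(["a"] * 100 + ["b"] * 100)
        err = loo_error(X, y, k=3)
        lo, hi = stats.binom.ppf([0.005, 0.995], 200, 0.5) / 200
        assert lo <= err <= hi

    def test_one_dimensional_bayes_error_calibration(self):
        # equal-variance Gaussians at Mahalanobis separation 2:
        # Bayes error = Phi(-1) ~ 0.1587
        rng = np.random.default_rng(17)
        n = 400
        X = np.concatenate([rng.normal(0, 1, n), rng.normal(2, 1, n)])[:, None]
        y = np.array(["a"] * n + ["b"] * n)
        err = loo_error(X, y, k=1)
        p = stats.norm.cdf(-1.0)
        lo, hi = stats.binom.ppf([0.005, 0.995], 2 * n, p) / (2 * n)
        assert lo <= err <= hi

    def test_error_non_increasing_in_separation(self):
        rng = np.random.default_rng(23)
        errs = []
        n = 150
        for delta in (0.0, 0.5, 1.0, 2.0, 4.0):
            X = np.concatenate([rng.normal(0, 1, n), rng.normal(delta, 1, n)])[:, None]
            y = np.array(["a"] * n + ["b"] * n)
            errs.append(loo_error(X, y, k=1))
        tau = stats.kendalltau(range(5), errs).statistic
        assert tau < 0  # decreasing trend across the sweep
        assert errs[-1] < errs[0]

    def test_fixed_mode_runs_and_bounds(self, rng):
        X, y = two_clouds(rng, n=15, delta=(5.0, 0.0))
        err = loo_error(X, y, k=2, mode="fixed")
        assert 0.0 <= err <= 1.0

    def test_small_or_single_class_inputs_rejected(self, rng):
        X = rng.normal(size=(3, 2))
        with pytest.raises(ValidationError):
            loo_error(X, ["a", "a", "b"], k=1)
        X = rng.normal(size=(6, 2))
        with pytest.raises(ValidationError):
            loo_error(X, ["a"] * 5 + ["b"], k=1)
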