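import numpy as np
import pytest

from kmyouden import (BiomarkerSample, empirical_youden, fit_logistic,
                      fit_minmax, fit_mvn, fit_stepwise, optimal_cutoff)
from kmyouden.comparators import (_coefficient_grid, binormal_optimal_cutpoint)
from scipy.stats import norm


def gaussian_sample(rng, n=400, mu=(1.0, 0.5, 0.0), hetero=False):
    m = len(mu)
    y = np.repeat([1.0, -1.0], n // 2)
    X = rng.standard_normal((n, m))
    if hetero:
        X[y < 0] *= 1.5
    X[y > 0] += np.asarray(mu)
    return BiomarkerSample(X, y)


class TestMVN:
    def test_fisher_direction_under_homoscedasticity(self, rng):
        sample = gaussian_sample(rng, n=4000)
        model = fit_mvn(sample, seed=0)
        Xp, Xn = sample.X[sample.y > 0], sample.X[sample.y < 0]
        pooled = 0.5 * (np.cov(Xp, rowvar=False) + np.cov(Xn, rowvar=False))
        fisher = np.linalg.solve(pooled, Xp.mean(0) - Xn.mean(0))
        fisher /= np.linalg.norm(fisher)
        cos = abs(model.beta @ fisher)
        assert np.degrees(np.arccos(np.clip(cos, -1, 1))) < 5.0

    def test_univariate_reduces_to_binormal_closed_form(self, rng):
        n = 3000
        y = np.repeat([1.0, -1.0], n // 2)
        X = rng.standard_normal((n, 1))
        X[y > 0] = X[y > 0] * 2.0 + 1.0  # unequal variances
        sample = BiomarkerSample(X, y)
        model = fit_mvn(sample, seed=1)
        m1, s1 = X[y > 0].mean(), X[y > 0].std(ddof=1)
        m0, s0 = X[y < 0].mean(), X[y < 0].std(ddof=1)
        expected_c = binormal_optimal_cutpoint(m0, s0, m1, s1)
        # model cutoff lives on the scale beta * x with beta = +-1
        assert model.beta.shape == (1,)
        c = model.cutoff / model.beta[0]
        assert c == pytest.approx(expected_c, abs=1e-3)

    def test_binormal_cutpoint_equal_variances_is_midpoint(self):
        assert binormal_optimal_cutpoint(0.0, 1.0, 2.0, 1.0) == pytest.approx(1.0)

    def test_binormal_cutpoint_maximizes_binormal_J(self):
        m0, s0, m1, s1 = 0.0, 1.0, 1.5, 2.0
        c_star = binormal_optimal_cutpoint(m0, s0, m1, s1)
        J = lambda c: norm.cdf((c - m0) / s0) - norm.cdf((c - m1) / s1)
        grid = np.linspace(-5, 8, 5001)
        assert J(c_star) >= J(grid).max() - 1e-6


class TestMMM:
    def test_max_alone_separates(self, rng):
        n = 60
        y = np.repeat([1.0, -1.0], n // 2)
        X = rng.uniform(0, 1, size=(n, 3))
        X[y > 0, 0] += 5.0  # max feature separates perfectly
        model = fit_minmax(BiomarkerSample(X, y))
        assert model.extras["train_J"] == pytest.approx(1.0)
        assert model.beta[1] == pytest.approx(0.0)

    def test_grid_search_matches_brute_force(self, rng):
        sample = gaussian_sample(rng, n=80)
        model = fit_minmax(sample)
        feats = np.column_stack([sample.X.max(1), sample.X.min(1)])
        best = max(
            optimal_cutoff(sign * feats[:, 0] + g * feats[:, 1], sample.y).J
            for sign in (1.0, -1.0) for g in _coefficient_grid())
        assert model.extras["train_J"] == pytest.approx(best)

    def test_needs_two_markers(self, rng):
        with pytest.raises(ValueError):
            fit_minmax(BiomarkerSample(rng.standard_normal((10, 1)),
                                       np.tile([1.0, -1.0], 5)))


class TestSWM:
    def test_single_informative_marker_first_and_noise_zeroed(self, rng):
        n = 300
        y = np.repeat([1.0, -1.0], n // 2)
        X = rng.standard_normal((n, 3)) * 0.05
        X[y > 0, 1] += 4.0
        model = fit_stepwise(BiomarkerSample(X, y))
        assert model.extras["order"][0] == 1
        assert model.extras["train_J"] == pytest.approx(1.0)
        assert model.beta[1] == 1.0

    def test_single_marker_equals_optimal_cutoff(self, rng):
        n = 50
        y = np.tile([1.0, -1.0], n // 2)
        X = rng.standard_normal((n, 1)) + (y > 0)[:, None]
        sample = BiomarkerSample(X, y)
        model = fit_stepwise(sample)
        ref = optimal_cutoff(X[:, 0], y)
        assert model.extras["train_J"] == pytest.approx(ref.J)
        assert model.cutoff == pytest.approx(ref.cutoff)

    def test_each_step_matches_per_step_brute_force(self, rng):
        sample = gaussian_sample(rng, n=60, mu=(0.8, 0.4))
        model = fit_stepwise(sample)
        order = model.extras["order"]
        grid = _coefficient_grid()
        s = sample.X[:, order[0]]
        for j in order[1:]:
            best_J = max(optimal_cutoff(s + g * sample.X[:, j], sample.y).J
                         for g in grid)
            chosen = model.beta[j]
            got = optimal_cutoff(s + chosen * sample.X[:, j], sample.y).J
            assert got == pytest.approx(best_J)
            s = s + chosen * sample.X[:, j]


class TestLR:
    def test_recovers_bayes_direction_on_symmetric_gaussians(self, rng):
        sample = gaussian_sample(rng, n=6000, mu=(1.0, 0.5, 0.25))
        model = fit_logistic(sample)
        bayes = np.asarray([1.0, 0.5, 0.25])  # equal covariance: beta = mu1 - mu0
        cos = (model.beta @ bayes) / np.linalg.norm(model.beta) / np.linalg.norm(bayes)
        assert np.degrees(np.arccos(np.clip(cos, -1, 1))) < 10.0

    def test_all_noise_markers_near_zero_test_J(self, rng):
        y = np.where(rng.random(300) < 0.5, 1.0, -1.0)
        y[:2] = [1, -1]
        model = fit_logistic(BiomarkerSample(rng.standard_normal((300, 4)), y))
        yt = np.where(rng.random(2000) < 0.5, 1.0, -1.0)
        Xt = rng.standard_normal((2000, 4))
        J = empirical_youden(model.scores(Xt), yt, model.cutoff).J
        assert abs(J) < 0.1

    def test_separable_falls_back_to_ridge_flagged(self):
        X = np.array([[0.0], [0.1], [2.0], [2.1]])
        y = np.array([-1.0, -1.0, 1.0, 1.0])
        model = fit_logistic(BiomarkerSample(X, y))
        assert model.degenerate
        assert np.isfinite(model.beta).all()

    def test_youden_cutoff_option(self, rng):
        sample = gaussian_sample(rng, n=200)
        model = fit_logistic(sample, cutoff="youden")
        ref = optimal_cutoff(model.scores(sample.X), sample.y)
        assert model.cutoff == pytest.approx(ref.cutoff)


def test_internal_consistency_training_J(rng):
    """Each comparator's reported training J equals the empirical Youden of
    its own scores at its own cutoff."""
    sample = gaussian_sample(rng, n=120, hetero=True)
    for fitter in (fit_minmax, fit_stepwise, fit_logistic):
        model = fitter(sample)
        J = empirical_youden(model.scores(sample.X), sample.y, model.cutoff).J
        assert J == pytest.approx(model.extras["train_J"])


def test_marker_reordering_invariance(rng):
    sample = gaussian_sample(rng, n=150, hetero=True)
    perm = [2, 0, 1]
    permuted = BiomarkerSample(sample.X[:, perm], sample.y)
    Xt = np.random.default_rng(0).standard_normal((50, 3))
    # mmm depends only on row max/min, so scores are literally unchanged
    a, b = fit_minmax(sample), fit_minmax(permuted)
    assert np.allclose(a.scores(Xt), b.scores(Xt), atol=1e-8)
    # lr coefficients permute along with the columns
    a, b = fit_logistic(sample), fit_logistic(permuted)
    assert np.allclose(a.scores(Xt), b.scores(Xt[:, perm]), atol=1e-5)
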