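import numpy as np
import pytest

from kmyouden import (BiomarkerSample, KernelSpec, KMEModel, class_weights,
                      empirical_youden, fit_kme, generate_example,
                      objective_value, optimal_cutoff, predict_score)
from kmyouden.kernels import kernel_matrix
from kmyouden.losses import LossSpec, loss_value

from conftest import random_instance


class TestClassWeights:
    def test_balanced(self):
        y = np.repeat([1.0, -1.0], 5)
        assert class_weights(y) == (2.0, 2.0)

    def test_unbalanced(self):
        y = np.array([1.0] * 8 + [-1.0] * 2)
        assert class_weights(y) == (1.25, 5.0)

    def test_normalization_identity(self, rng):
        for _ in range(10):
            y = np.where(rng.random(37) < 0.3, 1.0, -1.0)
            y[:2] = [1, -1]
            w_pos, w_neg = class_weights(y)
            n_pos, n_neg = np.sum(y > 0), np.sum(y < 0)
            assert (n_pos * w_pos + n_neg * w_neg) / len(y) == pytest.approx(2.0)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            class_weights(np.ones(5))


class TestObjective:
    def test_zero_coefficients_give_two(self, rng):
        y = np.where(rng.random(12) < 0.7, 1.0, -1.0)
        y[:2] = [1, -1]
        K = np.eye(12)
        val = objective_value(np.zeros(12), 0.0, K, y, 0.1, 1.0)
        assert val == pytest.approx(2.0)

    def test_large_negative_offset_leaves_negative_losses(self, rng):
        y = np.where(rng.random(12) < 0.5, 1.0, -1.0)
        y[:2] = [1, -1]
        K = np.eye(12)
        # u_i = -y_i c; c << -delta: positive-class losses 0, negatives 1
        val = objective_value(np.zeros(12), -10.0, K, y, 0.1, 1.0)
        assert val == pytest.approx(1.0)

    def test_matches_term_by_term_oracle(self, rng):
        sample = random_instance(rng, n=15)
        K = kernel_matrix(sample.X, sample.X, KernelSpec("linear"))
        a = rng.standard_normal(15) * 0.1
        c, delta, lam = 0.3, 0.1, 0.05
        w_pos, w_neg = class_weights(sample.y)
        total = 0.0
        for i in range(15):
            u_i = sample.y[i] * (sum(a[j] * K[i, j] for j in range(15)) - c)
            w_i = w_pos if sample.y[i] > 0 else w_neg
            total += w_i * loss_value(u_i, LossSpec("psi_delta", delta))
        oracle = total / 15 + 0.5 * lam * a @ K @ a
        assert objective_value(a, c, K, sample.y, delta, lam) == pytest.approx(
            oracle, abs=1e-10)


class TestFitKME:
    def test_two_point_separable(self):
        sample = BiomarkerSample(np.array([[0.0], [1.0]]), np.array([-1.0, 1.0]))
        model = fit_kme(sample, KernelSpec("linear"), lam=1e-3)
        scores = predict_score(model, sample.X)
        assert optimal_cutoff(scores, sample.y).J == pytest.approx(1.0)
        assert empirical_youden(scores, sample.y, model.c).J == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(50))
    def test_dca_descent_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        sample = random_instance(rng, n=25)
        kernel = (KernelSpec("gaussian", tau2=2.0) if seed % 2 else
                  KernelSpec("linear"))
        lam = 10.0 ** rng.uniform(-3, 1)
        model = fit_kme(sample, kernel, lam)
        trace = model.objective_trace
        assert len(trace) >= 1
        assert np.all(np.diff(trace) <= 1e-10)

    def test_large_lambda_degenerates_to_constant_score(self, small_sample):
        model = fit_kme(small_sample, KernelSpec("linear"), lam=1e6)
        scores = predict_score(model, small_sample.X)
        assert np.max(np.abs(scores - scores.mean())) < 1e-4
        assert empirical_youden(scores, small_sample.y, model.c).J == pytest.approx(0.0, abs=1e-9)

    def test_predict_consistent_with_gram_path(self, small_sample):
        model = fit_kme(small_sample, KernelSpec("gaussian", tau2=3.0), lam=0.1)
        K = kernel_matrix(small_sample.X, small_sample.X, model.kernel)
        assert np.allclose(K @ model.a, predict_score(model, small_sample.X))

    def test_predict_zero_coefficients_and_scalar_product(self):
        model = KMEModel(a=np.array([1.0]), c=0.0, X_train=np.array([[2.0]]),
                         kernel=KernelSpec("linear"), lam=1.0, delta=0.1)
        assert predict_score(model, np.array([[3.0]]))[0] == pytest.approx(6.0)
        model.a = np.zeros(1)
        assert predict_score(model, np.array([[3.0]]))[0] == 0.0

    def test_input_validation(self, small_sample):
        with pytest.raises(ValueError):
            fit_kme(small_sample, KernelSpec("linear"), lam=-1.0)
        with pytest.raises(ValueError):
            fit_kme(small_sample, KernelSpec("linear"), lam=0.1, delta=2.0)
        one_class = BiomarkerSample(np.zeros((3, 1)), np.ones(3))
        with pytest.raises(ValueError):
            fit_kme(one_class, KernelSpec("linear"), lam=0.1)
        model = fit_kme(small_sample, KernelSpec("linear"), lam=0.1)
        with pytest.raises(ValueError):
            predict_score(model, np.zeros((2, 99)))


def test_homoscedastic_toy_recovers_sum_direction():
    """Linear-kernel fit on N((1,1), I) vs N((0,0), I): the fitted linear
    combination should align with (1,1)/sqrt(2) within 15 degrees."""
    sample = generate_example("toy_homo", 600, seed=7)
    model = fit_kme(sample, KernelSpec("linear"), lam=0.1)
    beta = sample.X.T @ model.a  # linear kernel: g(x) = (X'a)'x
    beta /= np.linalg.norm(beta)
    target = np.array([1.0, 1.0]) / np.sqrt(2)
    angle = np.degrees(np.arccos(np.clip(beta @ target, -1, 1)))
    assert angle < 15.0


def test_serialization_roundtrip(small_sample):
    model = fit_kme(small_sample, KernelSpec("gaussian", tau2=1.7), lam=0.2)
    clone = KMEModel.from_json(model.to_json())
    assert np.allclose(clone.a, model.a)
    assert clone.c == model.c
    assert clone.kernel == model.kernel
    X_new = small_sample.X[:5] + 0.1
    assert np.allclose(predict_score(clone, X_new), predict_score(model, X_new))
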