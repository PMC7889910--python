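"""Sparse autoencoder core: forward maps, cost terms, gradients, training."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breathcad import ssae
from breathcad.ssae import (AutoencoderParams, FineTuneHyperparams,
                            SAEHyperparams, SSAEClassifier, SSAEModel,
                            SoftmaxHyperparams, SoftmaxParams,
                            average_activation, decode, encode, fine_tune,
                            finetune_cost_grad, kl_divergence, predict,
                            sae_cost, sae_gradient, softmax_cost_grad,
                            softmax_predict, stack_train, train_sae,
                            train_softmax, weight_decay_term)


def _params(d, h, seed=0, scale=1.0):
    rng = np.random.default_rng(seed)
    return AutoencoderParams(W=scale * rng.normal(size=(h, d)),
                             b=scale * rng.normal(size=h),
                             W_dec=scale * rng.normal(size=(d, h)),
                             b_dec=scale * rng.normal(size=d))


def _flatten(p: AutoencoderParams):
    return np.concatenate([p.W.ravel(), p.b, p.W_dec.ravel(), p.b_dec])


def _unflatten(v, d, h):
    W = v[:h * d].reshape(h, d)
    b = v[h * d:h * d + h]
    W_dec = v[h * d + h:h * d + h + d * h].reshape(d, h)
    b_dec = v[-d:]
    return AutoencoderParams(W, b, W_dec, b_dec)


def numeric_gradient(cost_fn, v0, step=1e-5):
    """Central finite differences of a scalar cost over a flat parameter vector."""
    grad = np.zeros_like(v0)
    for i in range(v0.size):
        up, down = v0.copy(), v0.copy()
        up[i] += step
        down[i] -= step
        grad[i] = (cost_fn(up) - cost_fn(down)) / (2 * step)
    return grad


def rel_error(a, b):
    return np.linalg.norm(a - b) / max(1e-12, np.linalg.norm(a) + np.linalg.norm(b))


class TestForwardMaps:
    def test_zero_params_give_half(self):
        p = AutoencoderParams(np.zeros((3, 4)), np.zeros(3), np.zeros((4, 3)), np.zeros(4))
        np.testing.assert_allclose(encode(np.ones(4), p), 0.5)
        np.testing.assert_allclose(decode(np.ones(3), p), 0.5)

    def test_bias_saturation(self):
        p = AutoencoderParams(np.zeros((2, 3)), np.array([10.0, -10.0]),
                              np.zeros((3, 2)), np.zeros(3))
        z = encode(np.zeros(3), p)
        assert z[0] > 0.999 and z[1] < 0.001

    def test_scalar_evaluations(self):
        p = AutoencoderParams(W=np.array([[1.0, 1.0]]), b=np.zeros(1),
                              W_dec=np.array([[2.0], [0.0]]), b_dec=np.array([-1.0, 0.0]))
        z = encode(np.array([0.5, 0.5]), p)
        assert z[0] == pytest.approx(0.7310585786300049, abs=1e-12)  # sigmoid(1)
        xhat = decode(np.array([0.5]), p)
        assert xhat[0] == pytest.approx(0.5, abs=1e-12)  # sigmoid(0)

    def test_reconstruction_finite(self, rng):
        p = _params(6, 3)
        x = rng.normal(size=(5, 6)) * 100
        out = decode(encode(x, p), p)
        assert np.all(np.isfinite(out)) and np.all((out > 0) & (out < 1))

    def test_dimension_mismatch(self):
        p = _params(4, 2)
        with pytest.raises(ValueError):
            encode(np.zeros(5), p)
        with pytest.raises(ValueError):
            decode(np.zeros(3), p)


class TestAverageActivation:
    def test_single_sample(self, rng):
        p = _params(4, 3)
        x = rng.uniform(size=4)
        np.testing.assert_allclose(average_activation(x, p), encode(x, p))

    def test_arithmetic_mean_and_zero_params(self):
        p = AutoencoderParams(np.zeros((2, 3)), np.zeros(2), np.zeros((3, 2)), np.zeros(3))
        np.testing.assert_allclose(average_activation(np.zeros((7, 3)), p), 0.5)

    def test_empty_batch_errors(self):
        with pytest.raises(ValueError):
            average_activation(np.zeros((0, 3)), _params(3, 2))


class TestKLDivergence:
    def test_zero_at_equality(self):
        assert kl_divergence(0.05, 0.05) == pytest.approx(0.0, abs=1e-12)

    def test_frozen_values(self):
        # 0.5*ln 2 + 0.5*ln(2/3) and 0.9*ln 19, from the closed form
        assert kl_divergence(0.5, 0.25) == pytest.approx(0.1438410362258904, abs=1e-12)
        assert kl_divergence(0.05, 0.95) == pytest.approx(0.9 * math.log(19.0), abs=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(p=st.floats(0.01, 0.99), r=st.floats(0.01, 0.99))
    def test_nonnegative(self, p, r):
        assert kl_divergence(p, r) >= -1e-15

    def test_strictly_increasing_away_from_target(self):
        p = 0.05
        right = [kl_divergence(p, r) for r in np.linspace(0.05, 0.95, 40)]
        left = [kl_divergence(p, r) for r in np.linspace(0.05, 0.01, 10)]
        assert all(np.diff(right) > 0) and all(np.diff(left) > 0)

    def test_boundary_arguments_clamped(self):
        assert np.isfinite(kl_divergence(0.05, 1.0))
        assert np.isfinite(kl_divergence(0.05, 0.0))


class TestCost:
    def test_weight_decay_term(self):
        assert weight_decay_term(np.zeros((3, 3))) == 0.0
        assert weight_decay_term(np.eye(2)) == 2.0
        assert weight_decay_term(np.array([[1.0, 2.0], [3.0, 4.0]])) == 30.0

    def test_component_isolation(self, rng):
        d, h = 4, 3
        p = _params(d, h, seed=1)
        X = rng.uniform(0.1, 0.9, size=(6, d))
        beta = 0.37
        hyper = SAEHyperparams(hidden_size=h, sparsity_weight=0.0, weight_decay=beta)
        _, (recon, sparsity, decay) = sae_cost(X, p, hyper)
        assert sparsity == 0.0
        assert decay == pytest.approx(beta * (np.sum(p.W**2) + np.sum(p.W_dec**2)),
                                      rel=1e-12)

    def test_decomposition_sums_to_total(self, rng):
        p = _params(5, 4, seed=2)
        X = rng.uniform(size=(8, 5))
        hyper = SAEHyperparams(hidden_size=4, sparsity_weight=4.0, weight_decay=0.01)
        total, comps = sae_cost(X, p, hyper)
        assert total == pytest.approx(sum(comps), abs=1e-12)

    def test_independent_single_formula_oracle(self, rng):
        # one-expression re-evaluation of the objective, no shared code path
        from scipy.special import expit
        d, h, n = 6, 4, 5
        p = _params(d, h, seed=3)
        X = rng.uniform(size=(n, d))
        sw, beta, rho0 = 4.0, 0.02, 0.05
        A = expit(X @ p.W.T + p.b)
        Xhat = expit(A @ p.W_dec.T + p.b_dec)
        rho = A.mean(0)
        expected = (0.5 * np.sum((X - Xhat) ** 2) / n
                    + sw * np.sum(rho0 * np.log(rho0 / rho)
                                  + (1 - rho0) * np.log((1 - rho0) / (1 - rho)))
                    + beta * (np.sum(p.W**2) + np.sum(p.W_dec**2)))
        hyper = SAEHyperparams(hidden_size=h, sparsity_target=rho0,
                               sparsity_weight=sw, weight_decay=beta)
        total, _ = sae_cost(X, p, hyper)
        assert total == pytest.approx(expected, abs=1e-12)


class TestGradients:
    @pytest.mark.parametrize("seed", range(10))
    def test_sae_gradient_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        d, h, n = int(rng.integers(3, 11)), int(rng.integers(2, 7)), int(rng.integers(2, 6))
        X = rng.uniform(0.05, 0.95, size=(n, d))
        params = _params(d, h, seed=seed + 100, scale=0.5)
        hyper = SAEHyperparams(hidden_size=h,
                               sparsity_target=float(rng.uniform(0.02, 0.2)),
                               sparsity_weight=float(rng.uniform(0, 5)),
                               weight_decay=float(rng.uniform(0, 0.1)))
        analytic = _flatten(sae_gradient(X, params, hyper))
        numeric = numeric_gradient(
            lambda v: sae_cost(X, _unflatten(v, d, h), hyper)[0], _flatten(params))
        assert rel_error(analytic, numeric) < 1e-6

    def test_weight_decay_gradient_linearity(self, rng):
        d, h = 5, 3
        params = _params(d, h, seed=4)
        X = rng.uniform(size=(4, d))
        base = SAEHyperparams(hidden_size=h, sparsity_weight=0.0, weight_decay=0.0)
        g0 = sae_gradient(X, params, base)
        g1 = sae_gradient(X, params, SAEHyperparams(hidden_size=h, sparsity_weight=0.0,
                                                    weight_decay=1.0))
        g2 = sae_gradient(X, params, SAEHyperparams(hidden_size=h, sparsity_weight=0.0,
                                                    weight_decay=2.0))
        np.testing.assert_allclose(g2.W - g0.W, 2 * (g1.W - g0.W), atol=1e-12)

    def test_stationary_at_exact_reconstruction(self):
        # identity-like optimum: 1-d input fixed at 0.5, zero weights reproduce it
        params = AutoencoderParams(np.zeros((1, 1)), np.zeros(1),
                                   np.zeros((1, 1)), np.zeros(1))
        X = np.full((4, 1), 0.5)
        hyper = SAEHyperparams(hidden_size=1, sparsity_weight=0.0, weight_decay=0.0)
        g = sae_gradient(X, params, hyper)
        assert np.linalg.norm(_flatten(g)) < 1e-8


class TestTrainSAE:
    def test_zero_learning_rate_keeps_params(self, rng):
        X = rng.uniform(size=(10, 6))
        hyper = SAEHyperparams(hidden_size=3, learning_rate=0.0, epochs=5, seed=1)
        params, trace = train_sae(X, hyper)
        expected = ssae._glorot_init(6, 3, np.random.default_rng(1))
        np.testing.assert_array_equal(params.W, expected.W)
        assert len(set(trace.total)) == 1  # flat trace

    def test_deterministic_from_seed(self, rng):
        X = rng.uniform(size=(12, 5))
        hyper = SAEHyperparams(hidden_size=3, learning_rate=0.1, epochs=20, seed=9)
        a, _ = train_sae(X, hyper)
        b, _ = train_sae(X, hyper)
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.b_dec, b.b_dec)

    def test_reconstruction_error_halves_on_low_rank_data(self):
        rng = np.random.default_rng(0)
        basis = rng.uniform(-1, 1, size=(2, 8))
        codes = rng.uniform(size=(50, 2))
        X = 1 / (1 + np.exp(-(codes @ basis)))  # rank-2 latent structure
        hyper = SAEHyperparams(hidden_size=2, learning_rate=0.5, epochs=1000,
                               sparsity_weight=0.0, weight_decay=0.0, seed=3)
        _, trace = train_sae(X, hyper)
        assert trace.reconstruction[-1] <= 0.5 * trace.reconstruction[0]

    def test_glorot_init_range(self):
        params = ssae._glorot_init(50, 100, np.random.default_rng(0))
        bound = np.sqrt(6.0 / 150)
        assert np.abs(params.W).max() <= bound
        assert np.all(params.b == 0)


class TestStack:
    def test_code_widths(self, rng):
        X = rng.uniform(size=(20, 50))
        hyper = SAEHyperparams(epochs=2, seed=0)
        layers = stack_train(X, [100, 40], hyper)
        z1 = encode(X, layers[0])
        z2 = encode(z1, layers[1])
        assert z1.shape == (20, 100) and z2.shape == (20, 40)

    def test_single_layer_equals_train_sae(self, rng):
        X = rng.uniform(size=(15, 6))
        hyper = SAEHyperparams(hidden_size=4, epochs=10, seed=5)
        (layer,) = stack_train(X, [4], hyper)
        child = int(np.random.SeedSequence([5, 0]).generate_state(1)[0] % 2**31)
        direct, _ = train_sae(X, SAEHyperparams(hidden_size=4, epochs=10, seed=child))
        np.testing.assert_array_equal(layer.W, direct.W)

    def test_unsupervised_labels_unused(self, rng):
        # stack_train signature takes no labels: permuting them cannot matter
        X = rng.uniform(size=(10, 5))
        a = stack_train(X, [3], SAEHyperparams(epochs=3, seed=1))
        b = stack_train(X, [3], SAEHyperparams(epochs=3, seed=1))
        np.testing.assert_array_equal(a[0].W, b[0].W)


class TestSoftmax:
    def test_uniform_on_equal_logits(self):
        p = SoftmaxParams(np.zeros((3, 4)), np.zeros(3))
        np.testing.assert_allclose(softmax_predict(np.ones(4), p), 1 / 3)

    def test_closed_form_ratios(self):
        p = SoftmaxParams(np.eye(3), np.zeros(3))
        z = np.log([1.0, 2.0, 3.0])
        np.testing.assert_allclose(softmax_predict(z, p), [1 / 6, 2 / 6, 3 / 6],
                                   atol=1e-12)

    def test_shift_invariance(self, rng):
        p = SoftmaxParams(rng.normal(size=(3, 5)), rng.normal(size=3))
        z = rng.normal(size=5)
        a = softmax_predict(z, p)
        p_shifted = SoftmaxParams(p.W, p.b + 7.3)
        np.testing.assert_allclose(softmax_predict(z, p_shifted), a, atol=1e-12)

    def test_gradient_matches_finite_differences(self, rng):
        n, h, C = 6, 4, 3
        Z = rng.uniform(size=(n, h))
        labels = rng.integers(0, C, size=n)
        labels[:3] = [0, 1, 2]
        params = SoftmaxParams(rng.normal(size=(C, h)), rng.normal(size=C))
        _, grad = softmax_cost_grad(Z, labels, params, l2=0.01)
        v0 = np.concatenate([params.W.ravel(), params.b])

        def cost(v):
            p = SoftmaxParams(v[:C * h].reshape(C, h), v[C * h:])
            return softmax_cost_grad(Z, labels, p, l2=0.01)[0]

        numeric = numeric_gradient(cost, v0)
        analytic = np.concatenate([grad.W.ravel(), grad.b])
        assert rel_error(analytic, numeric) < 1e-6

    def test_separable_toy_reaches_perfect_training_accuracy(self):
        rng = np.random.default_rng(2)
        centers = np.array([[0.0, 0.0], [5.0, 0.0], [0.0, 5.0]])
        Z = np.vstack([c + 0.1 * rng.normal(size=(20, 2)) for c in centers])
        labels = np.repeat([0, 1, 2], 20)
        params = train_softmax(Z, labels, SoftmaxHyperparams(epochs=800))
        pred = np.argmax(softmax_predict(Z, params), axis=1)
        assert np.mean(pred == labels) == 1.0

    def test_zero_epochs_uniform_predictions(self, rng):
        Z = rng.uniform(size=(8, 3))
        labels = np.array([0, 1, 2, 0, 1, 2, 0, 1])
        params = train_softmax(Z, labels, SoftmaxHyperparams(epochs=0))
        np.testing.assert_allclose(softmax_predict(Z, params), 1 / 3)

    def test_single_class_errors(self, rng):
        with pytest.raises(ValueError):
            train_softmax(rng.uniform(size=(5, 2)), np.zeros(5, dtype=int))


def _toy_model(d=5, sizes=(4, 3), seed=0):
    rng = np.random.default_rng(seed)
    layers = []
    prev = d
    for h in sizes:
        layers.append(AutoencoderParams(0.5 * rng.normal(size=(h, prev)),
                                        0.1 * rng.normal(size=h),
                                        0.5 * rng.normal(size=(prev, h)),
                                        0.1 * rng.normal(size=prev)))
        prev = h
    softmax = SoftmaxParams(0.5 * rng.normal(size=(3, prev)), 0.1 * rng.normal(size=3))
    return SSAEModel(layers, softmax, list(sizes))


class TestFineTune:
    def test_zero_learning_rate_identity(self, rng):
        model = _toy_model()
        X = rng.uniform(size=(6, 5))
        labels = np.array([0, 1, 2, 0, 1, 2])
        tuned, trace = fine_tune(model, X, labels,
                                 FineTuneHyperparams(learning_rate=0.0, epochs=3))
        np.testing.assert_array_equal(tuned.layers[0].W, model.layers[0].W)
        assert len(trace.cross_entropy) == 3

    def test_full_pipeline_gradient_matches_finite_differences(self, rng):
        model = _toy_model(seed=7)
        X = rng.uniform(size=(5, 5))
        labels = np.array([0, 1, 2, 1, 0])
        beta = 0.02
        cost, layer_grads, softmax_grad = finetune_cost_grad(model, X, labels, beta)

        def pack(m):
            parts = []
            for l in m.layers:
                parts.extend([l.W.ravel(), l.b])
            parts.extend([m.softmax.W.ravel(), m.softmax.b])
            return np.concatenate(parts)

        def unpack(v):
            m = model.copy()
            i = 0
            for l in m.layers:
                l.W[:] = v[i:i + l.W.size].reshape(l.W.shape); i += l.W.size
                l.b[:] = v[i:i + l.b.size]; i += l.b.size
            W = m.softmax.W
            W[:] = v[i:i + W.size].reshape(W.shape); i += W.size
            m.softmax.b[:] = v[i:]
            return m

        v0 = pack(model)
        numeric = numeric_gradient(
            lambda v: finetune_cost_grad(unpack(v), X, labels, beta)[0], v0)
        analytic = np.concatenate(
            [np.concatenate([g.W.ravel(), g.b]) for g in layer_grads]
            + [softmax_grad.W.ravel(), softmax_grad.b])
        assert rel_error(analytic, numeric) < 1e-6

    def test_cross_entropy_decreases(self, rng):
        model = _toy_model(seed=1)
        X = rng.uniform(size=(30, 5))
        labels = rng.integers(0, 3, size=30)
        _, trace = fine_tune(model, X, labels,
                             FineTuneHyperparams(learning_rate=0.3, epochs=100))
        assert trace.cross_entropy[-1] <= trace.cross_entropy[0]


class TestPredictAndEstimator:
    def test_probability_rows_sum_to_one(self, rng):
        model = _toy_model()
        _, probs = predict(model, rng.uniform(size=(7, 5)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_deterministic(self, rng):
        model = _toy_model()
        X = rng.uniform(size=(4, 5))
        a = predict(model, X)
        b = predict(model, X)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_dimension_mismatch_errors(self, rng):
        model = _toy_model(d=5)
        with pytest.raises(ValueError):
            predict(model, rng.uniform(size=(3, 7)))

    def test_estimator_fits_separable_data(self):
        rng = np.random.default_rng(0)
        centers = np.array([[0.1] * 6, [0.5] * 6, [0.9] * 6])
        X = np.vstack([c + 0.03 * rng.normal(size=(25, 6)) for c in centers])
        y = np.repeat([0, 1, 2], 25)
        clf = SSAEClassifier(hidden_layer_sizes=(8, 4), pretrain_epochs=50,
                             softmax_epochs=300, finetune_epochs=300, random_state=1)
        clf.fit(X, y)
        assert clf.predict(X).shape == (75,)
        assert np.mean(clf.predict(X) == y) >= 0.95
        probs = clf.predict_proba(X)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_estimator_sklearn_params_round_trip(self):
        from sklearn.base import clone
        clf = SSAEClassifier(hidden_layer_sizes=(10, 5), random_state=3)
        assert clone(clf).get_params() == clf.get_params()


class TestSparsityEffect:
    def test_sparsity_penalty_pulls_mean_activation_toward_target(self, rng):
        X = rng.uniform(size=(40, 10))
        common = dict(hidden_size=12, learning_rate=0.05, epochs=400,
                      weight_decay=0.0, seed=21)
        sparse, _ = train_sae(X, SAEHyperparams(sparsity_weight=4.0,
                                                sparsity_target=0.05, **common))
        plain, _ = train_sae(X, SAEHyperparams(sparsity_weight=0.0,
                                               sparsity_target=0.05, **common))
        rho_sparse = float(np.mean(average_activation(X, sparse)))
        rho_plain = float(np.mean(average_activation(X, plain)))
        assert abs(rho_sparse - 0.05) < abs(rho_plain - 0.05)
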