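"""RMSNN forward/backward, training behavior and cross-validation mechanics."""

import numpy as np
import pytest

from spinewave import _kernels
from spinewave.rmsnn import (
    RMSNNModel,
    TrainingConfig,
    backward_update,
    cross_validate,
    confusion_matrix_counts,
    forward,
    init_model,
    loss_and_grads,
    one_hot,
    predict,
    predict_scores,
    regularized_cost,
    train,
)


def tiny_model(seed=7, input_size=5, se="disk:1", maps=2, hidden=3):
    return init_model(n_maps=maps, hidden=hidden, input_size=input_size, se_shape=se, seed=seed, se_init=0.3)


class TestForward:
    def test_zero_classifier_gives_half(self, rng):
        m = tiny_model()
        m.W1[:] = 0
        m.b1[:] = 0
        m.W2[:] = 0
        m.b2[:] = 0
        out, _ = forward(m, rng.uniform(size=(5, 5)))
        assert np.allclose(out, 0.5)

    def test_scalar_closed_form(self):
        """1x1 image, single-element SEs: the feature is a(0) cancels to
        hit-miss difference; one weight path gives sigmoid(w*a + ...)."""
        m = init_model(n_maps=1, hidden=1, input_size=1, se_shape="disk:0", seed=0, se_init=0.0)
        m.hit1[:] = 0.2
        m.miss1[:] = -0.1
        m.hit2[:] = 0.0
        m.miss2[:] = 0.0
        m.W1[:] = 0.8
        m.b1[:] = 0.0
        m.W2[:] = 1.5
        m.b2[:] = 0.0
        img = np.array([[0.6]])
        # layer1: (0.6-0.2)-(0.6+0.1) = -0.3; layer2 with zero SEs: 0
        # hidden = sigmoid(0.8*0); out = sigmoid(1.5*0.5)
        out, cache = forward(m, img)
        a1 = cache["a1"][0, 0, 0]
        assert a1 == pytest.approx(-0.3)
        assert cache["a2"][0, 0, 0] == pytest.approx(0.0)
        sig = lambda x: 1 / (1 + np.exp(-x))
        assert out[0] == pytest.approx(sig(1.5 * sig(0.0)))

    def test_deterministic(self, rng):
        m = tiny_model()
        img = rng.uniform(size=(5, 5))
        o1, _ = forward(m, img)
        o2, _ = forward(m, img)
        assert np.array_equal(o1, o2)

    def test_gray_shift_invariance(self, rng):
        m = init_model(seed=3)
        img = rng.uniform(size=(20, 20))
        s0 = predict_scores(m, img[None])[0]
        s1 = predict_scores(m, img[None] + 0.31)[0]
        assert np.allclose(s0, s1, atol=1e-12)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            forward(tiny_model(), rng.uniform(size=(7, 7)))

    def test_numba_matches_numpy_reference(self, rng):
        m = init_model(seed=11)
        img = rng.uniform(size=(20, 20))
        ref, _ = forward(m, img)
        fast = predict_scores(m, img[None])[0]
        assert np.allclose(ref, fast, atol=1e-14)


class TestBackward:
    def test_zero_error_no_update(self, rng):
        m = tiny_model()
        img = rng.uniform(size=(5, 5))
        out, _ = forward(m, img)
        before = {n: getattr(m, n).copy() for n in ("W1", "W2", "hit1", "miss2")}
        cfg = TrainingConfig(eta=0.1, lam=0.0)
        backward_update(m, img, out, cfg)  # target == output exactly
        for n, v in before.items():
            assert np.allclose(getattr(m, n), v, atol=1e-12)

    def test_gradients_match_finite_differences(self, rng):
        """Analytic backprop (SE subgradients and penalty included) vs
        central differences on a tiny network, relative 1e-4."""
        m = tiny_model(seed=5, input_size=4, se="disk:1", maps=1, hidden=2)
        img = rng.uniform(size=(4, 4))
        t = np.array([0.0, 1.0, 0.0])
        lam, w0 = 1e-2, 0.8
        _, grads, _ = loss_and_grads(m, img, t, lam=lam, w0=w0, regularize_ses=True)

        def cost():
            out, _ = forward(m, img)
            es = 0.5 * float(((t - out) ** 2).sum())
            return regularized_cost(es, m, lam, w0, include_ses=True)

        eps = 1e-6
        for name, g in grads.items():
            arr = getattr(m, name)
            flat, gf = arr.ravel(), g.ravel()
            for i in rng.choice(flat.size, min(8, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                cp = cost()
                flat[i] = orig - eps
                cm = cost()
                flat[i] = orig
                fd = (cp - cm) / (2 * eps)
                assert fd == pytest.approx(gf[i], rel=1e-4, abs=1e-9), name

    def test_non_extremal_se_element_has_zero_gradient(self, rng):
        """Perturbing an SE element that is not the arg-extremum of any
        window leaves the loss unchanged to first order."""
        m = tiny_model(seed=5, input_size=4, se="disk:1", maps=1, hidden=2)
        img = rng.uniform(size=(4, 4))
        t = np.array([1.0, 0.0, 0.0])
        _, grads, cache = loss_and_grads(m, img, t)
        used = set(np.unique(cache["amin1"]))
        unused = [d for d in range(m.hit1.shape[1]) if d not in used]
        for d in unused:
            assert grads["hit1"][0, d] == 0.0

    def test_kernel_step_equals_reference_step(self, rng):
        m1 = init_model(seed=2)
        m2 = init_model(seed=2)
        img = rng.uniform(size=(1, 20, 20))
        tgt = one_hot(np.array([1]))
        cfg = TrainingConfig(eta=0.01, lam=1e-3)
        backward_update(m1, img[0], tgt[0], cfg)
        dy, dx = m2.offsets
        _kernels.train_epoch(
            np.ascontiguousarray(img), tgt, np.array([0]),
            m2.hit1, m2.miss1, m2.hit2, m2.miss2, dy, dx,
            m2.W1, m2.b1, m2.W2, m2.b2,
            cfg.eta, cfg.lam, cfg.w0, cfg.regularize_ses,
        )
        for name in ("hit1", "miss1", "hit2", "miss2", "W1", "b1", "W2", "b2"):
            assert np.allclose(getattr(m1, name), getattr(m2, name), atol=1e-12), name


class TestRegularizedCost:
    def test_zero_weights_no_penalty(self):
        m = tiny_model()
        m.W1[:] = 0
        m.W2[:] = 0
        assert regularized_cost(0.42, m, lam=0.5, w0=1.0) == pytest.approx(0.42)

    def test_single_weight_at_w0_is_half(self):
        m = tiny_model()
        m.W1[:] = 0
        m.W2[:] = 0
        m.W1[0, 0] = 1.0
        assert regularized_cost(0.0, m, lam=1.0, w0=1.0) == pytest.approx(0.5)

    def test_penalty_saturates_monotonically(self):
        u = np.array([0.1, 1.0, 10.0, 1000.0])
        pen = (u**2) / (1 + u**2)
        assert np.all(np.diff(pen) > 0) and pen[-1] < 1.0


def toy_separable_library(n=30, seed=0):
    """Two bright-corner patterns per class on 8x8 images: trivially
    separable by local contrast layout."""
    rng = np.random.default_rng(seed)
    images, labels = [], []
    for i in range(n):
        c = i % 3
        img = rng.uniform(0, 0.1, (8, 8))
        if c == 0:
            img[:4, :4] += 0.8
        elif c == 1:
            img[4:, 4:] += 0.8
        else:
            img[:4, 4:] += 0.8
        images.append(img)
        labels.append(c)
    return np.stack(images), np.array(labels)


class TestTraining:
    def test_separable_toy_converges(self):
        images, labels = toy_separable_library(60, seed=1)
        m = init_model(n_maps=2, hidden=4, input_size=8, se_shape="disk:1", seed=1)
        cfg = TrainingConfig(eta=0.05, max_epochs=200, mse_target=5e-3, lam=0.0, seed=1)
        hist = train(m, images, labels, cfg)
        assert hist["mean_squared_error"][-1] < 5e-3
        assert (predict(m, images) == labels).all()

    def test_determinism(self):
        images, labels = toy_separable_library(30, seed=2)
        ms = []
        for _ in range(2):
            m = init_model(n_maps=1, hidden=3, input_size=8, se_shape="disk:1", seed=3)
            train(m, images, labels, TrainingConfig(eta=0.02, max_epochs=20, seed=3))
            ms.append(m)
        for name in ("hit1", "miss1", "W1", "W2"):
            assert np.array_equal(getattr(ms[0], name), getattr(ms[1], name))

    def test_smoothed_error_nonincreasing_on_toy(self):
        images, labels = toy_separable_library(60, seed=4)
        m = init_model(n_maps=1, hidden=4, input_size=8, se_shape="disk:1", seed=4)
        hist = train(m, images, labels, TrainingConfig(eta=0.05, max_epochs=120, seed=4))
        curve = hist["mean_squared_error"]
        smooth = np.convolve(curve, np.ones(10) / 10, mode="valid")
        assert np.all(np.diff(smooth) < 1e-3)

    def test_regularization_zeroes_weights(self):
        images, labels = toy_separable_library(60, seed=5)
        counts = {}
        for lam in (0.0, 3e-3):
            m = init_model(n_maps=1, hidden=4, input_size=8, se_shape="disk:1", seed=5)
            train(m, images, labels, TrainingConfig(eta=0.05, max_epochs=150, lam=lam, seed=5))
            counts[lam] = int((np.abs(m.W1) < 0.01).sum() + (np.abs(m.W2) < 0.01).sum())
        assert counts[3e-3] > counts[0.0]

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            train(tiny_model(input_size=8), np.zeros((0, 8, 8)), np.zeros(0), TrainingConfig())

    def test_divergence_detected(self):
        images, labels = toy_separable_library(9, seed=6)
        m = init_model(n_maps=1, hidden=3, input_size=8, se_shape="disk:1", seed=6)
        m.b2[:] = np.nan  # corrupted state propagates to the loss
        with pytest.raises(FloatingPointError):
            train(m, images, labels, TrainingConfig(eta=0.01, max_epochs=3, seed=6))


class TestCrossValidation:
    def test_row_sums_conserve_counts(self):
        images, labels = toy_separable_library(60, seed=7)
        cfg = TrainingConfig(eta=0.05, max_epochs=40, seed=7)
        res = cross_validate(images, labels, cfg, folds=5, n_maps=1, hidden=3, se_shape="disk:1")
        assert res["confusion_counts"].sum(axis=1).tolist() == [20, 20, 20]
        assert np.allclose(res["confusion_percent"].sum(axis=1), 100.0)

    def test_perfect_oracle_identity_confusion(self):
        y = np.array([0, 1, 2] * 10)
        cm = confusion_matrix_counts(y, y)
        assert np.array_equal(cm, np.diag([10, 10, 10]))

    def test_insufficient_samples_per_class(self):
        images, labels = toy_separable_library(9, seed=8)
        with pytest.raises(ValueError):
            cross_validate(images, labels, TrainingConfig(), folds=10)


class TestSerialization:
    def test_round_trip(self, tmp_path, rng):
        m = init_model(seed=9)
        path = tmp_path / "model.json"
        m.save(path)
        loaded = RMSNNModel.load(path)
        img = rng.uniform(size=(20, 20))
        assert np.allclose(predict_scores(m, img[None]), predict_scores(loaded, img[None]))
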