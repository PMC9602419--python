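import numpy as np
import pytest

from ciea import (
    AdamState,
    LrSchedule,
    NetworkSpec,
    TrainConfig,
    adam_step,
    binary_cross_entropy,
    build_network,
    conv2d,
    decayed_learning_rate,
    evaluate,
    leaky_relu,
    max_pool,
    train,
)
from ciea.network import CBAMBlock, Model, _sigmoid
from ciea.synthetic import LabeledImage


class TestConv2d:
    def test_identity_kernel(self, rng):
        x = rng.random((1, 6, 6))
        k = np.zeros((1, 1, 3, 3))
        k[0, 0, 1, 1] = 1.0
        np.testing.assert_allclose(conv2d(x, k), x, atol=1e-15)

    def test_ones_kernel_on_constant_valid_mode(self):
        x = np.full((1, 5, 5), 2.0)
        k = np.ones((1, 1, 3, 3))
        out = conv2d(x, k, bias=np.array([0.5]), mode="valid")
        assert out.shape == (1, 3, 3)  # (m - n + 1) x (m - n + 1)
        np.testing.assert_allclose(out, 9 * 2.0 + 0.5)

    def test_matches_quadruple_loop(self, rng):
        x = rng.normal(size=(1, 5, 5))
        k = rng.normal(size=(2, 1, 3, 3))
        b = rng.normal(size=2)
        got = conv2d(x, k, b, mode="valid")
        expected = np.zeros((2, 3, 3))
        for o in range(2):
            for u in range(3):
                for v in range(3):
                    acc = b[o]
                    for i in range(3):
                        for j in range(3):
                            acc += x[0, u + i, v + j] * k[o, 0, i, j]
                    expected[o, u, v] = acc
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_channel_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            conv2d(rng.random((2, 5, 5)), rng.random((1, 3, 3, 3)))


class TestPointwiseOps:
    @pytest.mark.parametrize(
        "x,a,expected", [(5.0, 0.01, 5.0), (-2.0, 0.01, -0.02), (0.0, 0.3, 0.0)]
    )
    def test_leaky_relu_values(self, x, a, expected):
        assert leaky_relu(x, a) == pytest.approx(expected)

    def test_max_pool_examples(self):
        assert max_pool(np.array([[1.0, 2.0], [3.0, 4.0]])) == 4.0
        np.testing.assert_allclose(max_pool(np.full((1, 4, 4), 3.0)), 3.0)

    def test_max_pool_matches_loops(self, rng):
        x = rng.normal(size=(2, 8, 8))
        got = max_pool(x, r=2)
        for c in range(2):
            for i in range(4):
                for j in range(4):
                    block = [
                        x[c, 2 * i + di, 2 * j + dj] for di in range(2) for dj in range(2)
                    ]
                    assert got[c, i, j] == max(block)

    def test_bce_values(self):
        assert binary_cross_entropy([1], [1 - 1e-12]) == pytest.approx(0.0, abs=1e-9)
        assert binary_cross_entropy([1], [0.5]) == pytest.approx(np.log(2))
        assert binary_cross_entropy([0, 1], [0.5, 0.5]) == pytest.approx(np.log(2))
        with pytest.raises(ValueError):
            binary_cross_entropy([0, 1], [0.5])


class TestSchedule:
    def test_closed_form_values(self):
        s = LrSchedule(learning_rate=1e-4, decay_rate=0.96, decay_steps=50)
        assert decayed_learning_rate(s, 0) == pytest.approx(1e-4)
        assert decayed_learning_rate(s, 50) == pytest.approx(9.6e-5)
        s2 = LrSchedule(learning_rate=1.0, decay_rate=0.5, decay_steps=10)
        assert decayed_learning_rate(s2, 20) == pytest.approx(0.25)

    def test_continuous_not_staircase(self):
        s = LrSchedule(learning_rate=1.0, decay_rate=0.5, decay_steps=10)
        assert decayed_learning_rate(s, 5) == pytest.approx(0.5**0.5)

    def test_never_exceeds_initial(self):
        s = LrSchedule(learning_rate=3e-4, decay_rate=0.9, decay_steps=7)
        for step in range(0, 200, 13):
            assert decayed_learning_rate(s, step) <= s.learning_rate + 1e-18


class TestAdam:
    def test_first_step_moves_by_alpha_sign(self):
        state = AdamState(theta=np.array([1.0, -2.0]), alpha=0.1, eps=1e-12)
        g = np.array([3.0, -4.0])
        new = adam_step(state, g)
        np.testing.assert_allclose(
            new.theta, state.theta - 0.1 * np.sign(g), rtol=1e-9
        )

    def test_zero_gradient_never_moves(self):
        state = AdamState(theta=np.array([1.0]))
        for _ in range(5):
            state = adam_step(state, np.zeros(1))
        assert state.theta[0] == 1.0
        assert state.t == 5

    def test_ten_step_quadratic_matches_hand_rolled_loop(self):
        """f(theta) = theta^2, gradient 2*theta, ten Adam steps."""
        alpha, b1, b2, eps = 0.1, 0.9, 0.999, 1e-8
        theta, m, v = 1.0, 0.0, 0.0
        trajectory = []
        for t in range(1, 11):
            g = 2 * theta
            m = b1 * m + (1 - b1) * g
            v = b2 * v + (1 - b2) * g * g
            mh = m / (1 - b1**t)
            vh = v / (1 - b2**t)
            theta = theta - alpha * mh / (np.sqrt(vh) + eps)
            trajectory.append(theta)

        state = AdamState(theta=np.array([1.0]), alpha=alpha, beta1=b1, beta2=b2, eps=eps)
        for t in range(10):
            state = adam_step(state, 2 * state.theta)
            assert state.theta[0] == pytest.approx(trajectory[t], abs=1e-12)


def tiny_spec(**kw):
    defaults = dict(
        input_size=32,
        channels=(2, 3, 4, 4, 4),
        fc_hidden=5,
        reduction_ratio=2,
        spatial_kernel=3,
        dropout_rate=0.0,
    )
    defaults.update(kw)
    return NetworkSpec(**defaults)


class TestArchitecture:
    def test_feature_side_after_five_pools(self):
        assert NetworkSpec(input_size=224).feature_side == 7
        assert NetworkSpec(input_size=64).feature_side == 2

    def test_small_input_rejected(self):
        with pytest.raises(ValueError):
            NetworkSpec(input_size=16)
        with pytest.raises(ValueError):
            NetworkSpec(channels=(8, 8, 8))

    def test_forward_gives_probabilities(self, rng):
        model = build_network(tiny_spec(), seed=0)
        p = _sigmoid(model.forward(rng.random((3, 1, 32, 32)).astype(np.float32)))
        assert p.shape == (3,)
        assert np.all((p > 0) & (p < 1))

    def test_parameter_count_is_function_of_spec(self):
        spec = tiny_spec()
        assert build_network(spec, seed=0).n_parameters() == build_network(
            spec, seed=99
        ).n_parameters()

        def block_params(cin, cout, red, k):
            conv = cout * cin * 9 + cout
            bn = 2 * cout
            hidden = max(1, cout // red)
            cbam = cout * hidden + hidden * cout + cout + 2 * k * k + 1
            return conv + bn + cbam

        expected = 0
        cin = 1
        for cout in (2, 3, 4, 4, 4):
            expected += block_params(cin, cout, 2, 3)
            cin = cout
        expected += (4 * 1 * 1) * 5 + 5  # fc1 on the 1x1 feature map
        expected += 5 * 1 + 1  # fc2
        assert build_network(tiny_spec(), seed=0).n_parameters() == expected


class TestGradients:
    def test_backprop_matches_numerical_gradients(self, rng):
        """End-to-end analytic/numeric gradient agreement (float64 model)."""
        model = Model(tiny_spec(), seed=0, dtype=np.float64)
        x = rng.random((2, 1, 32, 32))
        y = np.array([0.0, 1.0])

        def loss():
            return binary_cross_entropy(y, _sigmoid(model.forward(x, train=False)))

        p = _sigmoid(model.forward(x, train=False))
        model.zero_grad()
        model.backward((p - y) / len(y))
        eps = 1e-5
        check_rng = np.random.default_rng(0)
        for prm in model.params():
            flat, grad = prm.value.ravel(), prm.grad.ravel()
            for i in check_rng.choice(flat.size, size=min(3, flat.size), replace=False):
                old = flat[i]
                flat[i] = old + eps
                lp = loss()
                flat[i] = old - eps
                lm = loss()
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                assert grad[i] == pytest.approx(num, rel=1e-3, abs=1e-9), prm.name

    def test_cbam_block_gradients(self, rng):
        blk = CBAMBlock(3, 1, 3, np.random.default_rng(0))
        x = rng.random((2, 3, 5, 5))
        w = rng.random((2, 3, 5, 5))
        blk.forward(x, True)
        for p in blk.params():
            p.grad[...] = 0
        dx = blk.backward(w)

        def loss():
            return float(np.sum(w * blk.forward(x, True)))

        eps = 1e-6
        flat = x.ravel()
        for i in np.random.default_rng(1).choice(flat.size, 10, replace=False):
            old = flat[i]
            flat[i] = old + eps
            lp = loss()
            flat[i] = old - eps
            lm = loss()
            flat[i] = old
            assert dx.ravel()[i] == pytest.approx((lp - lm) / (2 * eps), rel=1e-4, abs=1e-8)


def make_dataset(n, size, seed):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        label = i % 2
        img = rng.random((size, size)) * 0.2 + 0.6 * label
        out.append(LabeledImage(np.clip(img, 0, 1), label, id=str(i)))
    return out


class TestTraining:
    def test_initial_learning_rate_logged(self):
        ds = make_dataset(10, 32, seed=0)
        model = build_network(tiny_spec(), seed=0)
        hist = train(model, ds, TrainConfig(epochs=1, seed=0, learning_rate=1e-4))
        assert hist["lr"][0] == pytest.approx(1e-4)

    def test_memorizes_small_dataset(self):
        """Ten strongly separated samples are fit to near-zero loss
        within 200 optimisation steps."""
        ds = make_dataset(10, 32, seed=1)
        model = build_network(
            tiny_spec(channels=(4, 8, 16, 16, 16), fc_hidden=16), seed=1
        )
        hist = train(
            model,
            ds,
            TrainConfig(
                epochs=200, batch_size=16, learning_rate=3e-3, decay_rate=1.0, seed=1
            ),
        )
        assert min(hist["train_loss"]) < 0.05

    def test_eval_mode_deterministic(self):
        ds = make_dataset(10, 32, seed=2)
        model = build_network(tiny_spec(dropout_rate=0.5), seed=2)
        train(model, ds, TrainConfig(epochs=1, seed=2))
        p1 = model.predict_proba(ds)
        p2 = model.predict_proba(ds)
        np.testing.assert_array_equal(p1, p2)

    def test_empty_dataset_rejected(self):
        model = build_network(tiny_spec(), seed=0)
        with pytest.raises(ValueError):
            train(model, [], TrainConfig(epochs=1))
        with pytest.raises(ValueError):
            evaluate(model, [])

    def test_evaluate_thresholding(self):
        class Fake:
            def predict_proba(self, ds):
                return np.array([0.4, 0.6])

        ds = [LabeledImage(np.zeros((4, 4)), 0), LabeledImage(np.zeros((4, 4)), 1)]
        assert evaluate(Fake(), ds) == 1.0

        class FakeBad:
            def predict_proba(self, ds):
                return np.array([0.6, 0.4])

        assert evaluate(FakeBad(), ds) == 0.0

    def test_checkpoint_roundtrip(self):
        ds = make_dataset(10, 32, seed=3)
        model = build_network(tiny_spec(), seed=3)
        train(model, ds, TrainConfig(epochs=1, seed=3))
        state = model.state_dict()
        clone = build_network(tiny_spec(), seed=99)
        clone.load_state_dict(state)
        np.testing.assert_array_equal(model.predict_proba(ds), clone.predict_proba(ds))
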