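"""Network building blocks: gradients, residual identity, GRL, losses."""

import numpy as np
import pytest

from emoconn.nn.layers import (BatchNorm, Conv2d, Dense, Dropout, Flatten,
                               ReLU, ResidualBlock, Sequential, Sigmoid, softmax)
from emoconn.nn.network import (DARCNN, GradientReversal, SoftmaxCrossEntropy,
                                classifier_loss, discriminator_loss)
from emoconn.nn.optim import Adam


def numeric_grad(f, x, eps=1e-3):
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        xp = x.copy(); xp[idx] += eps
        xm = x.copy(); xm[idx] -= eps
        g[idx] = (f(xp) - f(xm)) / (2 * eps)
    return g


def check_input_grad(layer, x, rtol=2e-2, train=True, eps=1e-3):
    """Finite-difference vs analytic input gradient (random projection)."""
    layer.set_mode(train)
    rng = np.random.default_rng(0)
    y = layer.forward(x)
    proj = rng.standard_normal(y.shape).astype(np.float32)
    gx = layer.backward(proj)

    def f(xx):
        return float((layer.forward(xx.astype(np.float32)) * proj).sum())

    num = numeric_grad(f, x.astype(np.float64), eps=eps)
    layer.forward(x)  # restore caches
    denom = max(np.abs(num).max(), 1e-6)
    assert np.abs(gx - num).max() / denom < rtol


class TestLayerGradients:
    def test_conv_input_and_weight_gradients(self, rng):
        conv = Conv2d(3, 4, 3, rng)
        x = rng.standard_normal((2, 6, 6, 3)).astype(np.float32)
        check_input_grad(conv, x)
        # weight gradient
        proj = rng.standard_normal((2, 6, 6, 4)).astype(np.float32)
        conv.forward(x)
        conv.backward(proj)
        w0 = conv.w.value.copy()

        def f(wv):
            conv.w.value = wv.astype(np.float32)
            out = float((conv.forward(x) * proj).sum())
            conv.w.value = w0
            return out

        num = numeric_grad(f, w0.astype(np.float64))
        assert np.abs(conv.w.grad - num).max() / max(np.abs(num).max(), 1e-6) < 2e-2

    def test_batchnorm_gradient_train_mode(self, rng):
        bn = BatchNorm(3)
        x = rng.standard_normal((8, 4, 4, 3)).astype(np.float32)
        check_input_grad(bn, x)

    def test_dense_gradient(self, rng):
        d = Dense(5, 3, rng)
        x = rng.standard_normal((4, 5)).astype(np.float32)
        check_input_grad(d, x)

    def test_residual_block_gradient_through_both_branches(self, rng):
        """Finite-difference agreement through F(x) + shortcut(x).

        Entries whose perturbation crosses a ReLU kink make the central
        difference itself wrong, so agreement is asserted on the 90th
        percentile of the error rather than the max.
        """
        rb = ResidualBlock(2, 4, 3, rng)  # projection shortcut
        rb.set_mode(True)
        proj_rng = np.random.default_rng(0)
        x = rng.standard_normal((2, 5, 5, 2)).astype(np.float32)
        y = rb.forward(x)
        proj = proj_rng.standard_normal(y.shape).astype(np.float32)
        gx = rb.backward(proj)

        def f(xx):
            return float((rb.forward(xx.astype(np.float32)) * proj).sum())

        num = numeric_grad(f, x.astype(np.float64))
        err = np.abs(gx - num)
        assert np.quantile(err, 0.9) / max(np.abs(num).max(), 1e-6) < 1e-2

    def test_sigmoid_and_relu_gradients(self, rng):
        for layer in (Sigmoid(), ReLU()):
            x = rng.standard_normal((4, 7)).astype(np.float32) + 0.05
            check_input_grad(layer, x)


class TestResidualBlock:
    def test_zeroed_body_is_identity(self, rng):
        rb = ResidualBlock(3, 3, 3, rng)
        for p in rb.body.params():
            p.value[...] = 0.0
        x = rng.standard_normal((2, 6, 6, 3)).astype(np.float32)
        rb.set_mode(False)
        assert np.allclose(rb.forward(x), x, atol=1e-6)

    def test_channel_growth_uses_projection(self, rng):
        rb = ResidualBlock(4, 8, 3, rng)
        assert rb.shortcut is not None
        x = rng.standard_normal((2, 6, 6, 4)).astype(np.float32)
        assert rb.forward(x).shape == (2, 6, 6, 8)

    def test_matching_channels_identity_shortcut(self, rng):
        assert ResidualBlock(4, 4, 3, rng).shortcut is None


class TestGradientReversal:
    def test_forward_identity(self, rng):
        v = rng.standard_normal((3, 4))
        assert np.array_equal(GradientReversal(0.7).forward(v), v)

    def test_backward_negates_scaled(self, rng):
        g = rng.standard_normal((3, 4))
        assert np.allclose(GradientReversal(1.0).backward(g), -g)
        assert np.allclose(GradientReversal(0.0).backward(g), 0.0)
        assert np.allclose(GradientReversal(2.5).backward(g), -2.5 * g)

    def test_equals_negated_plain_gradient_through_network(self, rng):
        """lambda=1: the gradient of a loss through GRL equals the negated
        gradient of the same loss without GRL (autodiff comparison)."""
        d = Dense(6, 2, rng)
        x = rng.standard_normal((5, 6)).astype(np.float32)
        ce = SoftmaxCrossEntropy("mean")
        y = np.array([0, 1, 0, 1, 0])
        ce.forward(d.forward(x), y)
        plain = d.backward(ce.backward())
        ce.forward(d.forward(x), y)
        reversed_ = GradientReversal(1.0).backward(d.backward(ce.backward()))
        assert np.allclose(reversed_, -plain, atol=1e-7)


class TestLosses:
    def test_perfect_prediction_zero(self):
        probs = np.eye(3)[np.array([0, 1, 2])]
        assert classifier_loss(probs, [0, 1, 2]) == pytest.approx(0.0, abs=1e-12)

    def test_half_probability_closed_form(self):
        assert classifier_loss(np.array([[0.5, 0.5]]), [0]) == pytest.approx(np.log(2), rel=1e-12)

    def test_matches_double_sum_oracle(self, rng):
        """Independently coded double sum over samples and classes with the
        one-hot indicator."""
        p = rng.dirichlet(np.ones(4), size=12)
        y = rng.integers(0, 4, 12)
        expected = 0.0
        for i in range(12):
            for c in range(4):
                expected += -(1.0 if y[i] == c else 0.0) * np.log(p[i, c])
        assert classifier_loss(p, y, "sum") == pytest.approx(expected, rel=1e-10)
        assert classifier_loss(p, y, "mean") == pytest.approx(expected / 12, rel=1e-10)

    def test_zero_probability_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamping"):
            v = classifier_loss(np.array([[0.0, 1.0]]), [0])
        assert np.isfinite(v)

    def test_discriminator_closed_form(self):
        # P=0.5 everywhere, one source and one target sample -> 2 log 2
        probs = np.array([[0.5, 0.5], [0.5, 0.5]])
        v = discriminator_loss(probs, [0, 1])
        assert v == pytest.approx(2 * np.log(2), rel=1e-12)

    def test_discriminator_perfect_zero(self):
        probs = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert discriminator_loss(probs, [0, 1]) == pytest.approx(0.0, abs=1e-9)

    def test_discriminator_single_domain_flagged(self):
        with pytest.warns(UserWarning, match="single domain"):
            discriminator_loss(np.array([[0.9, 0.1]]), [0])

    def test_discriminator_matches_bruteforce(self, rng):
        p1 = rng.dirichlet(np.ones(2), 5)
        labs = np.array([0, 0, 1, 1, 0])
        expected = -sum(np.log(p1[i, labs[i]]) for i in range(5))
        assert discriminator_loss(p1, labs) == pytest.approx(expected, rel=1e-10)


class TestDarcnnModel:
    def test_table_layer_shapes_default_config(self, rng):
        """Stem and residual blocks keep 32x32 spatial maps with channel
        widths 32/32/64/128; dense stages are 1024 and 512."""
        net = DARCNN((32, 32), n_classes=2, kernel=5, stem_filters=32,
                     block_channels=(32, 64, 128), dense_sizes=(1024, 512), seed=0)
        x = np.zeros((1, 32, 32, 1), dtype=np.float32)
        net.set_mode(False)
        shapes = []
        h = x
        for layer in net.feature.layers:
            h = layer.forward(h)
            shapes.append(h.shape)
        assert shapes[2][1:] == (32, 32, 32)     # after stem conv+bn+relu
        assert shapes[3][1:] == (32, 32, 32)     # block 1
        assert shapes[4][1:] == (32, 32, 64)     # block 2
        assert shapes[5][1:] == (32, 32, 128)    # block 3
        for layer in net.label_head.layers:
            h = layer.forward(h)
        assert h.shape == (1, 2)

    def test_single_block_configuration(self):
        net = DARCNN((16, 16), kernel=3, stem_filters=4, block_channels=(4,),
                     dense_sizes=(8, 4), seed=0)
        blocks = [l for l in net.feature.layers if isinstance(l, ResidualBlock)]
        assert len(blocks) == 1

    def test_zero_batch_forward_finite_softmax(self):
        net = DARCNN((8, 8), kernel=3, stem_filters=2, block_channels=(2,),
                     dense_sizes=(8, 4), seed=0)
        p = net.predict_proba(np.zeros((3, 8, 8)))
        assert np.all(np.isfinite(p))
        assert np.allclose(p.sum(axis=1), 1.0)

    def test_kernel_too_large_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            DARCNN((4, 4), kernel=5)

    def test_predict_tie_breaks_low_class(self):
        assert np.argmax(np.array([[0.5, 0.5]]), axis=1)[0] == 0
        net = DARCNN((8, 8), kernel=3, stem_filters=2, block_channels=(2,),
                     dense_sizes=(4, 2), seed=0)
        # force identical logits by zeroing the final dense layer
        final = net.label_head.layers[-1]
        final.w.value[...] = 0.0
        final.b.value[...] = 0.0
        assert np.all(net.predict(np.random.default_rng(0).standard_normal((4, 8, 8))) == 0)

    def test_predictions_invariant_to_monotone_logit_transform(self, rng):
        logits = rng.standard_normal((10, 2))
        a = np.argmax(softmax(logits), axis=1)
        b = np.argmax(softmax(3.0 * logits + 1.0), axis=1)
        assert np.array_equal(a, b)

    def test_full_network_gradient(self, rng):
        """End-to-end finite-difference check of d(loss)/d(input)."""
        net = DARCNN((6, 6), kernel=3, stem_filters=2, block_channels=(2,),
                     dense_sizes=(6, 4), dropout=0.0, dense_activation="relu", seed=3)
        net.set_mode(True)
        x = rng.standard_normal((3, 6, 6)).astype(np.float32)
        y = np.array([0, 1, 0])
        ce = SoftmaxCrossEntropy("mean")

        def loss_of(xx):
            f = net.feature.forward(net._as_batch(xx.astype(np.float32)))
            _, l = ce.forward(net.label_head.forward(f), y)
            return l

        loss_of(x)
        g = net.feature.backward(net.label_head.backward(ce.backward()))[..., 0]
        num = numeric_grad(loss_of, x.astype(np.float64), eps=1e-2)
        assert np.abs(g - num).max() / max(np.abs(num).max(), 1e-6) < 5e-2

    def test_adam_reduces_loss_on_toy_problem(self, rng):
        d = Dense(4, 2, rng)
        x = rng.standard_normal((32, 4)).astype(np.float32)
        y = (x[:, 0] > 0).astype(int)
        ce = SoftmaxCrossEntropy("mean")
        opt = Adam(d.params(), lr=0.05)
        losses = []
        for _ in range(200):
            opt.zero_grad()
            probs, l = ce.forward(d.forward(x), y)
            d.backward(ce.backward())
            opt.step()
            losses.append(l)
        assert losses[-1] < 0.25 * losses[0]
        assert np.array_equal(np.argmax(probs, axis=1), y)


class TestDropout:
    def test_eval_mode_identity(self, rng):
        dr = Dropout(0.5, rng)
        dr.set_mode(False)
        x = rng.standard_normal((4, 6)).astype(np.float32)
        assert np.array_equal(dr.forward(x), x)

    def test_train_mode_preserves_expectation(self, rng):
        dr = Dropout(0.3, np.random.default_rng(0))
        x = np.ones((200, 50), dtype=np.float32)
        out = dr.forward(x)
        assert out.mean() == pytest.approx(1.0, abs=0.05)

    def test_invalid_rate(self, rng):
        with pytest.raises(ValueError):
            Dropout(1.0, rng)
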