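"""Classifier model: focal loss closed forms and gradients, architecture
shape arithmetic, end-to-end gradient check, serialization."""

import numpy as np
import pytest

from swnemg import nn
from swnemg.model import (
    CnnLstmClassifier,
    ModelConfig,
    PredictionBatch,
    build_model,
    focal_loss,
    focal_loss_grad,
    gradient_reversal,
    softmax,
)

from helpers import assert_grad_close, fd_gradient


def tiny_config(**kw):
    base = dict(n_input_channels=6, t_seg=12, seed=3)
    base.update(kw)
    return ModelConfig(**base)


class TestSoftmax:
    def test_rows_sum_to_one(self, rng):
        p = softmax(rng.standard_normal((10, 3)))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, rtol=1e-12)

    def test_shift_invariance(self, rng):
        z = rng.standard_normal((4, 5))
        np.testing.assert_allclose(softmax(z), softmax(z + 100.0), rtol=1e-12)


class TestFocalLossClosedForms:
    def test_perfect_predictions_zero(self):
        probs = np.eye(3)[[0, 1, 2, 1]]
        batch = PredictionBatch(probs, np.array([0, 1, 2, 1]))
        assert focal_loss(batch, gamma=2.0) == 0.0

    def test_gamma_zero_single_class_is_cross_entropy_sum(self, rng):
        """All labels in one class: the printed alpha is count/count = 1, so
        gamma = 0 reduces to the plain cross-entropy sum."""
        probs = softmax(rng.standard_normal((8, 3)))
        labels = np.full(8, 2)
        batch = PredictionBatch(probs, labels)
        ce = -np.log(probs[:, 2]).sum()
        assert np.isclose(focal_loss(batch, gamma=0.0), ce, rtol=1e-12)

    def test_hand_computed_quarter_ln_two(self):
        """One sample, true-class probability 1/2, gamma 2:
        alpha = 1, (1 - 1/2)^2 * ln 2 = 0.25 ln 2."""
        probs = np.array([[0.5, 0.25, 0.25]])
        batch = PredictionBatch(probs, np.array([0]))
        assert np.isclose(focal_loss(batch, gamma=2.0), 0.25 * np.log(2.0), rtol=1e-12)

    def test_as_printed_alpha_upweights_majority(self):
        """The printed weight count_l/count gives the majority class the
        larger alpha (documented departure from conventional balancing)."""
        probs = np.full((4, 3), 1 / 3.0)
        labels = np.array([0, 0, 0, 1])
        batch = PredictionBatch(probs, labels)
        ln3 = np.log(3.0)
        expected = (3 * 0.75 + 1 * 0.25) * (2 / 3.0) ** 2 * ln3
        assert np.isclose(focal_loss(batch, gamma=2.0), expected, rtol=1e-12)

    def test_inverse_alpha_mode(self):
        probs = np.full((4, 3), 1 / 3.0)
        labels = np.array([0, 0, 0, 1])
        batch = PredictionBatch(probs, labels)
        # inverse frequencies normalized: alpha_0 = (1/3)/(1/3+1), alpha_1 = 1/(1/3+1)
        a0, a1 = (1 / 3) / (4 / 3), 1 / (4 / 3)
        expected = (3 * a0 + a1) * (2 / 3.0) ** 2 * np.log(3.0)
        assert np.isclose(
            focal_loss(batch, gamma=2.0, alpha_mode="inverse"), expected, rtol=1e-12
        )

    def test_floor_clamp_warns(self):
        probs = np.array([[1.0, 0.0, 0.0]])
        batch = PredictionBatch(probs, np.array([1]))
        with pytest.warns(UserWarning):
            val = focal_loss(batch, gamma=2.0)
        assert np.isfinite(val)


class TestFocalLossGrad:
    @pytest.mark.parametrize("gamma", [0.0, 1.0, 2.0])
    @pytest.mark.parametrize("mode", ["as_printed", "inverse"])
    def test_matches_finite_differences(self, gamma, mode, rng):
        logits = rng.standard_normal((6, 3))
        labels = rng.integers(0, 3, 6)
        loss, dz = focal_loss_grad(logits, labels, gamma, mode)
        num = fd_gradient(
            lambda z: focal_loss_grad(z, labels, gamma, mode)[0], logits
        )
        assert_grad_close(dz, num, rtol=1e-6, atol=1e-9)

    def test_value_matches_focal_loss(self, rng):
        logits = rng.standard_normal((10, 3))
        labels = rng.integers(0, 3, 10)
        loss, _ = focal_loss_grad(logits, labels, 2.0)
        batch = PredictionBatch(softmax(logits), labels)
        assert np.isclose(loss, focal_loss(batch, 2.0), rtol=1e-12)


class TestArchitecture:
    def test_blurpool_placement_shape(self):
        """Block 1's conv lengthens 50 -> 52; blur pooling at the start of
        block 2 downsamples 52 -> 26 before that block's conv."""
        assert nn.BlurPool1d.out_len(52) == 26

    def test_forward_shapes(self):
        cfg = tiny_config()
        model = build_model(cfg)
        x = np.random.default_rng(0).standard_normal((2, 5, 6, 12))
        logits, dom = model.forward(x)
        assert logits.shape == (2, 5, 3)
        assert dom is None

    def test_domain_head_shapes_and_guard(self):
        cfg = tiny_config(with_domain_head=True)
        model = build_model(cfg)
        x = np.random.default_rng(0).standard_normal((1, 4, 6, 12))
        logits, dom = model.forward(x, with_domain=True)
        assert dom.shape == (1, 4, 3)
        plain = build_model(tiny_config())
        with pytest.raises(ValueError):
            plain.forward(x, with_domain=True)

    def test_zero_init_heads_uniform_at_init(self):
        model = build_model(tiny_config())
        x = np.random.default_rng(1).standard_normal((1, 3, 6, 12))
        probs = model.predict_proba(x)
        np.testing.assert_allclose(probs, 1 / 3.0, atol=1e-6)

    def test_channel_mismatch_raises(self):
        model = build_model(tiny_config())
        with pytest.raises(ValueError):
            model.forward(np.zeros((1, 2, 5, 12)))

    def test_eval_deterministic_train_stochastic(self):
        model = build_model(tiny_config())
        # give the zero-init head nonzero weights so logits reflect features
        head_w = model.class_head.params()[2]
        head_w.v[...] = np.random.default_rng(9).standard_normal(head_w.v.shape)
        x = np.random.default_rng(2).standard_normal((1, 4, 6, 12))
        a, _ = model.forward(x, train=False)
        b, _ = model.forward(x, train=False)
        np.testing.assert_array_equal(a, b)
        c, _ = model.forward(x, train=True)
        d, _ = model.forward(x, train=True)
        assert np.abs(c - d).max() > 0  # dropout masks differ


class TestEndToEndGradients:
    def test_full_model_gradcheck(self):
        """Focal-loss gradient through the whole CNN-LSTM (eval mode, so
        dropout is the identity and the map is deterministic)."""
        with nn.default_dtype(np.float64):
            cfg = tiny_config(seed=11)
            model = build_model(cfg)
            rng = np.random.default_rng(4)
            x = rng.standard_normal((2, 3, 6, 12))
            labels = rng.integers(0, 3, 6)
            # nudge the zero-init head so the loss is not at a stationary point
            head_w = model.class_head.params()[2]
            head_w.v[...] = rng.standard_normal(head_w.v.shape) * 0.3

            def total_loss():
                logits, _ = model.forward(x, train=False)
                loss, _ = focal_loss_grad(logits.reshape(6, 3), labels, 2.0)
                return loss

            logits, _ = model.forward(x, train=False)
            loss, dz = focal_loss_grad(logits.reshape(6, 3), labels, 2.0)
            for p in model.params():
                p.g[...] = 0.0
            model.backward(dz.reshape(2, 3, 3))

            eps = 1e-6
            rngp = np.random.default_rng(5)
            for p in model.params():
                flat = p.v.reshape(-1)
                idx = rngp.choice(flat.size, size=min(6, flat.size), replace=False)
                for i in idx:
                    old = flat[i]
                    flat[i] = old + eps
                    lp = total_loss()
                    flat[i] = old - eps
                    lm = total_loss()
                    flat[i] = old
                    num = (lp - lm) / (2 * eps)
                    ana = p.g.reshape(-1)[i]
                    assert abs(ana - num) <= 1e-6 + 1e-4 * abs(num), (
                        f"{p.name}[{i}]: analytic {ana} vs numeric {num}"
                    )

    def test_grl_reverses_domain_gradient_into_extractor(self):
        """With lambda flipped in sign, the domain loss's contribution to
        extractor gradients flips exactly."""
        with nn.default_dtype(np.float64):
            rng = np.random.default_rng(6)
            x = rng.standard_normal((1, 3, 6, 12))
            ydom = np.array([0, 1, 2])
            grads = {}
            for lam in (1.0, -1.0):
                model = build_model(tiny_config(with_domain_head=True, grl_lambda=lam))
                logits, dom = model.forward(x, train=False, with_domain=True)
                _, dzd = focal_loss_grad(dom.reshape(3, 3), ydom, 2.0)
                for p in model.params():
                    p.g[...] = 0.0
                model.backward(np.zeros_like(logits), dzd.reshape(1, 3, 3))
                grads[lam] = [p.g.copy() for p in model.cnn_params()]
            for ga, gb in zip(grads[1.0], grads[-1.0]):
                np.testing.assert_allclose(ga, -gb, atol=1e-12)

    def test_gradient_reversal_forward_identity(self, rng):
        x = rng.standard_normal((4, 5))
        np.testing.assert_array_equal(gradient_reversal(x, 2.0), x)


class TestSerialization:
    def test_save_load_roundtrip(self, tmp_path):
        model = build_model(tiny_config(with_domain_head=True))
        path = tmp_path / "m.npz"
        model.save(path)
        loaded = CnnLstmClassifier.load(path)
        x = np.random.default_rng(7).standard_normal((1, 4, 6, 12))
        a, _ = model.forward(x)
        b, _ = loaded.forward(x)
        np.testing.assert_array_equal(a, b)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(focal_gamma=-1.0)
        with pytest.raises(ValueError):
            ModelConfig(alpha_mode="bogus")
        with pytest.raises(ValueError):
            ModelConfig(dropout_rates=(0.1, 1.0, 0.3, 0.4))
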