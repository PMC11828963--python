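"""Backbone block semantics (residual addition, dense concatenation),
FPN shape contracts, and parameter structure."""

import numpy as np
import pytest

from cryoice import autodiff as ad
from cryoice.model import (BackboneConfig, ModelParameters, build_model,
                           dense_block, forward, group_norm, load_checkpoint,
                           predict_mask, residual_block, save_checkpoint)

RNG = np.random.default_rng(0)


class TestBuildModel:
    def test_same_seed_identical(self, tiny_backbone):
        a = build_model(tiny_backbone, init_seed=5)
        b = build_model(tiny_backbone, init_seed=5)
        assert all(np.array_equal(a.params[k].data, b.params[k].data)
                   for k in a.params)

    def test_name_set_invariant_to_seed(self, tiny_backbone):
        a = build_model(tiny_backbone, init_seed=1)
        b = build_model(tiny_backbone, init_seed=2)
        assert a.names() == b.names()
        assert any(not np.array_equal(a.params[k].data, b.params[k].data)
                   for k in a.params)

    def test_parameter_count_closed_form(self):
        """Hand-counted parameters for a minimal residual FPN."""
        cfg = BackboneConfig(family="residual", stage_channels=(4, 8, 16),
                             blocks_per_stage=(1, 1, 1), fpn_channels=8)
        mp = build_model(cfg, 0)
        expected = 0
        expected += 4 * 1 * 9 + 4 + 4                       # stem conv + gn
        prev = 4
        for ch in (4, 8, 16):
            expected += ch * prev * 9 + 2 * ch              # downsample + gn
            expected += 2 * (ch * ch * 9) + 4 * ch          # residual block
            expected += 8 * ch                              # lateral 1x1
            prev = ch
        expected += 8 * 8 * 9 + 2 * 8                       # head conv + gn
        expected += 1 * 8 + 1                               # head out + bias
        assert mp.n_parameters() == expected

    def test_dense_requires_growth_rate(self):
        with pytest.raises(ValueError, match="growth_rate"):
            BackboneConfig(family="dense", stage_channels=(4, 8, 16),
                           blocks_per_stage=(1, 1, 1))

    def test_too_few_stages_rejected(self):
        with pytest.raises(ValueError, match="3 pyramid stages"):
            BackboneConfig(stage_channels=(4, 8), blocks_per_stage=(1, 1))

    def test_checkpoint_roundtrip(self, tmp_path, tiny_theta):
        p = tmp_path / "ckpt.npz"
        save_checkpoint(p, tiny_theta)
        back = load_checkpoint(p)
        assert back.config == tiny_theta.config
        assert all(np.array_equal(back.params[k].data,
                                  tiny_theta.params[k].data)
                   for k in tiny_theta.params)


class TestResidualBlock:
    def _weights(self, c, zero=False):
        mk = (lambda *s: np.zeros(s)) if zero else \
             (lambda *s: RNG.normal(0, 0.3, size=s))
        return {
            "conv1.w": ad.Tensor(mk(c, c, 3, 3)),
            "gn1.w": ad.Tensor(np.ones(c)), "gn1.b": ad.Tensor(np.zeros(c)),
            "conv2.w": ad.Tensor(mk(c, c, 3, 3)),
            "gn2.w": ad.Tensor(np.ones(c)), "gn2.b": ad.Tensor(np.zeros(c)),
        }

    def test_zero_residual_is_identity_on_nonnegative(self):
        """With F ≡ 0 the block reduces to ReLU(x) = x for x >= 0."""
        x = ad.Tensor(np.abs(RNG.normal(size=(1, 4, 6, 6))))
        y = residual_block(x, self._weights(4, zero=True))
        np.testing.assert_allclose(y.data, x.data, atol=1e-12)

    def test_output_is_residual_plus_input(self):
        """y equals F(x) + x: recompute F along the non-skip path."""
        c = 4
        w = self._weights(c)
        x = ad.Tensor(np.abs(RNG.normal(size=(2, c, 6, 6))) + 0.5)
        y = residual_block(x, w)
        h = ad.conv2d(x, w["conv1.w"], 1, 1)
        h = ad.relu(group_norm(h, w["gn1.w"], w["gn1.b"]))
        h = ad.conv2d(h, w["conv2.w"], 1, 1)
        f = group_norm(h, w["gn2.w"], w["gn2.b"])
        np.testing.assert_allclose(y.data,
                                   np.maximum(f.data + x.data, 0.0), atol=1e-12)

    def test_jacobian_includes_identity_path(self):
        """d<c, block(x)>/dx matches finite differences (skip contributes the
        identity term)."""
        c = 2
        w = self._weights(c)
        xv = np.abs(RNG.normal(size=(1, c, 5, 5))) + 0.5
        cot = RNG.normal(size=xv.shape)
        xt = ad.Tensor(xv, requires_grad=True)
        (g,) = ad.grad(ad.tsum(residual_block(xt, w) * ad.Tensor(cot)), [xt])
        eps = 1e-6
        for idx in [(0, 0, 2, 2), (0, 1, 1, 3), (0, 0, 4, 0)]:
            x1, x2 = xv.copy(), xv.copy()
            x1[idx] += eps
            x2[idx] -= eps
            num = ((residual_block(ad.Tensor(x1), w).data
                    - residual_block(ad.Tensor(x2), w).data) * cot).sum() / (2 * eps)
            assert g.data[idx] == pytest.approx(num, abs=1e-4)


class TestDenseBlock:
    def _weights(self, cin, layers, growth, zero_layer=None):
        w = {}
        for j in range(layers):
            c_j = cin + j * growth
            data = np.zeros((growth, c_j, 3, 3)) if j == zero_layer else \
                RNG.normal(0, 0.3, size=(growth, c_j, 3, 3))
            w[f"dense{j}.w"] = ad.Tensor(data)
            w[f"dense{j}.gn.w"] = ad.Tensor(np.ones(growth))
            w[f"dense{j}.gn.b"] = ad.Tensor(np.zeros(growth))
        return w

    def test_channel_count_closed_form(self):
        x = ad.Tensor(RNG.normal(size=(1, 8, 6, 6)))
        y = dense_block(x, self._weights(8, 2, 4), layers=2, growth=4)
        assert y.shape == (1, 16, 6, 6)

    def test_concatenation_preserves_input_slots(self):
        x = ad.Tensor(RNG.normal(size=(1, 3, 6, 6)))
        y = dense_block(x, self._weights(3, 1, 2), layers=1, growth=2)
        np.testing.assert_array_equal(y.data[:, :3], x.data)

    def test_earlier_layer_feeds_later_layer(self):
        """Zeroing layer 0's weights changes layer 1's input and output."""
        x = ad.Tensor(RNG.normal(size=(1, 4, 6, 6)))
        w_full = self._weights(4, 2, 3)
        w_zero = {k: (ad.Tensor(np.zeros(v.shape))
                      if k == "dense0.w" else v)
                  for k, v in w_full.items()}
        y_full = dense_block(x, w_full, layers=2, growth=3)
        y_zero = dense_block(x, w_zero, layers=2, growth=3)
        # last `growth` channels are layer 1's output: must differ
        assert not np.allclose(y_full.data[:, -3:], y_zero.data[:, -3:])


class TestForward:
    @pytest.mark.parametrize("shape", [(32, 32), (32, 48), (64, 64)])
    @pytest.mark.parametrize("family", ["residual", "dense"])
    def test_output_matches_input_spatial_dims(self, shape, family):
        kw = dict(stage_channels=(4, 8, 8), blocks_per_stage=(1, 1, 1),
                  fpn_channels=4, family=family)
        if family == "dense":
            kw["growth_rate"] = 4
        theta = build_model(BackboneConfig(**kw), 0)
        x = RNG.normal(size=(2, *shape))
        out = forward(theta, x)
        assert out.shape == (2, *shape)

    def test_indivisible_input_rejected(self, tiny_theta):
        with pytest.raises(ValueError, match="divisible"):
            forward(tiny_theta, RNG.normal(size=(1, 30, 32)))

    def test_zeroed_head_outputs_bias(self, tiny_backbone):
        theta = build_model(tiny_backbone, 0)
        theta.params["head.out.w"] = ad.Tensor(
            np.zeros(theta.params["head.out.w"].shape))
        theta.params["head.out.b"] = ad.Tensor(np.array([-1.7]))
        out = forward(theta, RNG.normal(size=(1, 32, 32)))
        np.testing.assert_allclose(out.data, -1.7, atol=1e-12)

    def test_model_responds_to_contrast(self, tiny_theta):
        x = RNG.normal(size=(1, 32, 32))
        a = forward(tiny_theta, x)
        b = forward(tiny_theta, 2.0 * x)
        assert not np.allclose(a.data, b.data)


class TestPredictMask:
    def test_strongly_negative_logits_give_empty_mask(self):
        mask = predict_mask(np.full((8, 8), -100.0))
        assert mask.mask.sum() == 0

    def test_zero_logit_at_half_threshold_is_foreground(self):
        mask = predict_mask(np.zeros((2, 2)), threshold=0.5)
        assert mask.mask.sum() == 4  # sigmoid(0) = 0.5 >= 0.5

    def test_matches_elementwise_recomputation(self):
        logits = RNG.normal(size=(16, 16))
        thr = 0.3
        mask = predict_mask(logits, threshold=thr)
        expected = (1.0 / (1.0 + np.exp(-logits)) >= thr).astype(np.uint8)
        np.testing.assert_array_equal(mask.mask, expected)
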