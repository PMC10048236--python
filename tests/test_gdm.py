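"""Decision module: attention-branch semantics against a brute-force
double-loop oracle, the combination rules, pooled-descriptor arithmetic and
the softmax head."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fruitscan.gdm import (
    GDM,
    BaselineLogisticDecision,
    ConfigurationError,
    GSAMConfig,
    attention_branch,
    attention_scores,
    baseline_features,
    combine_add,
    combine_weighted,
    gsam_concat,
    pooled_descriptor,
)
from fruitscan import nn


def attention_oracle(features, scores, orientation):
    """Explicit double loop: softmax weights along the attended axis, then a
    weighted sum of feature vectors broadcast back over that axis."""
    n, c, h, w = features.shape
    out = np.zeros_like(features, dtype=np.float64)
    for b in range(n):
        if orientation == "vertical":
            for j in range(w):
                e = np.exp(scores[b, :, j] - scores[b, :, j].max())
                alpha = e / e.sum()
                ctx = sum(alpha[i] * features[b, :, i, j] for i in range(h))
                for i in range(h):
                    out[b, :, i, j] = ctx
        else:
            for i in range(h):
                e = np.exp(scores[b, i, :] - scores[b, i, :].max())
                alpha = e / e.sum()
                ctx = sum(alpha[j] * features[b, :, i, j] for j in range(w))
                for j in range(w):
                    out[b, :, i, j] = ctx
    return out


class TestAttentionBranch:
    def test_uniform_scores_give_axis_mean(self, rng):
        f = rng.normal(0, 1, (1, 3, 4, 5))
        out = attention_branch(f, "vertical")
        assert np.allclose(out, f.mean(axis=2, keepdims=True), atol=1e-6)
        out_h = attention_branch(f, "horizontal")
        assert np.allclose(out_h, f.mean(axis=3, keepdims=True), atol=1e-6)

    def test_single_row_is_identity(self, rng):
        f = rng.normal(0, 1, (1, 2, 1, 6))
        s = rng.normal(0, 1, (1, 1, 6))
        assert np.allclose(attention_branch(f, "vertical", s), f, atol=1e-7)

    @pytest.mark.parametrize("orientation", ["vertical", "horizontal"])
    def test_matches_double_loop_oracle(self, orientation, rng):
        f = rng.normal(0, 1, (2, 1, 3, 2))
        s = rng.normal(0, 2, (2, 3, 2))
        out = attention_branch(f, orientation, s)
        assert np.allclose(out, attention_oracle(f, s, orientation), atol=1e-6)

    def test_softmax_weights_sum_to_one_per_slice(self, rng):
        s = rng.normal(0, 3, (1, 5, 4))
        alpha = nn.softmax(s, axis=1)
        assert np.allclose(alpha.sum(axis=1), 1.0, atol=1e-6)


class TestCombine:
    def test_add_is_elementwise_sum(self, rng):
        a, b = rng.normal(0, 1, (1, 2, 3, 3)), rng.normal(0, 1, (1, 2, 3, 3))
        assert np.array_equal(combine_add(a, b), a + b)
        assert np.allclose(combine_add(a, -a), 0)

    def test_weighted_defaults_map_unit_constants_to_084(self):
        c1, c0 = np.ones((1, 1, 2, 2)), np.zeros((1, 1, 2, 2))
        out = combine_weighted(c1, c0, GSAMConfig())
        assert np.allclose(out, 0.84)

    def test_weighted_collapses_when_equal(self, rng):
        c = rng.normal(0, 1, (1, 2, 3, 3))
        out = combine_weighted(c, c.copy(), GSAMConfig(A=0.3, B=0.7))
        assert np.allclose(out, c)

    def test_boundary_coefficient_is_pure_max(self, rng):
        a, b = rng.normal(0, 1, (1, 1, 4, 4)), rng.normal(0, 1, (1, 1, 4, 4))
        out = combine_weighted(a, b, GSAMConfig(A=1.0, B=0.0))
        assert np.array_equal(out, np.maximum(a, b))

    def test_invalid_weights_rejected(self):
        with pytest.raises(ConfigurationError):
            combine_weighted(np.zeros((1, 1, 1, 1)), np.zeros((1, 1, 1, 1)),
                             GSAMConfig(A=0.9, B=0.3))

    @settings(deadline=None, max_examples=30)
    @given(st.floats(0.0, 1.0), st.integers(0, 2**31 - 1))
    def test_weighted_symmetric_and_bounded(self, a_coef, seed):
        rng = np.random.default_rng(seed)
        cfg = GSAMConfig(A=a_coef, B=1.0 - a_coef)
        x, y = rng.normal(0, 1, (1, 1, 3, 3)), rng.normal(0, 1, (1, 1, 3, 3))
        w1 = combine_weighted(x, y, cfg)
        w2 = combine_weighted(y, x, cfg)
        assert np.allclose(w1, w2, atol=1e-12)
        assert np.all(w1 >= np.minimum(x, y) - 1e-12)
        assert np.all(w1 <= np.maximum(x, y) + 1e-12)


class TestGSAM:
    def test_concatenation_quadruples_channels(self, rng):
        f = rng.normal(0, 1, (1, 5, 4, 4))
        c_i = attention_branch(f, "vertical")
        c_ii = attention_branch(f, "horizontal")
        assert gsam_concat(c_i, c_ii, GSAMConfig()).shape == (1, 20, 4, 4)

    def test_full_module_matches_brute_force_oracle(self, rng):
        """End-to-end GSAM on random 4x4x2 features equals the explicit-loop
        composition of both attention branches, addition, the A/B max-min
        blend, concatenation and the 1x1 fusion."""
        gdm = GDM(channels=2, gsam=GSAMConfig(), rng=np.random.default_rng(5),
                  init_std=0.5)
        f = rng.normal(0, 1, (1, 2, 4, 4)).astype(np.float32)
        mask = rng.uniform(0, 1, (1, 1, 2, 2)).astype(np.float32)
        out = gdm.forward(f, mask)

        s_v = attention_scores(f.astype(np.float64),
                               gdm.proj_v.weight.value[0].astype(np.float64),
                               float(gdm.proj_v.bias.value[0]))
        s_h = attention_scores(f.astype(np.float64),
                               gdm.proj_h.weight.value[0].astype(np.float64),
                               float(gdm.proj_h.bias.value[0]))
        c_i = attention_oracle(f, s_v, "vertical")
        c_ii = attention_oracle(f, s_h, "horizontal")
        concat = np.concatenate(
            [c_i, c_ii, c_i + c_ii,
             0.84 * np.maximum(c_i, c_ii) + 0.16 * np.minimum(c_i, c_ii)], axis=1)
        w = gdm.fusion.weight.value.astype(np.float64)  # (C, 4C)
        fused = np.einsum("oc,nchw->nohw", w, concat) \
            + gdm.fusion.bias.value[None, :, None, None]
        assert np.allclose(out["fused"], fused, atol=1e-5)
        # descriptor from the oracle path
        desc = np.concatenate([fused.max(axis=(2, 3)), fused.mean(axis=(2, 3)),
                               mask.max(axis=(2, 3)), mask.mean(axis=(2, 3))],
                              axis=1)
        assert np.allclose(out["descriptor"], desc, atol=1e-5)

    def test_zero_features_give_bias_only_fusion(self):
        gdm = GDM(channels=3, gsam=GSAMConfig(), rng=np.random.default_rng(1))
        gdm.fusion.bias.value[...] = [0.1, -0.2, 0.3]
        out = gdm.forward(np.zeros((1, 3, 4, 4), dtype=np.float32),
                          np.zeros((1, 1, 2, 2), dtype=np.float32))
        assert np.allclose(out["fused"][0, :, 0, 0], [0.1, -0.2, 0.3], atol=1e-7)


class TestPooledDescriptor:
    def test_default_width_gives_66_neurons(self, rng):
        f = rng.normal(0, 1, (1, 32, 8, 8))
        mask = rng.uniform(0, 1, (1, 1, 8, 8))
        assert pooled_descriptor(f, mask).shape == (1, 66)

    @pytest.mark.parametrize("k", [2, 8, 32])
    def test_length_is_2k_plus_2(self, k, rng):
        f = rng.normal(0, 1, (1, k, 4, 4))
        mask = rng.uniform(0, 1, (1, 1, 4, 4))
        assert pooled_descriptor(f, mask).shape == (1, 2 * k + 2)

    def test_constant_features_pool_to_value(self):
        f = np.full((1, 3, 5, 5), 2.5)
        mask = np.full((1, 1, 5, 5), 0.25)
        desc = pooled_descriptor(f, mask)[0]
        assert np.allclose(desc[:6], 2.5)
        assert np.allclose(desc[6:], 0.25)

    def test_single_hot_mask_pooling(self):
        mask = np.zeros((1, 1, 64, 64))
        mask[0, 0, 10, 20] = 1.0
        desc = pooled_descriptor(np.zeros((1, 2, 64, 64)), mask)[0]
        assert desc[-2] == 1.0
        assert desc[-1] == pytest.approx(1 / 4096)


class TestDecide:
    def test_zero_weight_head_gives_half(self, rng):
        gdm = GDM(channels=2, gsam=GSAMConfig(), rng=np.random.default_rng(0))
        gdm.fc.weight.value[...] = 0
        gdm.fc.bias.value[...] = 0
        score = gdm.decide(rng.normal(0, 1, (1, 2, 4, 4)).astype(np.float32),
                           rng.uniform(0, 1, (1, 1, 2, 2)).astype(np.float32))
        assert score[0] == pytest.approx(0.5)

    def test_probabilities_sum_to_one(self, rng):
        gdm = GDM(channels=2, gsam=GSAMConfig(), rng=np.random.default_rng(2),
                  init_std=0.5)
        out = gdm.forward(rng.normal(0, 1, (3, 2, 4, 4)).astype(np.float32),
                          rng.uniform(0, 1, (3, 1, 2, 2)).astype(np.float32))
        assert np.allclose(out["probs"].sum(axis=1), 1.0, atol=1e-6)

    def test_gradient_matches_finite_differences(self, rng):
        gdm = GDM(channels=2, gsam=GSAMConfig(), rng=np.random.default_rng(3),
                  init_std=0.3)
        f = rng.normal(0, 1, (1, 2, 3, 3)).astype(np.float32)
        mask = rng.uniform(0.1, 0.9, (1, 1, 2, 2)).astype(np.float32)
        target = np.array([1])

        out = gdm.forward(f, mask)
        _, d_logits = nn.softmax_cross_entropy(out["logits"], target)
        gdm.zero_grad()
        gdm.backward(d_logits)

        eps = 1e-3
        for p in gdm.params():
            flat, grad = p.value.reshape(-1), p.grad.reshape(-1)
            for i in range(0, flat.size, max(1, flat.size // 4)):
                old = flat[i]
                flat[i] = old + eps
                lp = nn.softmax_cross_entropy(gdm.forward(f, mask)["logits"], target)[0]
                flat[i] = old - eps
                lm = nn.softmax_cross_entropy(gdm.forward(f, mask)["logits"], target)[0]
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(float(grad[i]), abs=2e-3)


class TestBaseline:
    def test_features_are_pooling_only(self, rng):
        seg = rng.normal(0, 1, (2, 2, 8, 8))
        mask = rng.uniform(0, 1, (2, 1, 4, 4))
        feats = baseline_features(seg, mask)
        assert feats.shape == (2, 4)  # max/avg of P(defect), max/avg of mask

    def test_separable_features_fit_perfectly(self):
        feats = np.array([[0.9, 0.8, 1, 0.5], [0.95, 0.85, 1, 0.6],
                          [0.1, 0.05, 0, 0.01], [0.12, 0.06, 0, 0.02]])
        labels = np.array([1, 1, 0, 0])
        clf = BaselineLogisticDecision(seed=0).fit(feats, labels)
        pred = (clf.decide(feats) >= 0.5).astype(int)
        assert np.array_equal(pred, labels)

    def test_unfitted_baseline_raises(self):
        with pytest.raises(RuntimeError):
            BaselineLogisticDecision().decide(np.zeros((1, 4)))
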