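"""Global decision module: image-level defect classification on top of the
frozen segmentation network.

The module takes the segmentation network's two outputs — the C-channel
final feature map and the 1/8-resolution mask — and produces a per-image
defect probability:

1. A global spatial attention mechanism (GSAM) re-weights the feature map.
   A learned 1x1 projection scores every position; the vertical branch
   softmax-normalizes scores over rows within each column and broadcasts the
   weighted sum of row feature-vectors back over that column (the horizontal
   branch is symmetric over columns). The two contexts are combined three
   ways: elementwise addition, and an A*max + B*min blend with A + B = 1
   (defaults A=0.84, B=0.16); contexts and combinations are concatenated to
   4C channels and a learned 1x1 fusion convolution restores C channels.
2. Global max- and average-pooling of the attended features (C values each)
   are concatenated with the global max and average of the mask, giving a
   descriptor of length 2C + 2 (66 for C = 32).
3. A fully connected layer maps the descriptor to 2 logits; softmax gives
   P(defective).

A pooled-descriptor + logistic-regression baseline (the "no decision module"
ablation) is provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression

from . import nn
from .nn import Conv2d, Linear, softmax


class ConfigurationError(ValueError):
    pass


@dataclass
class GSAMConfig:
    """Weights of the max (A) and min (B) blend branches; A + B must be 1."""

    A: float = 0.84
    B: float = 0.16

    def validate(self) -> None:
        if abs(self.A + self.B - 1.0) > 1e-9:
            raise ConfigurationError("GSAM weights must satisfy A + B = 1")
        if not (0 <= self.A <= 1 and 0 <= self.B <= 1):
            raise ConfigurationError("GSAM weights must lie in [0, 1]")


# ---------------------------------------------------------------------------
# functional GSAM pieces (shared by the trainable module and by tests)


def attention_scores(features: np.ndarray, weight: np.ndarray, bias: float) -> np.ndarray:
    """Learned 1x1 projection of (N, C, H, W) features to scalar scores."""
    return np.einsum("nchw,c->nhw", features, weight, optimize=True) + bias


def attention_branch(features: np.ndarray, orientation: str,
                     scores: np.ndarray | None = None) -> np.ndarray:
    """One attention context map.

    ``orientation="vertical"``: scores are softmax-normalized over rows within
    each column; the context is the weighted sum of row feature-vectors,
    broadcast back over that column. ``"horizontal"`` is symmetric over
    columns. With ``scores=None`` uniform scores are used (the context is the
    plain mean along the attended axis).
    """
    n, c, h, w = features.shape
    if scores is None:
        scores = np.zeros((n, h, w), dtype=features.dtype)
    if orientation == "vertical":
        axis = 1  # rows of the (N, H, W) score map
    elif orientation == "horizontal":
        axis = 2
    else:
        raise ValueError("orientation must be 'vertical' or 'horizontal'")
    alpha = softmax(scores.astype(np.float64), axis=axis)
    if orientation == "vertical":
        ctx = np.einsum("nhw,nchw->ncw", alpha, features, optimize=True)
        out = np.broadcast_to(ctx[:, :, None, :], features.shape)
    else:
        ctx = np.einsum("nhw,nchw->nch", alpha, features, optimize=True)
        out = np.broadcast_to(ctx[:, :, :, None], features.shape)
    return np.ascontiguousarray(out, dtype=features.dtype)


def combine_add(c_i: np.ndarray, c_ii: np.ndarray) -> np.ndarray:
    """Elementwise sum of the two attention contexts."""
    if c_i.shape != c_ii.shape:
        raise ValueError("context shapes must match")
    return c_i + c_ii


def combine_weighted(c_i: np.ndarray, c_ii: np.ndarray, config: GSAMConfig) -> np.ndarray:
    """Elementwise A*max(C_I, C_II) + B*min(C_I, C_II)."""
    config.validate()
    if c_i.shape != c_ii.shape:
        raise ValueError("context shapes must match")
    return config.A * np.maximum(c_i, c_ii) + config.B * np.minimum(c_i, c_ii)


def gsam_concat(c_i: np.ndarray, c_ii: np.ndarray, config: GSAMConfig) -> np.ndarray:
    """Concatenate (C_I, C_II, add, weight) along channels -> 4C channels."""
    return np.concatenate(
        [c_i, c_ii, combine_add(c_i, c_ii), combine_weighted(c_i, c_ii, config)],
        axis=1,
    )


def pooled_descriptor(seg_features: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Concatenate [per-channel global max (K), per-channel global average
    (K), mask global max (1), mask global average (1)] -> (N, 2K + 2)."""
    if seg_features.ndim != 4 or mask.ndim != 4 or mask.shape[1] != 1:
        raise ValueError("expected (N, K, H, W) features and (N, 1, h, w) mask")
    f_max = seg_features.max(axis=(2, 3))
    f_avg = seg_features.mean(axis=(2, 3))
    m_max = mask.max(axis=(2, 3))
    m_avg = mask.mean(axis=(2, 3))
    return np.concatenate([f_max, f_avg, m_max, m_avg], axis=1)


# ---------------------------------------------------------------------------
# trainable module


class GDM:
    """Trainable decision head: GSAM -> pooled descriptor -> FC -> softmax."""

    def __init__(self, channels: int, gsam: GSAMConfig, rng: np.random.Generator,
                 init_std: float = 0.01):
        gsam.validate()
        self.channels = channels
        self.gsam_config = gsam
        self.proj_v = Conv2d(channels, 1, 1, rng, role="proj", init_std=init_std)
        self.proj_h = Conv2d(channels, 1, 1, rng, role="proj", init_std=init_std)
        self.fusion = Conv2d(4 * channels, channels, 1, rng, role="fusion",
                             init_std=init_std)
        self.fc = Linear(2 * channels + 2, 2, rng, init_std=init_std)
        self._cache: dict | None = None

    def params(self) -> list[nn.Param]:
        return (self.proj_v.params() + self.proj_h.params()
                + self.fusion.params() + self.fc.params())

    def decay_mask(self) -> list[bool]:
        return [True, False] * 4

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    # -- forward ------------------------------------------------------------

    def forward(self, features: np.ndarray, mask: np.ndarray) -> dict:
        n, c, h, w = features.shape
        if c != self.channels:
            raise ValueError(f"expected {self.channels} feature channels, got {c}")
        s_v = self.proj_v.forward(features)[:, 0]  # (N, H, W)
        s_h = self.proj_h.forward(features)[:, 0]
        a_v = softmax(s_v.astype(np.float64), axis=1).astype(nn.DTYPE)
        a_h = softmax(s_h.astype(np.float64), axis=2).astype(nn.DTYPE)
        ctx_v = np.einsum("nhw,nchw->ncw", a_v, features, optimize=True)
        ctx_h = np.einsum("nhw,nchw->nch", a_h, features, optimize=True)
        c_i = np.ascontiguousarray(np.broadcast_to(ctx_v[:, :, None, :], features.shape))
        c_ii = np.ascontiguousarray(np.broadcast_to(ctx_h[:, :, :, None], features.shape))
        concat = gsam_concat(c_i, c_ii, self.gsam_config)
        fused = self.fusion.forward(concat)
        desc = pooled_descriptor(fused, mask)
        logits = self.fc.forward(desc)
        probs = softmax(logits, axis=1)
        self._cache = {
            "features": features, "mask": mask,
            "a_v": a_v, "a_h": a_h, "c_i": c_i, "c_ii": c_ii,
            "fused": fused, "desc": desc,
        }
        return {"logits": logits, "probs": probs, "score": probs[:, 1],
                "descriptor": desc, "fused": fused, "c_i": c_i, "c_ii": c_ii}

    def decide(self, features: np.ndarray, mask: np.ndarray) -> np.ndarray:
        """Per-image probability of the defective class."""
        return self.forward(features, mask)["score"]

    # -- backward -----------------------------------------------------------

    def backward(self, d_logits: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Accumulate gradients for all decision-head parameters; returns
        (d_features, d_mask) for completeness (unused when the backbone is
        frozen)."""
        cache = self._cache
        F = cache["features"]
        n, c, h, w = F.shape
        d_desc = self.fc.backward(d_logits)

        # un-pool the descriptor gradient
        fused = cache["fused"]
        d_fused = np.zeros_like(fused)
        d_fmax, d_favg = d_desc[:, :c], d_desc[:, c : 2 * c]
        flat = fused.reshape(n, c, h * w)
        idx = flat.argmax(axis=2)
        np.put_along_axis(
            d_fused.reshape(n, c, h * w), idx[:, :, None], d_fmax[:, :, None], axis=2
        )
        d_fused += (d_favg / (h * w))[:, :, None, None]

        mask = cache["mask"]
        d_mask = np.zeros_like(mask)
        mh, mw = mask.shape[2:]
        mflat = mask.reshape(n, 1, mh * mw)
        midx = mflat.argmax(axis=2)
        dm = d_mask.reshape(n, 1, mh * mw)
        np.put_along_axis(dm, midx[:, :, None], d_desc[:, 2 * c : 2 * c + 1, None], axis=2)
        d_mask += (d_desc[:, 2 * c + 1 : 2 * c + 2] / (mh * mw))[:, :, None, None]

        d_concat = self.fusion.backward(d_fused)
        d1, d2, d3, d4 = np.split(d_concat, 4, axis=1)
        A, B = self.gsam_config.A, self.gsam_config.B
        c_i, c_ii = cache["c_i"], cache["c_ii"]
        i_is_max = c_i >= c_ii
        d_ci = d1 + d3 + np.where(i_is_max, A * d4, B * d4)
        d_cii = d2 + d3 + np.where(i_is_max, B * d4, A * d4)

        d_features = np.zeros_like(F)
        # vertical branch: context broadcast over rows of each column
        g = d_ci.sum(axis=2)  # (N, C, W)
        d_features += np.einsum("nhw,ncw->nchw", cache["a_v"], g, optimize=True)
        da = np.einsum("ncw,nchw->nhw", g, F, optimize=True)
        ds = cache["a_v"] * (da - (cache["a_v"] * da).sum(axis=1, keepdims=True))
        d_features += self.proj_v.backward(ds[:, None])
        # horizontal branch
        g = d_cii.sum(axis=3)  # (N, C, H)
        d_features += np.einsum("nhw,nch->nchw", cache["a_h"], g, optimize=True)
        da = np.einsum("nch,nchw->nhw", g, F, optimize=True)
        ds = cache["a_h"] * (da - (cache["a_h"] * da).sum(axis=2, keepdims=True))
        d_features += self.proj_h.backward(ds[:, None])
        return d_features, d_mask


# ---------------------------------------------------------------------------
# logistic-regression baseline (the "no decision module" ablation)


def baseline_features(seg_logits: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Short pooled descriptor from the raw segmentation output: global max
    and average of the per-pixel defect probability plus the pooled mask."""
    p_defect = softmax(seg_logits.astype(np.float64), axis=1)[:, 1:2]
    return np.concatenate(
        [
            p_defect.max(axis=(2, 3)),
            p_defect.mean(axis=(2, 3)),
            mask.max(axis=(2, 3)),
            mask.mean(axis=(2, 3)),
        ],
        axis=1,
    )


class BaselineLogisticDecision:
    """Pooled descriptor + logistic regression on a frozen backbone."""

    def __init__(self, seed: int = 0):
        self._clf = LogisticRegression(max_iter=1000, random_state=seed)
        self._fitted = False

    def fit(self, features: np.ndarray, labels: np.ndarray) -> "BaselineLogisticDecision":
        self._clf.fit(features, labels)
        self._fitted = True
        return self

    def decide(self, features: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("baseline called before fitting (train the "
                               "segmentation network and fit the baseline first)")
        return self._clf.predict_proba(features)[:, 1]
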