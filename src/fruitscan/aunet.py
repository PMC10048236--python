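"""Encoder-decoder defect segmentation network with depth-dependent
convolution blocks and a 1/8-resolution mask shortcut.

Architecture (defaults):

* Encoder: 4 levels. Level ``l`` applies ``depconv_counts[l]`` repetitions of
  (5x5 conv -> batch norm -> ReLU) with ``C0 * 2**l`` output channels; levels
  are separated by three 2x2 max-poolings, so the bottleneck sits at 1/8 of
  the input resolution. Stacking more convolutions at deeper levels grows the
  receptive-field capacity where the resolution is low; because channels
  double exactly as the resolution halves, the multiply-add cost per
  convolution is balanced across levels.
* Mask shortcut: an *additional* 1x1 convolution on the bottleneck followed
  by a logistic squashing produces a single-channel defect map at 1/8
  resolution — both an input to the decision module and an auxiliary
  supervision target.
* Decoder: the mask is concatenated onto the bottleneck, then three
  (2x2 transposed conv -> concat skip -> 3x3 conv + BN + ReLU) stages restore
  full resolution; a final 1x1 convolution yields 2-class per-pixel logits.

Counting encoder convolutions (1+2+3+4), decoder convolutions (3) and the
segmentation head (1) gives 14 convolutional layers; the 3 up-convolutions
and the additional mask projection are tallied separately. The bottleneck is
the 13th layer in forward order when convolutions and poolings are counted
together (1+1+2+1+3+1+4).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Conv2d, ConvTranspose2d, MaxPool2d, BatchNorm2d, ReLU, relu  # noqa: F401 (re-exported contracts)
from .nn import batch_normalize, BNState  # noqa: F401


class ArchitectureError(ValueError):
    pass


@dataclass
class ArchConfig:
    """Architecture hyperparameters.

    ``base_channels`` (C0) is never printed in the network description; it is
    pinned to 32 by the decision module's 66-neuron pooled descriptor
    (2*C0 + 2 = 66).
    """

    input_side: int = 512
    base_channels: int = 32
    depth: int = 4  # levels; depth-1 poolings
    depconv_counts: tuple[int, ...] = (1, 2, 3, 4)
    depconv_kernel: int = 5
    decoder_kernel: int = 3
    mask_kernel: int = 1
    num_classes: int = 2
    bn_epsilon: float = 1e-5
    plain_unet_mode: bool = False  # ablation: 2 ordinary convs per level
    init_std: float = 0.01

    def validate(self) -> None:
        if self.input_side % 2 ** (self.depth - 1) != 0:
            raise ArchitectureError("input_side must be divisible by 2**(depth-1)")
        if len(self.depconv_counts) != self.depth:
            raise ArchitectureError("depconv_counts length must equal depth")
        if self.num_classes != 2:
            raise ArchitectureError("the segmentation head is binary (2 classes)")

    def level_channels(self, level: int) -> int:
        return self.base_channels * 2**level

    def effective_counts(self) -> tuple[int, ...]:
        if self.plain_unet_mode:
            return (2,) * self.depth
        return self.depconv_counts


class AUNet:
    """The segmentation network. Forward returns a cache dict consumed by the
    decision module and by the backward pass."""

    def __init__(self, config: ArchConfig, rng: np.random.Generator):
        config.validate()
        self.config = config
        c = config
        counts = c.effective_counts()
        kernel = 3 if c.plain_unet_mode else c.depconv_kernel

        self.enc_convs: list[list[Conv2d]] = []
        self.enc_bns: list[list[BatchNorm2d]] = []
        c_in = 3
        for level in range(c.depth):
            c_out = c.level_channels(level)
            convs, bns = [], []
            for _ in range(counts[level]):
                convs.append(Conv2d(c_in, c_out, kernel, rng, role="counted",
                                    init_std=c.init_std))
                bns.append(BatchNorm2d(c_out, epsilon=c.bn_epsilon))
                c_in = c_out
            self.enc_convs.append(convs)
            self.enc_bns.append(bns)
        self.pools = [MaxPool2d() for _ in range(c.depth - 1)]

        bott = c.level_channels(c.depth - 1)
        self.mask_conv = Conv2d(bott, 1, c.mask_kernel, rng, role="mask",
                                init_std=c.init_std)

        self.upconvs: list[ConvTranspose2d] = []
        self.dec_convs: list[Conv2d] = []
        self.dec_bns: list[BatchNorm2d] = []
        c_prev = bott + 1  # mask channel fused onto the bottleneck
        for level in range(c.depth - 2, -1, -1):
            c_out = c.level_channels(level)
            self.upconvs.append(ConvTranspose2d(c_prev, c_out, rng, init_std=c.init_std))
            self.dec_convs.append(Conv2d(2 * c_out, c_out, c.decoder_kernel, rng,
                                         role="counted", init_std=c.init_std))
            self.dec_bns.append(BatchNorm2d(c_out, epsilon=c.bn_epsilon))
            c_prev = c_out
        self.seg_head = Conv2d(c.base_channels, c.num_classes, 1, rng, role="counted",
                               init_std=c.init_std)

    # -- parameter plumbing -------------------------------------------------

    def layers(self) -> list:
        out: list = []
        for convs, bns in zip(self.enc_convs, self.enc_bns):
            for cv, bn in zip(convs, bns):
                out += [cv, bn]
        out.append(self.mask_conv)
        for up, cv, bn in zip(self.upconvs, self.dec_convs, self.dec_bns):
            out += [up, cv, bn]
        out.append(self.seg_head)
        return out

    def params(self) -> list[nn.Param]:
        return [p for layer in self.layers() for p in layer.params()]

    def decay_mask(self) -> list[bool]:
        mask = []
        for layer in self.layers():
            if isinstance(layer, BatchNorm2d):
                mask += [False, False]  # gamma, beta
            else:
                mask += [True, False]  # weight, bias
        return mask

    def zero_grad(self) -> None:
        for layer in self.layers():
            layer.zero_grad()

    # -- forward / backward -------------------------------------------------

    def encode(self, image: np.ndarray, train: bool = False) -> tuple[list[np.ndarray], np.ndarray]:
        """Run the depth-dependent-block encoder. ``image``: (N, 3, S, S). Returns the
        per-level skip features and the bottleneck feature map."""
        c = self.config
        if image.ndim != 4 or image.shape[1] != 3 or image.shape[2] != image.shape[3]:
            raise ValueError("expected (N, 3, S, S) input")
        if image.shape[2] % 2 ** (c.depth - 1) != 0:
            raise ValueError("input side must be divisible by 2**(depth-1)")
        self._enc_relus = []
        x = image.astype(nn.DTYPE)
        skips = []
        for level in range(c.depth):
            relus = []
            for cv, bn in zip(self.enc_convs[level], self.enc_bns[level]):
                r = ReLU()
                x = r.forward(bn.forward(cv.forward(x), train))
                relus.append(r)
            self._enc_relus.append(relus)
            if level < c.depth - 1:
                skips.append(x)
                x = self.pools[level].forward(x)
        return skips, x

    def mask_head(self, bottleneck: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Additional 1x1 convolution + logistic squashing -> (logits, mask)."""
        logits = self.mask_conv.forward(bottleneck)
        return logits, nn.sigmoid(logits)

    def decode(self, skips: list[np.ndarray], bottleneck: np.ndarray,
               mask: np.ndarray, train: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """Fuse the mask onto the bottleneck and up-sample back to full
        resolution. Returns (final_features (N,C0,S,S), seg_logits (N,2,S,S))."""
        x = np.concatenate([bottleneck, mask], axis=1)
        self._dec_relus = []
        for up, cv, bn, skip in zip(self.upconvs, self.dec_convs, self.dec_bns,
                                    reversed(skips)):
            x = up.forward(x)
            if x.shape[2:] != skip.shape[2:]:
                raise ArchitectureError("skip/up-sample shape mismatch")
            x = np.concatenate([x, skip], axis=1)
            r = ReLU()
            x = r.forward(bn.forward(cv.forward(x), train))
            self._dec_relus.append(r)
        seg = self.seg_head.forward(x)
        return x, seg

    def forward(self, image: np.ndarray, train: bool = False) -> dict:
        skips, bottleneck = self.encode(image, train)
        mask_logits, mask = self.mask_head(bottleneck)
        final_features, seg_logits = self.decode(skips, bottleneck, mask, train)
        return {
            "skips": skips,
            "bottleneck": bottleneck,
            "mask_logits": mask_logits,
            "mask": mask,
            "final_features": final_features,
            "seg_logits": seg_logits,
        }

    def backward(self, cache: dict, d_seg_logits: np.ndarray,
                 d_mask_logits: np.ndarray | None = None,
                 d_final_features: np.ndarray | None = None) -> None:
        """Accumulate parameter gradients for the stage-1 losses."""
        c = self.config
        dx = self.seg_head.backward(d_seg_logits)
        if d_final_features is not None:
            dx = dx + d_final_features
        # decoder, in reverse
        d_skips: list[np.ndarray] = []
        for up, cv, bn, r in zip(reversed(self.upconvs), reversed(self.dec_convs),
                                 reversed(self.dec_bns), reversed(self._dec_relus)):
            d = cv.backward(bn.backward(r.backward(dx)))
            c_out = up.c_out
            d_up, d_skip = d[:, :c_out], d[:, c_out:]
            d_skips.append(d_skip)
            dx = up.backward(d_up)
        # reversed decoder iteration visits the shallowest stage first, so
        # d_skips is already ordered by skip level 0 .. depth-2

        # split fused bottleneck gradient into bottleneck + mask parts
        bott_c = c.level_channels(c.depth - 1)
        d_bott, d_mask = dx[:, :bott_c], dx[:, bott_c:]
        d_ml = d_mask * cache["mask"] * (1 - cache["mask"])  # through sigmoid
        if d_mask_logits is not None:
            d_ml = d_ml + d_mask_logits
        d_bott = d_bott + self.mask_conv.backward(d_ml)

        # encoder, in reverse
        dx = d_bott
        for level in range(c.depth - 1, -1, -1):
            for cv, bn, r in zip(reversed(self.enc_convs[level]),
                                 reversed(self.enc_bns[level]),
                                 reversed(self._enc_relus[level])):
                dx = cv.backward(bn.backward(r.backward(dx)))
            if level > 0:
                dx = self.pools[level - 1].backward(dx)
                dx = dx + d_skips[level - 1]

    def set_bn_mode(self, train: bool) -> None:  # kept for symmetry; BN mode is per-call
        self._bn_train = train

    def num_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))


def count_layers(model: AUNet) -> tuple[int, int, int, int]:
    """Architecture census: (counted convolutions, max-poolings,
    up-convolutions, additional mask convolutions)."""
    n_conv = sum(1 for layer in model.layers()
                 if isinstance(layer, Conv2d) and layer.role == "counted")
    n_pool = len(model.pools)
    n_upconv = len(model.upconvs)
    n_mask = sum(1 for layer in model.layers()
                 if isinstance(layer, Conv2d) and layer.role == "mask")
    return n_conv, n_pool, n_upconv, n_mask


def conv_macs_per_level(config: ArchConfig) -> list[list[int]]:
    """Multiply-add count of every encoder convolution, grouped by level."""
    out = []
    counts = config.effective_counts()
    k = 3 if config.plain_unet_mode else config.depconv_kernel
    c_in = 3
    for level in range(config.depth):
        side = config.input_side // 2**level
        c_out = config.level_channels(level)
        macs = []
        for _ in range(counts[level]):
            macs.append(side * side * k * k * c_in * c_out)
            c_in = c_out
        out.append(macs)
    return out
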