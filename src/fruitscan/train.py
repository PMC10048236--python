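"""Two-stage balanced training protocol.

Stage 1 trains the segmentation backbone alone with a per-pixel
cross-entropy loss (each pixel acts as a training sample) plus an auxiliary
binary cross-entropy on the 1/8-resolution mask shortcut against the
8x-max-pooled ground-truth mask. Stage 2 freezes the backbone — parameters
and batch-norm running statistics — and trains only the decision head with
an image-level cross-entropy.

Sampling is balanced and alternating: defective and non-defective images
alternate (defective first); defective images are drawn without replacement
and an epoch ends once every defective image has been seen at least once,
while non-defective images are drawn uniformly with replacement (an epoch
does not necessarily visit all of them).

The optimizer is plain stochastic gradient descent without momentum, with
coupled L2 weight decay, batch size 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np

from . import nn
from .model import DefectInspector


class ConfigurationError(ValueError):
    pass


class StateError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    batch_size: int = 1
    learning_rate: float = 0.1
    momentum: float = 0.0  # the protocol uses no momentum
    weight_decay: float = 0.0005
    epochs: int = 100
    seed: int = 0
    mask_aux_weight: float = 1.0

    def validate(self) -> None:
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.momentum != 0.0:
            raise ConfigurationError("the training protocol is momentum-free")


@dataclass
class TrainingSet:
    """In-memory training split: preprocessed images and ground truth.

    ``images``: list of (3, S, S) float32 tensors; ``masks``: list of (S, S)
    {0,1} arrays; ``labels``: 1 for defective, 0 for non-defective.
    """

    images: list[np.ndarray]
    masks: list[np.ndarray]
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if not (len(self.images) == len(self.masks) == len(self.labels)):
            raise ConfigurationError("images, masks and labels must align")

    @property
    def defective_indices(self) -> np.ndarray:
        return np.flatnonzero(self.labels == 1)

    @property
    def normal_indices(self) -> np.ndarray:
        return np.flatnonzero(self.labels == 0)


@dataclass
class EpochPlan:
    """Ordered sample indices for one epoch of balanced alternation."""

    indices: list[int]
    defective_seen: set[int] = field(default_factory=set)


def balanced_sampler(labels: Sequence[int], seed: int) -> Iterator[EpochPlan]:
    """Yield one :class:`EpochPlan` per epoch, indefinitely.

    Pattern (d, n, d, n, ...): defectives shuffled without replacement until
    exhausted — which ends the epoch — and normals drawn uniformly with
    replacement across epochs.
    """
    labels = np.asarray(labels)
    defective = np.flatnonzero(labels == 1)
    normal = np.flatnonzero(labels == 0)
    if len(defective) == 0 or len(normal) == 0:
        raise ConfigurationError(
            "balanced sampling needs at least one defective and one "
            "non-defective training image")
    rng = np.random.default_rng(seed)
    while True:
        order = rng.permutation(defective)
        indices: list[int] = []
        for d in order:
            indices.append(int(d))
            indices.append(int(rng.choice(normal)))
        yield EpochPlan(indices=indices, defective_seen=set(int(d) for d in order))


def pixel_cross_entropy(seg_logits: np.ndarray, truth_mask: np.ndarray
                        ) -> tuple[float, np.ndarray]:
    """Mean 2-class cross-entropy over all pixels; defect pixels are class 1.

    ``seg_logits``: (N, 2, H, W); ``truth_mask``: (N, H, W) in {0, 1}.
    Returns (loss, gradient w.r.t. the logits).
    """
    if seg_logits.shape[0] != truth_mask.shape[0] or seg_logits.shape[2:] != truth_mask.shape[1:]:
        raise ValueError("segmentation logits and truth mask shapes must match")
    return nn.softmax_cross_entropy(seg_logits, truth_mask.astype(np.int64), class_axis=1)


def downsample_mask(mask: np.ndarray, factor: int = 8) -> np.ndarray:
    """Max-pool a binary (H, W) mask by ``factor`` (supervision target for
    the 1/8-resolution shortcut)."""
    h, w = mask.shape
    return mask.reshape(h // factor, factor, w // factor, factor).max(axis=(1, 3))


@dataclass
class History:
    stage1: list[dict] = field(default_factory=list)
    stage2: list[dict] = field(default_factory=list)


def _check_finite(loss: float, where: str) -> None:
    if not np.isfinite(loss):
        raise FloatingPointError(f"training diverged ({where}: loss={loss})")


def train_segmentation(model: DefectInspector, data: TrainingSet,
                       config: TrainConfig) -> History:
    """Stage 1: train the segmentation backbone alone."""
    config.validate()
    if len(data.images) == 0:
        raise ConfigurationError("empty training split")
    opt = nn.SGD(model.aunet.params(), lr=config.learning_rate,
                 weight_decay=config.weight_decay,
                 decay_mask=model.aunet.decay_mask())
    sampler = balanced_sampler(data.labels, seed=config.seed)
    history = History()
    factor = 2 ** (model.arch.depth - 1)
    for epoch in range(config.epochs):
        plan = next(sampler)
        losses = []
        for idx in plan.indices:
            x = data.images[idx][None]
            gt = data.masks[idx][None].astype(np.int64)
            out = model.aunet.forward(x, train=True)
            loss, d_seg = pixel_cross_entropy(out["seg_logits"], gt)
            d_ml = None
            if config.mask_aux_weight > 0:
                target = downsample_mask(data.masks[idx], factor)[None, None]
                aux, d_ml = nn.bce_with_logits(out["mask_logits"],
                                               target.astype(np.float64))
                loss += config.mask_aux_weight * aux
                d_ml = (config.mask_aux_weight * d_ml).astype(nn.DTYPE)
            _check_finite(loss, f"stage 1 epoch {epoch}")
            opt.zero_grad()
            model.aunet.backward(out, d_seg, d_mask_logits=d_ml)
            opt.step()
            losses.append(loss)
        history.stage1.append({"epoch": epoch, "stage": 1,
                               "loss": float(np.mean(losses)),
                               "n_samples": len(plan.indices)})
    model.stage1_done = True
    return history


def _frozen_outputs(model: DefectInspector, data: TrainingSet) -> dict[int, tuple]:
    """Eval-mode backbone outputs per image; the backbone is frozen in stage
    2, so these are constants of the optimization."""
    cache = {}
    for idx in range(len(data.images)):
        out = model.aunet.forward(data.images[idx][None], train=False)
        cache[idx] = (out["final_features"], out["mask"])
    return cache


def train_decision(model: DefectInspector, data: TrainingSet,
                   config: TrainConfig, history: History | None = None) -> History:
    """Stage 2: freeze the backbone, train only the decision head with an
    image-level cross-entropy."""
    config.validate()
    if not model.stage1_done:
        raise StateError("stage 2 requires a stage-1-trained backbone")
    history = history or History()
    opt = nn.SGD(model.gdm.params(), lr=config.learning_rate,
                 weight_decay=config.weight_decay,
                 decay_mask=model.gdm.decay_mask())
    sampler = balanced_sampler(data.labels, seed=config.seed + 1)
    frozen = _frozen_outputs(model, data)
    for epoch in range(config.epochs):
        plan = next(sampler)
        losses = []
        for idx in plan.indices:
            features, mask = frozen[idx]
            out = model.gdm.forward(features, mask)
            target = np.array([data.labels[idx]], dtype=np.int64)
            loss, d_logits = nn.softmax_cross_entropy(out["logits"], target,
                                                      class_axis=1)
            _check_finite(loss, f"stage 2 epoch {epoch}")
            opt.zero_grad()
            model.gdm.backward(d_logits)
            opt.step()
            losses.append(loss)
        history.stage2.append({"epoch": epoch, "stage": 2,
                               "loss": float(np.mean(losses)),
                               "n_samples": len(plan.indices)})
    model.stage2_done = True
    return history


def two_stage_train(model: DefectInspector, data: TrainingSet,
                    config: TrainConfig) -> History:
    """Stage 1 then stage 2 (simultaneous training is deliberately not
    offered; the two losses act at different ranges — pixel vs image)."""
    history = train_segmentation(model, data, config)
    return train_decision(model, data, config, history=history)
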