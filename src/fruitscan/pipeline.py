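"""End-to-end plumbing: named run profiles, dataset -> tensor conversion,
and the train/evaluate loops used by the CLI, the experiment harnesses and
the test fixtures.

Two profiles are provided:

* ``paper`` — the full-scale configuration: 512x512 inputs, 32 base
  channels, learning rate 0.1, 100 epochs, a 500-image training set with the
  emulated class mix and a 150/50 balanced test split.
* ``fixture`` — a desk-scale configuration that exercises the identical code
  path on one CPU: 128x128 inputs, 8 base channels, learning rate 0.01,
  10 epochs, 64 training / 32 test images with a half-defective mix and
  full-contrast defects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .aunet import ArchConfig
from .gdm import GSAMConfig
from .model import DefectInspector
from .preprocess import PreprocessConfig, prepare
from .synthgen import (
    BALANCED_TEST_PROPORTIONS,
    TABLE2_PROPORTIONS,
    DatasetManifest,
    DefectClass,
    DefectParams,
    SceneConfig,
    generate_sample,
    load_sample,
)
from .train import TrainConfig, TrainingSet, two_stage_train


#: half-defective mix used by the desk-scale fixture splits
FIXTURE_PROPORTIONS: dict[DefectClass, float] = {
    DefectClass.NORMAL: 0.5,
    DefectClass.ROT: 0.125,
    DefectClass.DISEASE: 0.125,
    DefectClass.LACERATION: 0.125,
    DefectClass.MECHANICAL: 0.125,
}


@dataclass
class RunConfig:
    """Composition of all sub-configurations for one run."""

    profile: str
    arch: ArchConfig
    gsam: GSAMConfig
    train: TrainConfig
    preprocess: PreprocessConfig
    scene: SceneConfig
    defect_params: DefectParams
    n_train: int
    n_test: int
    train_proportions: dict[DefectClass, float]
    test_proportions: dict[DefectClass, float]

    def validate(self) -> None:
        self.arch.validate()
        self.gsam.validate()
        self.train.validate()
        self.preprocess.validate()
        self.scene.validate()


def paper_profile(seed: int = 0) -> RunConfig:
    return RunConfig(
        profile="paper",
        arch=ArchConfig(input_side=512, base_channels=32),
        gsam=GSAMConfig(),
        train=TrainConfig(learning_rate=0.1, epochs=100, seed=seed),
        preprocess=PreprocessConfig(target_side=512, apply_background_removal=False),
        scene=SceneConfig(image_side=512, seed=seed),
        defect_params=DefectParams(),
        n_train=500,
        n_test=200,
        train_proportions=TABLE2_PROPORTIONS,
        test_proportions=BALANCED_TEST_PROPORTIONS,
    )


def fixture_profile(seed: int = 0) -> RunConfig:
    return RunConfig(
        profile="fixture",
        arch=ArchConfig(input_side=128, base_channels=8),
        gsam=GSAMConfig(),
        train=TrainConfig(learning_rate=0.01, epochs=10, seed=seed),
        preprocess=PreprocessConfig(target_side=128, apply_background_removal=False),
        scene=SceneConfig(image_side=128, seed=seed),
        defect_params=DefectParams(area_fraction_range=(0.06, 0.14),
                                   contrast_range=(1.0, 1.0)),
        n_train=64,
        n_test=32,
        train_proportions=FIXTURE_PROPORTIONS,
        test_proportions=FIXTURE_PROPORTIONS,
    )


PROFILES = {"paper": paper_profile, "fixture": fixture_profile}


def load_profile(name: str, seed: int = 0) -> RunConfig:
    try:
        factory = PROFILES[name]
    except KeyError:
        raise ValueError(f"unknown profile {name!r}; choose from {sorted(PROFILES)}")
    return factory(seed)


# ---------------------------------------------------------------------------
# dataset -> tensors


def _class_sequence(n: int, proportions: dict[DefectClass, float],
                    rng: np.random.Generator) -> list[DefectClass]:
    from .synthgen import largest_remainder_counts

    counts = largest_remainder_counts(n, proportions)
    classes: list[DefectClass] = []
    for c in DefectClass:
        classes.extend([c] * counts.get(c, 0))
    rng.shuffle(classes)
    return classes


def synthesize_split(n: int, proportions: dict[DefectClass, float],
                     config: RunConfig, seed: int) -> TrainingSet:
    """Generate a split entirely in memory (images already network-sized)."""
    rng = np.random.default_rng(seed)
    classes = _class_sequence(n, proportions, rng)
    return _materialize(classes, config, seed)


def _materialize(classes: list[DefectClass], config: RunConfig, seed: int) -> TrainingSet:
    child = np.random.SeedSequence(seed).generate_state(len(classes)) % 2**31
    images, masks, labels = [], [], []
    pp = config.preprocess
    for i, cls in enumerate(classes):
        sample = generate_sample(cls, config.scene, config.defect_params,
                                 seed=int(child[i]))
        images.append(prepare(sample.image, pp))
        mask = sample.mask
        if mask.shape[0] != pp.target_side:
            # nearest-neighbour resize of the binary mask
            idx = (np.arange(pp.target_side) * mask.shape[0] / pp.target_side).astype(int)
            mask = mask[np.ix_(idx, idx)]
        masks.append(mask.astype(np.int64))
        labels.append(1 if cls != DefectClass.NORMAL else 0)
    return TrainingSet(images=images, masks=masks, labels=np.array(labels))


def manifest_to_set(manifest: DatasetManifest, config: RunConfig) -> TrainingSet:
    """Load a generated on-disk dataset into tensors."""
    images, masks, labels = [], [], []
    pp = config.preprocess
    for record in manifest.records:
        sample = load_sample(manifest, record)
        images.append(prepare(sample.image, pp))
        mask = sample.mask
        if mask.shape[0] != pp.target_side:
            idx = (np.arange(pp.target_side) * mask.shape[0] / pp.target_side).astype(int)
            mask = mask[np.ix_(idx, idx)]
        masks.append(mask.astype(np.int64))
        labels.append(1 if sample.label == "defective" else 0)
    return TrainingSet(images=images, masks=masks, labels=np.array(labels))


# ---------------------------------------------------------------------------
# end-to-end runs


def build_model(config: RunConfig, seed: int) -> DefectInspector:
    return DefectInspector(config.arch, config.gsam,
                           rng=np.random.default_rng(seed))


def run_fixture_experiment(seed: int = 0, n_train: int | None = None,
                           n_test: int | None = None,
                           epochs: int | None = None) -> dict:
    """Generate the fixture dataset, run the two-stage training, and score
    the held-out split. Returns model, history, scores, labels."""
    config = fixture_profile(seed)
    if epochs is not None:
        config.train = replace(config.train, epochs=epochs)
    n_train = n_train or config.n_train
    n_test = n_test or config.n_test
    train_set = synthesize_split(n_train, config.train_proportions, config, seed)
    test_set = synthesize_split(n_test, config.test_proportions, config, seed + 10_000)
    model = build_model(config, seed)
    history = two_stage_train(model, train_set, config.train)
    scores = model.predict_scores(np.stack(test_set.images))
    return {
        "config": config,
        "model": model,
        "history": history,
        "train_set": train_set,
        "test_set": test_set,
        "scores": scores,
        "labels": test_set.labels,
    }
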