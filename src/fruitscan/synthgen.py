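"""Synthetic fruit-surface image generator with ground-truth defect masks.

Renders shaded spherical fruit (radial brightness falloff plus one specular
highlight, the two lighting effects that make real sorting-chamber images
hard) on a dark chamber background, optionally with a stem/calyx-like dark
distractor spot that is deliberately *not* part of the defect mask. Four
defect morphologies are drawn inside the fruit region: rot (dark irregular
blob), disease (speckle cluster), laceration (elongated streak) and
mechanical injury (low-contrast diffuse patch).

Datasets are written as PNG images + single-channel {0,255} PNG masks with a
CSV manifest (``path,mask_path,label,defect_class,split``) and a JSON sidecar
recording the configuration and seed. Generation is fully deterministic given
(config, seed).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image


class DefectClass(enum.Enum):
    NORMAL = "normal"
    ROT = "rot"
    DISEASE = "disease"
    LACERATION = "laceration"
    MECHANICAL = "mechanical"


#: training-set class mix of the emulated apple dataset
TABLE2_PROPORTIONS: dict[DefectClass, float] = {
    DefectClass.NORMAL: 0.792,
    DefectClass.ROT: 0.062,
    DefectClass.DISEASE: 0.042,
    DefectClass.LACERATION: 0.054,
    DefectClass.MECHANICAL: 0.050,
}

#: balanced test split: 150 normal / 50 defective, defect classes uniform
BALANCED_TEST_PROPORTIONS: dict[DefectClass, float] = {
    DefectClass.NORMAL: 0.75,
    DefectClass.ROT: 0.0625,
    DefectClass.DISEASE: 0.0625,
    DefectClass.LACERATION: 0.0625,
    DefectClass.MECHANICAL: 0.0625,
}

PROPORTION_PRESETS = {
    "table2": TABLE2_PROPORTIONS,
    "balanced_test": BALANCED_TEST_PROPORTIONS,
}


class ConfigurationError(ValueError):
    pass


@dataclass
class SceneConfig:
    """Rendering parameters for one fruit scene."""

    image_side: int = 128
    fruit_radius_range: tuple[float, float] = (0.32, 0.42)
    base_color: str = "red"  # or "green"
    highlight_strength: float = 0.5
    distractor_probability: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.image_side <= 0:
            raise ConfigurationError("image_side must be positive")
        lo, hi = self.fruit_radius_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("fruit_radius_range fractions must lie in (0, 0.5]")
        if not 0 <= self.distractor_probability <= 1:
            raise ConfigurationError("distractor_probability must lie in [0, 1]")
        if not 0 <= self.highlight_strength <= 1:
            raise ConfigurationError("highlight_strength must lie in [0, 1]")
        if self.base_color not in ("red", "green"):
            raise ConfigurationError("base_color must be 'red' or 'green'")


@dataclass
class DefectSpec:
    """Morphology parameters for one synthetic defect."""

    defect_class: DefectClass
    area_fraction: float = 0.08
    contrast: float = 1.0
    elongation: float = 4.0  # laceration aspect ratio
    speckle_count: int = 8  # disease spots

    def validate(self) -> None:
        if self.defect_class == DefectClass.NORMAL:
            raise ConfigurationError("a defect spec cannot have class 'normal'")
        if not 0 < self.area_fraction <= 0.5:
            raise ConfigurationError("area_fraction must lie in (0, 0.5]")
        if not 0 < self.contrast <= 1:
            raise ConfigurationError("contrast must lie in (0, 1]")
        if self.elongation < 1:
            raise ConfigurationError("elongation must be >= 1")


@dataclass
class SyntheticSample:
    image: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray  # (H, W) uint8 {0, 1}
    label: str  # "defective" | "non-defective"
    defect_class: DefectClass
    fruit_center: tuple[float, float] = (0.0, 0.0)
    fruit_radius: float = 0.0


@dataclass
class ManifestRecord:
    path: str
    mask_path: str | None
    label: str
    defect_class: str
    split: str


@dataclass
class DatasetManifest:
    records: list[ManifestRecord]
    class_counts: dict[DefectClass, int]
    seed: int
    root: str = "."

    def to_csv(self, path: Path) -> None:
        df = pd.DataFrame([asdict(r) for r in self.records])
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Path) -> "DatasetManifest":
        df = pd.read_csv(path)
        records = [
            ManifestRecord(
                path=row.path,
                mask_path=None if pd.isna(row.mask_path) else row.mask_path,
                label=row.label,
                defect_class=row.defect_class,
                split=row.split,
            )
            for row in df.itertuples()
        ]
        counts: dict[DefectClass, int] = {c: 0 for c in DefectClass}
        for r in records:
            counts[DefectClass(r.defect_class)] += 1
        sidecar = Path(path).with_suffix(".json")
        seed = -1
        if sidecar.exists():
            seed = json.loads(sidecar.read_text()).get("seed", -1)
        return cls(records=records, class_counts=counts, seed=seed,
                   root=str(Path(path).parent))


# ---------------------------------------------------------------------------
# rendering


_BASE_RGB = {"red": (205.0, 62.0, 48.0), "green": (92.0, 185.0, 58.0)}
_BACKGROUND_LEVEL = 14.0


def render_fruit(scene: SceneConfig, seed: int) -> SyntheticSample:
    """Render a non-defective shaded fruit disk on a dark chamber background."""
    scene.validate()
    rng = np.random.default_rng(seed)
    s = scene.image_side
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)

    lo, hi = scene.fruit_radius_range
    radius = rng.uniform(lo, hi) * s
    cx = s / 2 + rng.uniform(-0.05, 0.05) * s
    cy = s / 2 + rng.uniform(-0.05, 0.05) * s
    r = np.hypot(xx - cx, yy - cy)
    inside = r <= radius

    # background: dark chamber with mild sensor noise
    img = np.empty((s, s, 3), dtype=np.float64)
    img[...] = _BACKGROUND_LEVEL
    img += rng.normal(0, 2.0, size=(s, s, 1))

    # radial shading: bright near the center, darker toward the limb
    shade = 1.0 - 0.45 * np.clip(r / radius, 0, 1) ** 2
    base = np.array(_BASE_RGB[scene.base_color])
    jitter = rng.normal(1.0, 0.03, size=3)
    fruit = shade[..., None] * (base * jitter)[None, None, :]

    # one specular highlight (off-center Gaussian)
    hx = cx + rng.uniform(-0.4, 0.4) * radius
    hy = cy - rng.uniform(0.1, 0.5) * radius
    hl = np.exp(-((xx - hx) ** 2 + (yy - hy) ** 2) / (2 * (0.18 * radius) ** 2))
    fruit += 90.0 * scene.highlight_strength * hl[..., None]

    img[inside] = fruit[inside]
    img += rng.normal(0, 1.5, size=(s, s, 3))  # texture noise

    if rng.uniform() < scene.distractor_probability:
        # stem/calyx confounder: small dark brown spot, NOT in the mask
        ang = rng.uniform(0, 2 * np.pi)
        dist = rng.uniform(0.0, 0.35) * radius
        dx, dy = cx + dist * np.cos(ang), cy + dist * np.sin(ang)
        drad = rng.uniform(0.05, 0.10) * radius
        spot = np.hypot(xx - dx, yy - dy) <= drad
        spot &= inside
        img[spot] = img[spot] * 0.35 + np.array([28.0, 18.0, 10.0])[None, :]

    image = np.clip(img, 0, 255).astype(np.uint8)
    return SyntheticSample(
        image=image,
        mask=np.zeros((s, s), dtype=np.uint8),
        label="non-defective",
        defect_class=DefectClass.NORMAL,
        fruit_center=(cy, cx),
        fruit_radius=radius,
    )


def _fruit_geometry(sample: SyntheticSample) -> tuple[np.ndarray, float, float, float]:
    cy, cx = sample.fruit_center
    radius = sample.fruit_radius
    s = sample.image.shape[0]
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    inside = np.hypot(xx - cx, yy - cy) <= radius
    return inside, cy, cx, radius


def apply_defect(sample: SyntheticSample, spec: DefectSpec, seed: int) -> SyntheticSample:
    """Draw one defect inside the fruit region; the mask marks exactly the
    altered pixels."""
    spec.validate()
    if sample.label != "non-defective":
        raise ValueError("apply_defect expects a non-defective sample")
    rng = np.random.default_rng(seed)
    s = sample.image.shape[0]
    inside, cy, cx, radius = _fruit_geometry(sample)
    fruit_area = float(np.pi * radius**2)
    target_area = spec.area_fraction * fruit_area

    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    # defect center well inside the fruit so little of it is clipped
    ang = rng.uniform(0, 2 * np.pi)
    dist = rng.uniform(0.0, 0.45) * radius
    dcy, dcx = cy + dist * np.sin(ang), cx + dist * np.cos(ang)

    cls = spec.defect_class
    region = np.zeros((s, s), dtype=bool)
    if cls == DefectClass.ROT:
        # irregular blob: radius modulated by random low-order harmonics
        base_r = np.sqrt(target_area / np.pi)
        theta = np.arctan2(yy - dcy, xx - dcx)
        wobble = np.ones_like(theta)
        for k in range(2, 5):
            wobble += rng.uniform(0.05, 0.18) * np.sin(k * theta + rng.uniform(0, 2 * np.pi))
        region = np.hypot(xx - dcx, yy - dcy) <= base_r * wobble
    elif cls == DefectClass.DISEASE:
        n_spots = max(1, spec.speckle_count)
        spot_r = max(1.2, np.sqrt(target_area / (n_spots * np.pi)))
        cluster_r = max(spot_r * 2.5, np.sqrt(n_spots) * spot_r * 1.6)
        for _ in range(n_spots):
            a, d = rng.uniform(0, 2 * np.pi), rng.uniform(0, cluster_r)
            sy, sx = dcy + d * np.sin(a), dcx + d * np.cos(a)
            region |= np.hypot(xx - sx, yy - sy) <= spot_r * rng.uniform(0.85, 1.15)
    elif cls == DefectClass.LACERATION:
        # thin rectangle with aspect ratio = elongation; orientation stays
        # within 12 degrees of an image axis so the elongation survives in
        # the axis-aligned bounding box
        width = max(1.0, np.sqrt(target_area / spec.elongation))
        length = spec.elongation * width
        a = rng.uniform(-np.pi / 15, np.pi / 15) + rng.choice([0.0, np.pi / 2])
        u = (xx - dcx) * np.cos(a) + (yy - dcy) * np.sin(a)
        v = -(xx - dcx) * np.sin(a) + (yy - dcy) * np.cos(a)
        region = (np.abs(u) <= length / 2) & (np.abs(v) <= width / 2)
    elif cls == DefectClass.MECHANICAL:
        # diffuse bruise: mildly elongated ellipse, low-contrast darkening
        ecc = rng.uniform(1.2, 1.8)
        rr = np.sqrt(target_area / (np.pi * ecc))
        a = rng.uniform(0, np.pi)
        u = (xx - dcx) * np.cos(a) + (yy - dcy) * np.sin(a)
        v = -(xx - dcx) * np.sin(a) + (yy - dcy) * np.cos(a)
        region = (u / (rr * ecc)) ** 2 + (v / rr) ** 2 <= 1.0
    region &= inside
    if not region.any():
        # degenerate placement (fully clipped); fall back to a small central blob
        region = (np.hypot(xx - cx, yy - cy) <= max(2.0, np.sqrt(target_area / np.pi))) & inside

    img = sample.image.astype(np.float64)
    strength = spec.contrast if cls != DefectClass.MECHANICAL else 0.35 * spec.contrast
    tint = {
        DefectClass.ROT: np.array([45.0, 26.0, 14.0]),
        DefectClass.DISEASE: np.array([70.0, 52.0, 22.0]),
        DefectClass.LACERATION: np.array([60.0, 34.0, 24.0]),
        DefectClass.MECHANICAL: np.array([80.0, 60.0, 48.0]),
    }[cls]
    blended = img[region] * (1 - strength) + tint[None, :] * strength
    # guarantee every region pixel actually changes so mask == altered pixels
    # (comparison mirrors the final clip + uint8 truncation)
    same = np.all(np.clip(blended, 0, 255).astype(np.uint8) == sample.image[region], axis=1)
    blended[same] = np.clip(blended[same] - 3.0, 0.0, 252.0)
    img[region] = blended

    mask = np.zeros((s, s), dtype=np.uint8)
    mask[region] = 1
    return SyntheticSample(
        image=np.clip(img, 0, 255).astype(np.uint8),
        mask=mask,
        label="defective",
        defect_class=cls,
        fruit_center=sample.fruit_center,
        fruit_radius=sample.fruit_radius,
    )


# ---------------------------------------------------------------------------
# dataset assembly


def largest_remainder_counts(n: int, proportions: dict[DefectClass, float]) -> dict[DefectClass, int]:
    """Integer class counts summing exactly to n; ties broken in DefectClass
    enumeration order."""
    if abs(sum(proportions.values()) - 1.0) > 1e-9:
        raise ConfigurationError("proportions must sum to 1")
    classes = [c for c in DefectClass if c in proportions]
    quotas = np.array([n * proportions[c] for c in classes])
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    for i in order[:remainder]:
        counts[i] += 1
    return {c: int(k) for c, k in zip(classes, counts)}


@dataclass
class DefectParams:
    """Sampling ranges for per-image defect specs."""

    area_fraction_range: tuple[float, float] = (0.05, 0.14)
    contrast_range: tuple[float, float] = (0.7, 1.0)
    elongation: float = 4.0
    speckle_count: int = 8


def sample_defect_spec(cls: DefectClass, params: DefectParams,
                       rng: np.random.Generator) -> DefectSpec:
    return DefectSpec(
        defect_class=cls,
        area_fraction=float(rng.uniform(*params.area_fraction_range)),
        contrast=float(rng.uniform(*params.contrast_range)),
        elongation=params.elongation,
        speckle_count=params.speckle_count,
    )


def generate_sample(cls: DefectClass, scene: SceneConfig, params: DefectParams,
                    seed: int) -> SyntheticSample:
    """Render one sample of the given class (in memory)."""
    ss = np.random.SeedSequence(seed)
    s_render, s_spec, s_defect = ss.spawn(3)
    sample = render_fruit(scene, seed=int(s_render.generate_state(1)[0] % 2**31))
    if cls != DefectClass.NORMAL:
        rng = np.random.default_rng(s_spec)
        spec = sample_defect_spec(cls, params, rng)
        sample = apply_defect(sample, spec, seed=int(s_defect.generate_state(1)[0] % 2**31))
    return sample


def generate_dataset(n_images: int, proportions: dict[DefectClass, float],
                     scene: SceneConfig, seed: int, out_dir: Path | str,
                     split: str = "train",
                     defect_params: DefectParams | None = None) -> DatasetManifest:
    """Generate ``n_images`` samples with the given class mix and write them
    (PNG images, {0,255} PNG masks, CSV manifest + JSON sidecar) to disk."""
    if n_images <= 0:
        raise ConfigurationError("n_images must be positive")
    scene.validate()
    defect_params = defect_params or DefectParams()
    counts = largest_remainder_counts(n_images, proportions)
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)

    classes: list[DefectClass] = []
    for c in DefectClass:
        classes.extend([c] * counts.get(c, 0))
    rng = np.random.default_rng(seed)
    rng.shuffle(classes)  # interleave classes deterministically

    records = []
    child_seeds = np.random.SeedSequence(seed).generate_state(n_images) % 2**31
    for i, cls in enumerate(classes):
        sample = generate_sample(cls, scene, defect_params, seed=int(child_seeds[i]))
        img_rel = f"images/{split}_{i:05d}.png"
        Image.fromarray(sample.image).save(out_dir / img_rel)
        mask_rel = None
        if sample.label == "defective":
            mask_rel = f"masks/{split}_{i:05d}.png"
            Image.fromarray(sample.mask * 255).save(out_dir / mask_rel)
        records.append(ManifestRecord(path=img_rel, mask_path=mask_rel,
                                      label=sample.label,
                                      defect_class=cls.value, split=split))

    manifest = DatasetManifest(records=records, class_counts=counts, seed=seed,
                               root=str(out_dir))
    manifest.to_csv(out_dir / f"manifest_{split}.csv")
    sidecar = {
        "seed": seed,
        "n_images": n_images,
        "split": split,
        "proportions": {c.value: p for c, p in proportions.items()},
        "scene": asdict(scene),
        "defect_params": asdict(defect_params),
    }
    (out_dir / f"manifest_{split}.json").write_text(json.dumps(sidecar, indent=2))
    return manifest


def load_sample(manifest: DatasetManifest, record: ManifestRecord) -> SyntheticSample:
    """Read one manifest record back into memory."""
    root = Path(manifest.root)
    image = np.asarray(Image.open(root / record.path).convert("RGB"))
    if record.mask_path is not None:
        mask = (np.asarray(Image.open(root / record.mask_path)) > 127).astype(np.uint8)
    else:
        mask = np.zeros(image.shape[:2], dtype=np.uint8)
    return SyntheticSample(image=image, mask=mask, label=record.label,
                           defect_class=DefectClass(record.defect_class))
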