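"""The full two-network defect inspector: segmentation backbone + global
decision module, with checkpoint (de)serialization."""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .aunet import ArchConfig, AUNet
from .gdm import GDM, GSAMConfig
from . import nn


class DefectInspector:
    """Segmentation network plus decision head, trained in two stages."""

    def __init__(self, arch: ArchConfig, gsam: GSAMConfig,
                 rng: np.random.Generator | int | None = None):
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.arch = arch
        self.gsam = gsam
        self.aunet = AUNet(arch, rng)
        self.gdm = GDM(arch.base_channels, gsam, rng)
        self.stage1_done = False
        self.stage2_done = False

    def forward(self, image: np.ndarray, train: bool = False) -> dict:
        out = self.aunet.forward(image, train=train)
        out.update(self.gdm.forward(out["final_features"], out["mask"]))
        return out

    def predict_scores(self, images: np.ndarray, batch: int = 1) -> np.ndarray:
        """Eval-mode per-image defect probabilities for (N, 3, S, S) input."""
        scores = []
        for i in range(0, images.shape[0], batch):
            scores.append(self.forward(images[i : i + batch], train=False)["score"])
        return np.concatenate(scores)

    # -- serialization ------------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays: dict[str, np.ndarray] = {}
        for i, p in enumerate(self.aunet.params()):
            arrays[f"aunet_p{i}"] = p.value
        for i, layer in enumerate(self.aunet.layers()):
            if hasattr(layer, "running_mean"):
                arrays[f"aunet_bn{i}_mean"] = layer.running_mean
                arrays[f"aunet_bn{i}_var"] = layer.running_var
        for i, p in enumerate(self.gdm.params()):
            arrays[f"gdm_p{i}"] = p.value
        return arrays

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.aunet.params()):
            p.value[...] = arrays[f"aunet_p{i}"]
        for i, layer in enumerate(self.aunet.layers()):
            if hasattr(layer, "running_mean"):
                layer.running_mean = np.array(arrays[f"aunet_bn{i}_mean"], dtype=nn.DTYPE)
                layer.running_var = np.array(arrays[f"aunet_bn{i}_var"], dtype=nn.DTYPE)
        for i, p in enumerate(self.gdm.params()):
            p.value[...] = arrays[f"gdm_p{i}"]

    def aunet_weight_hash(self) -> str:
        """SHA-256 over the serialized backbone weights and BN statistics."""
        h = hashlib.sha256()
        for key, arr in sorted(self.state_arrays().items()):
            if key.startswith("aunet"):
                h.update(key.encode())
                h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()


def save_checkpoint(model: DefectInspector, path: Path | str,
                    extra: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": 1,
        "arch": asdict(model.arch),
        "gsam": asdict(model.gsam),
        "stage1_done": model.stage1_done,
        "stage2_done": model.stage2_done,
        "extra": extra or {},
    }
    arrays = model.state_arrays()
    arrays["_meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path: Path | str) -> DefectInspector:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        arch_d = meta["arch"]
        arch_d["depconv_counts"] = tuple(arch_d["depconv_counts"])
        arch = ArchConfig(**arch_d)
        gsam = GSAMConfig(**meta["gsam"])
        model = DefectInspector(arch, gsam, rng=0)
        model.load_state_arrays({k: data[k] for k in data.files if k != "_meta"})
    model.stage1_done = meta["stage1_done"]
    model.stage2_done = meta["stage2_done"]
    return model
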