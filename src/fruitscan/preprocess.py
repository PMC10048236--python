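"""Image preparation: resizing to the network input size and Otsu-threshold
background removal on the red or green color component.

The fruit is imaged bright against a dark chamber, so pixels strictly above
the Otsu threshold are treated as foreground. Red varieties are segmented on
the red channel, green varieties on the green channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize


class InputError(ValueError):
    pass


class DegenerateInputError(InputError):
    """Raised when a channel has a single distinct value (no valid split)."""


@dataclass
class PreprocessConfig:
    target_side: int = 512
    variety: str = "red"  # channel used for background removal
    apply_background_removal: bool = True

    def validate(self) -> None:
        if self.target_side % 8 != 0:
            raise InputError("target_side must be divisible by 8 "
                             "(the mask shortcut performs three halvings)")
        if self.variety not in ("red", "green"):
            raise InputError("variety must be 'red' or 'green'")


def resize_image(image: np.ndarray, target_side: int) -> np.ndarray:
    """Bilinear resize to ``target_side`` x ``target_side`` x 3; the aspect
    ratio is deliberately not preserved."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise InputError("expected an H x W x 3 image")
    h, w = image.shape[:2]
    if h < 2 or w < 2 or target_side < 1:
        raise InputError("image sides must be >= 2 and target_side >= 1")
    if (h, w) == (target_side, target_side):
        return image.copy()
    out = _sk_resize(image.astype(np.float64), (target_side, target_side),
                     order=1, anti_aliasing=False, preserve_range=True)
    if np.issubdtype(image.dtype, np.integer):
        return np.clip(np.round(out), 0, 255).astype(image.dtype)
    return out.astype(image.dtype)


def otsu_threshold(channel: np.ndarray) -> int:
    """Threshold t in [0, 255] maximizing between-class variance of the
    256-bin histogram; the smallest maximizing t is returned. Pixels > t are
    foreground."""
    channel = np.asarray(channel)
    if channel.size == 0:
        raise InputError("empty channel")
    values = np.clip(channel, 0, 255).astype(np.int64)
    hist = np.bincount(values.ravel(), minlength=256).astype(np.float64)
    total = hist.sum()
    if np.count_nonzero(hist) < 2:
        raise DegenerateInputError("channel is constant; no valid threshold")

    # cumulative class probabilities/means for classes {<=t} vs {>t}
    p = hist / total
    omega0 = np.cumsum(p)                      # weight of class <= t
    mu_cum = np.cumsum(p * np.arange(256))     # first moment up to t
    mu_total = mu_cum[-1]
    omega1 = 1.0 - omega0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu_cum / omega0
        mu1 = (mu_total - mu_cum) / omega1
        sigma_b = omega0 * omega1 * (mu0 - mu1) ** 2
    sigma_b = np.nan_to_num(sigma_b[:255], nan=-1.0)  # t=255 leaves class1 empty
    return int(np.argmax(sigma_b))  # argmax returns the smallest maximizer


def remove_background(image: np.ndarray, variety: str = "red") -> tuple[np.ndarray, np.ndarray]:
    """Zero out background pixels using an Otsu threshold on the red (red
    varieties) or green (green varieties) channel.

    Returns ``(image_with_background_zeroed, foreground_mask)``. Idempotent:
    already-zeroed background stays zero and below threshold.
    """
    if image.ndim != 3 or image.shape[2] != 3 or image.size == 0:
        raise InputError("expected a nonempty H x W x 3 image")
    if variety not in ("red", "green"):
        raise InputError("variety must be 'red' or 'green'")
    channel = image[..., 0 if variety == "red" else 1]
    t = otsu_threshold(channel)
    mask = channel > t
    out = image.copy()
    out[~mask] = 0
    return out, mask.astype(np.uint8)


def prepare(image: np.ndarray, config: PreprocessConfig) -> np.ndarray:
    """Full preparation: optional background removal, resize, scale to [0,1].

    Returns a ``(3, S, S)`` float32 tensor ready for the network.
    """
    config.validate()
    img = image
    if config.apply_background_removal:
        img, _ = remove_background(img, config.variety)
    img = resize_image(img, config.target_side)
    return (img.astype(np.float32) / 255.0).transpose(2, 0, 1)
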