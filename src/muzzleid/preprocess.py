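"""Canonicalization of a cropped muzzle ROI for the matcher.

The pipeline is fixed: luminance greyscale -> anisotropic bilinear resize to
480 x 640 (width x height, no aspect preservation) -> intensities on [0, 1]
-> affine normalization ``z = (x - 0.485) / 0.229``.  The normalization
constants are the canonical single-channel pretrained-backbone constants
applied as a fixed affine map, not per-image moment matching (a per-image
switch exists for sensitivity checks).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize as _resize

from .errors import PreprocessingError

#: ITU-R BT.601 luminance weights.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class PreprocessConfig:
    resize_width: int = 480
    resize_height: int = 640
    norm_mean: float = 0.485
    norm_sd: float = 0.229
    interpolation: str = "bilinear"
    per_image_moments: bool = False


DEFAULT_PREPROCESS = PreprocessConfig()

_ORDERS = {"nearest": 0, "bilinear": 1, "bicubic": 3}


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG as a float array on [0, 1] (greyscale or RGB)."""
    arr = np.asarray(Image.open(path))
    return arr.astype(np.float64) / 255.0


def preprocess(image: np.ndarray, config: PreprocessConfig = DEFAULT_PREPROCESS) -> np.ndarray:
    """Transform a cropped ROI into the matcher's canonical input.

    Accepts uint8 or float images with 1 or 3 channels; returns a float32
    array of shape ``(resize_height, resize_width)``.  Deterministic.
    """
    img = np.asarray(image)
    if img.size == 0 or img.ndim not in (2, 3):
        raise PreprocessingError(f"cannot preprocess image of shape {img.shape}")
    if np.issubdtype(img.dtype, np.integer):
        img = img.astype(np.float64) / 255.0
    else:
        img = img.astype(np.float64)
    if img.ndim == 3:
        if img.shape[2] not in (1, 3):
            raise PreprocessingError(f"expected 1 or 3 channels, got {img.shape[2]}")
        if img.shape[2] == 1:
            img = img[..., 0]
        else:
            img = img @ np.asarray(LUMA_WEIGHTS, dtype=np.float64)

    cfg = config
    if cfg.interpolation not in _ORDERS:
        raise PreprocessingError(f"unknown interpolation {cfg.interpolation!r}")
    target = (cfg.resize_height, cfg.resize_width)
    if img.shape != target:
        img = _resize(
            img,
            target,
            order=_ORDERS[cfg.interpolation],
            mode="edge",
            anti_aliasing=False,
            preserve_range=True,
        )
    if cfg.per_image_moments:
        sd = img.std()
        if sd == 0:
            raise PreprocessingError("flat image cannot be moment-normalized per image")
        img = (img - img.mean()) / sd * cfg.norm_sd + cfg.norm_mean
    z = (img - cfg.norm_mean) / cfg.norm_sd
    if not np.isfinite(z).all():
        raise PreprocessingError("non-finite values after normalization")
    return z.astype(np.float32)
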