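"""Fundus photograph normalisation.

Classifier input images are normalised by a fixed chain:

1. centre-crop to a fraction (default 90%) of each linear dimension, which
   symmetrically removes the dark circular-mask rim of a fundus photograph;
2. resize to a square network-input resolution (default 299 x 299, RGB);
3. subtract a smoothed local average colour per channel and re-centre on
   50% gray (add 128), which removes illumination gradients while keeping
   local structure; the local average is a Gaussian blur whose sigma is a
   fraction of the output width (default 1/30);
4. clamp to [0, 255].

The local-average subtraction makes the output invariant to a constant
intensity offset of the input, and maps any constant-colour image exactly
to the gray level.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.filters import gaussian
from skimage.transform import resize

__all__ = ["PrepConfig", "preprocess", "load_image", "save_image",
           "preprocess_file", "preprocess_dir"]

_INTERP_ORDER = {"nearest": 0, "bilinear": 1, "area": 1}


@dataclass(frozen=True)
class PrepConfig:
    """Normalisation-chain parameters."""

    crop_fraction: float = 0.90
    out_size: int = 299
    blur_scale: float = 1.0 / 30.0  # sigma as fraction of output width
    gray_level: int = 128
    gain: float = 1.0               # multiplier on the high-pass residual
    interpolation: str = "bilinear"

    def __post_init__(self) -> None:
        if not 0.0 < self.crop_fraction <= 1.0:
            raise ValueError("crop_fraction must lie in (0, 1]")
        if self.out_size < 8:
            raise ValueError("out_size must be >= 8")
        if self.blur_scale <= 0:
            raise ValueError("blur_scale must be positive")
        if self.interpolation not in _INTERP_ORDER:
            raise ValueError(f"unknown interpolation: {self.interpolation!r}")


def _validate(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an H x W x 3 image")
    if arr.shape[0] < 10 or arr.shape[1] < 10:
        raise ValueError("image must be at least 10 x 10 pixels")
    return arr


def center_crop(img: np.ndarray, fraction: float) -> np.ndarray:
    """Centred crop retaining *fraction* of each linear dimension
    (floored), e.g. 2000 x 1980 at 0.9 -> 1800 x 1782."""
    h, w = img.shape[:2]
    ch, cw = int(h * fraction), int(w * fraction)
    if ch < 1 or cw < 1:
        raise ValueError("crop would produce an empty image")
    top, left = (h - ch) // 2, (w - cw) // 2
    return img[top:top + ch, left:left + cw]


def preprocess(img: np.ndarray, cfg: PrepConfig | None = None) -> np.ndarray:
    """Run the full normalisation chain; returns uint8
    ``out_size x out_size x 3``.

    Raises
    ------
    ValueError
        On a malformed or too-small input image.
    """
    cfg = cfg or PrepConfig()
    arr = _validate(img).astype(np.float64)

    arr = center_crop(arr, cfg.crop_fraction)
    order = _INTERP_ORDER[cfg.interpolation]
    anti_alias = cfg.interpolation != "nearest"
    arr = resize(arr, (cfg.out_size, cfg.out_size), order=order,
                 anti_aliasing=anti_alias, preserve_range=True)

    sigma = cfg.blur_scale * cfg.out_size
    local_avg = gaussian(arr, sigma=sigma, channel_axis=-1,
                         preserve_range=True, mode="nearest")
    out = cfg.gain * (arr - local_avg) + cfg.gray_level
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


# ---- file-level conveniences ------------------------------------------


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG into an H x W x 3 uint8 array."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    return arr[..., :3]


def save_image(path: str | Path, img: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, np.asarray(img, dtype=np.uint8))


def preprocess_file(src: str | Path, dst: str | Path,
                    cfg: PrepConfig | None = None) -> None:
    save_image(dst, preprocess(load_image(src), cfg))


def preprocess_dir(src_dir: str | Path, dst_dir: str | Path,
                   cfg: PrepConfig | None = None,
                   patterns: tuple[str, ...] = ("*.png", "*.jpg", "*.jpeg"),
                   ) -> list[Path]:
    """Batch-normalise every matching image in *src_dir* into *dst_dir*."""
    src_dir, dst_dir = Path(src_dir), Path(dst_dir)
    dst_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for pat in patterns:
        for p in sorted(src_dir.glob(pat)):
            out = dst_dir / p.name
            preprocess_file(p, out, cfg)
            written.append(out)
    return written
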