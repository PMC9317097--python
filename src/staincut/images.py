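"""Image containers and raster I/O.

Images travel through the package as float arrays in [0, 1], H x W x 3;
quantization to 8-bit happens only at file boundaries.  ``DomainImage`` tags
an array with the stain domain it belongs to and its declared value range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .exceptions import DataError


@dataclass
class DomainImage:
    """An RGB raster tagged with its stain domain."""

    pixels: np.ndarray  # (H, W, 3) float
    domain: str = ""
    value_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise DataError(f"expected (H, W, 3) pixels, got {self.pixels.shape}")

    @property
    def shape(self):
        return self.pixels.shape


def to_unit(arr: np.ndarray) -> np.ndarray:
    """Convert a uint8/uint16/float raster to float64 in [0, 1]."""
    arr = np.asarray(arr)
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def quantize8(img: np.ndarray) -> np.ndarray:
    """Round a [0, 1] float image to the 8-bit grid."""
    return np.clip(np.rint(img * 255.0), 0, 255).astype(np.uint8)


def read_image(path: str | Path) -> np.ndarray:
    """Read a raster file as (H, W, 3) float in [0, 1]."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"image not found: {path}")
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    return to_unit(arr)


def write_image(path: str | Path, img: np.ndarray) -> None:
    """Write a [0, 1] float image as 8-bit PNG/TIFF (by extension)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, quantize8(img))


def unit_to_tanh(img: np.ndarray) -> np.ndarray:
    """Map [0, 1] pixel values onto the generator's [-1, 1] working range."""
    return img * 2.0 - 1.0


def tanh_to_unit(img: np.ndarray) -> np.ndarray:
    return np.clip((img + 1.0) / 2.0, 0.0, 1.0)


def hwc_to_nchw(img: np.ndarray) -> np.ndarray:
    return np.transpose(img, (2, 0, 1))[None]


def nchw_to_hwc(batch: np.ndarray) -> np.ndarray:
    return np.transpose(batch[0], (1, 2, 0))
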