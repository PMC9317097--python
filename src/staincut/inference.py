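"""Whole-frame staining by overlapping tiles and border-aware blending.

The networks are trained on fixed-size crops, but evaluation frames are
larger (e.g. 1539x1376).  A frame is split into overlapping tiles, each tile
is translated independently, and every output pixel is a weighted average of
the values it received from the tiles containing it,

    x = (sum_i w_i x_i) / (sum_i w_i),

where the weight w_i grows with the pixel's distance from the border of tile
i -- tiles in which the pixel sits near the center contribute more, which
suppresses seam artifacts between neighboring tiles.

The default weight is the separable product ``w(r, c) = (d_r + 1) * (d_c + 1)``
with ``d`` the distance in pixels to the nearest tile edge along each axis:
the simplest strictly positive window that is maximal at the center and
decreases monotonically toward the borders.  Accumulation runs in float64 at
full frame size; quantization happens only when a file is written.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError
from .images import hwc_to_nchw, nchw_to_hwc, tanh_to_unit, unit_to_tanh

log = logging.getLogger("staincut.inference")


@dataclass
class TileLayout:
    """Tile origins covering a frame, plus the per-tile blending weights."""

    frame_shape: tuple[int, int]
    tile_size: int
    stride: int
    origins: list[tuple[int, int]]
    weight_mask: np.ndarray  # (tile_size, tile_size), strictly positive


@dataclass
class FrameAccumulator:
    """Running weighted sum and weight sum per pixel."""

    weighted: np.ndarray  # (H, W, C) float64
    weights: np.ndarray  # (H, W) float64

    @classmethod
    def for_frame(cls, h: int, w: int, channels: int = 3) -> "FrameAccumulator":
        return cls(np.zeros((h, w, channels)), np.zeros((h, w)))

    def add(self, origin: tuple[int, int], tile: np.ndarray, mask: np.ndarray):
        r, c = origin
        t = tile.shape[0]
        self.weighted[r : r + t, c : c + t] += mask[..., None] * tile
        self.weights[r : r + t, c : c + t] += mask

    def resolve(self) -> np.ndarray:
        if not (self.weights > 0).all():
            raise ConfigurationError("tile layout left uncovered pixels")
        return self.weighted / self.weights[..., None]


def _axis_origins(extent: int, tile: int, stride: int) -> list[int]:
    origins = list(range(0, extent - tile + 1, stride))
    if not origins:
        origins = [0]
    if origins[-1] + tile < extent:
        origins.append(extent - tile)
    return origins


def plan_tiles(frame_shape: tuple[int, int], tile_size: int, stride: int) -> TileLayout:
    """Regular tile grid with the final row/column clamped to the frame edge."""
    if stride <= 0:
        raise ConfigurationError("stride must be positive")
    if stride > tile_size:
        raise ConfigurationError("stride must not exceed tile_size")
    h, w = frame_shape[:2]
    if tile_size > h or tile_size > w:
        raise ConfigurationError(
            f"tile_size {tile_size} exceeds frame {h}x{w}; pad the frame first"
        )
    origins = [(r, c) for r in _axis_origins(h, tile_size, stride)
               for c in _axis_origins(w, tile_size, stride)]
    return TileLayout(
        frame_shape=(h, w),
        tile_size=tile_size,
        stride=stride,
        origins=origins,
        weight_mask=border_weight_mask(tile_size),
    )


def border_weight_mask(tile_size: int) -> np.ndarray:
    """Separable center-peaked weights ``(d_r + 1)(d_c + 1)``, integer-valued."""
    if tile_size < 2:
        raise ConfigurationError("tile_size must be >= 2")
    idx = np.arange(tile_size)
    d = np.minimum(idx, tile_size - 1 - idx).astype(np.float64)
    return np.outer(d + 1.0, d + 1.0)


def stain_frame(
    translate,
    frame: np.ndarray,
    tile_size: int = 512,
    stride: int = 256,
    layout: TileLayout | None = None,
) -> np.ndarray:
    """Translate a frame tile-by-tile and blend with border-aware weights.

    ``translate`` maps an (t, t, C) tile to an equally-shaped tile on the
    same value scale.  Frames smaller than ``tile_size`` are reflect-padded
    to one full tile and cropped back afterwards.
    """
    frame = np.asarray(frame, dtype=np.float64)
    h, w = frame.shape[:2]
    pad_h = max(0, tile_size - h)
    pad_w = max(0, tile_size - w)
    if pad_h or pad_w:
        log.info("frame %dx%d smaller than tile %d: padding", h, w, tile_size)
        frame = np.pad(frame, ((0, pad_h), (0, pad_w), (0, 0)), mode="reflect")
    if layout is None:
        layout = plan_tiles(frame.shape[:2], tile_size, stride)
    if len(layout.origins) == 1:
        # degenerate tiling: defer to a plain forward pass (bit-identical)
        out = np.asarray(translate(frame), dtype=np.float64)
        return out[:h, :w]
    acc = FrameAccumulator.for_frame(*frame.shape[:2], frame.shape[2])
    for origin in layout.origins:
        r, c = origin
        tile = frame[r : r + tile_size, c : c + tile_size]
        out = np.asarray(translate(tile), dtype=np.float64)
        if out.shape != tile.shape:
            raise ValueError(
                f"translator changed tile shape {tile.shape} -> {out.shape}"
            )
        acc.add(origin, out, layout.weight_mask)
    result = acc.resolve()
    return result[:h, :w]


def generator_translator(generator):
    """Wrap a trained generator as a [0, 1]-scale tile translator."""

    def translate(tile: np.ndarray) -> np.ndarray:
        x = hwc_to_nchw(unit_to_tanh(tile))
        y, _ = generator.forward(x)
        return tanh_to_unit(nchw_to_hwc(y))

    return translate


def stain_image(
    generator,
    image: np.ndarray,
    tile_size: int = 512,
    stride: int = 256,
) -> np.ndarray:
    """Stain an image of any size.

    Images that fit a single tile (and satisfy the generator's divisibility
    constraint) go through one forward pass; larger ones take the tiled path.
    """
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape[:2]
    div = generator.spec.size_divisor
    if h <= tile_size and w <= tile_size and h % div == 0 and w % div == 0:
        log.info("image %dx%d fits one tile: single-pass path", h, w)
        return generator_translator(generator)(image)
    log.info("image %dx%d: tiled path (tile=%d stride=%d)", h, w, tile_size, stride)
    return stain_frame(generator_translator(generator), image, tile_size, stride)
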