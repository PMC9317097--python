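"""Classical stain-normalization baselines and the template-mosaic builder.

Two reference methods accompany the learned model:

* **Reinhard** statistics transfer: move the per-channel mean and standard
  deviation of the source image onto those of a reference image in a
  decorrelated perceptual color space.  The original method works in
  Ruderman's l-alpha-beta space (log-LMS decorrelated), which is the default
  here; a CIELAB mode is also provided since the two are often conflated.
* **Macenko** stain-vector normalization: in optical density space the color
  of H&E tissue is approximately a nonnegative combination of two stain
  vectors (hematoxylin, eosin).  The method estimates each image's stain
  basis from the top-2 principal directions of its tissue OD pixels, swaps
  the source basis for the reference basis, and rescales concentrations by
  their 99th percentiles.

Classical methods need a reference image; a *template mosaic* tiles patches
from many frames into one reference so that a single image spans more of the
color distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.color import lab2rgb, rgb2lab
from skimage.transform import resize

from .exceptions import ConfigurationError, DataError

log = logging.getLogger("staincut.baselines")

# Ruderman RGB <-> LMS
_RGB2LMS = np.array(
    [
        [0.3811, 0.5783, 0.0402],
        [0.1967, 0.7244, 0.0782],
        [0.0241, 0.1288, 0.8444],
    ]
)
_LMS2RGB = np.linalg.inv(_RGB2LMS)
_LAB_ROT = np.diag([1 / np.sqrt(3), 1 / np.sqrt(6), 1 / np.sqrt(2)]) @ np.array(
    [[1, 1, 1], [1, 1, -2], [1, -1, 0]], dtype=float
)
_LAB_ROT_INV = np.linalg.inv(_LAB_ROT)


# ---------------------------------------------------------------------------
# template mosaic
# ---------------------------------------------------------------------------


@dataclass
class StainTemplate:
    """A reference mosaic of tiled patches."""

    mosaic: np.ndarray  # (H, W, 3) float in [0, 1]
    grid: tuple[int, int]
    tile_size: tuple[int, int]


def build_template(
    patches: list[np.ndarray],
    grid: tuple[int, int],
    template_size: tuple[int, int],
) -> StainTemplate:
    """Tile patches row-major into a mosaic of the declared size.

    Tile size is ``(H // rows, W // cols)``; patches are resized to it and
    cycled if fewer than ``rows * cols`` are given.  If the grid does not
    divide the template exactly, extra cropped tiles fill the margin so the
    mosaic always has exactly the declared dimensions.
    """
    if not patches:
        raise DataError("build_template needs at least one patch")
    rows, cols = grid
    if rows < 1 or cols < 1:
        raise ConfigurationError("grid dimensions must be >= 1")
    h, w = template_size
    th, tw = h // rows, w // cols
    if th < 1 or tw < 1:
        raise ConfigurationError("grid too fine for the template size")
    tiles = [
        resize(np.asarray(p, dtype=np.float64), (th, tw, 3), anti_aliasing=True)
        for p in patches
    ]
    mosaic = np.zeros((h, w, 3))
    n_rows = -(-h // th)  # cover the remainder with cropped tiles
    n_cols = -(-w // tw)
    k = 0
    for i in range(n_rows):
        for j in range(n_cols):
            tile = tiles[k % len(tiles)]
            k += 1
            r, c = i * th, j * tw
            hh, ww = min(th, h - r), min(tw, w - c)
            mosaic[r : r + hh, c : c + ww] = tile[:hh, :ww]
    return StainTemplate(mosaic=mosaic, grid=(rows, cols), tile_size=(th, tw))


# ---------------------------------------------------------------------------
# Reinhard
# ---------------------------------------------------------------------------


def _to_lalphabeta(rgb: np.ndarray) -> np.ndarray:
    lms = np.clip(rgb @ _RGB2LMS.T, 1e-6, None)
    return np.log10(lms) @ _LAB_ROT.T


def _from_lalphabeta(lab: np.ndarray) -> np.ndarray:
    lms = 10.0 ** (lab @ _LAB_ROT_INV.T)
    return lms @ _LMS2RGB.T


def reinhard_normalize(
    source: np.ndarray, reference: np.ndarray, space: str = "lalphabeta"
) -> np.ndarray:
    """Match per-channel mean/std of ``source`` to ``reference``.

    Both images are RGB floats in [0, 1].  ``space`` selects Ruderman's
    l-alpha-beta (default) or CIELAB.  A zero-variance source channel keeps
    unit scale (with a warning) so constant images transfer cleanly.
    """
    source = np.asarray(source, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if space == "lalphabeta":
        fwd, inv = _to_lalphabeta, _from_lalphabeta
    elif space == "cielab":
        fwd, inv = rgb2lab, lab2rgb
    else:
        raise ConfigurationError(f"unknown color space {space!r}")
    s = fwd(source)
    r = fwd(reference)
    mu_s = s.mean(axis=(0, 1))
    sd_s = s.std(axis=(0, 1))
    mu_r = r.mean(axis=(0, 1))
    sd_r = r.std(axis=(0, 1))
    scale = np.empty(3)
    for c in range(3):
        if sd_s[c] < 1e-12:
            log.warning("reinhard: zero-variance source channel %d, scale kept 1", c)
            scale[c] = 1.0
        else:
            scale[c] = sd_r[c] / sd_s[c]
    out = (s - mu_s) * scale + mu_r
    return np.clip(inv(out), 0.0, 1.0)


# ---------------------------------------------------------------------------
# Macenko
# ---------------------------------------------------------------------------


@dataclass
class StainBasis:
    """Two unit stain vectors (columns: hematoxylin, eosin) in OD space."""

    vectors: np.ndarray  # (3, 2), unit columns, nonnegative orientation
    max_concentrations: np.ndarray  # (2,), 99th-percentile concentrations


def _rgb_to_od(img: np.ndarray, i0: float = 255.0) -> np.ndarray:
    counts = np.clip(img, 0.0, 1.0) * i0
    return -np.log((counts + 1.0) / (i0 + 1.0))


def _od_to_rgb(od: np.ndarray, i0: float = 255.0) -> np.ndarray:
    counts = (i0 + 1.0) * np.exp(-od) - 1.0
    return np.clip(counts / i0, 0.0, 1.0)


def _nnls_two_stain(basis: np.ndarray, od: np.ndarray) -> np.ndarray:
    """Exact nonnegative least squares for the two-stain system.

    ``basis`` is (3, 2) with unit columns, ``od`` is (N, 3).  With two
    variables the active-set solution is either the unconstrained optimum or
    its projection onto one of the single-stain edges (clamped at zero), so
    concentrations are nonnegative by construction.
    """
    conc = np.linalg.lstsq(basis, od.T, rcond=None)[0]  # (2, N)
    v1, v2 = basis[:, 0], basis[:, 1]
    neg1 = conc[0] < 0
    if neg1.any():
        conc[0, neg1] = 0.0
        conc[1, neg1] = np.maximum(od[neg1] @ v2 / (v2 @ v2), 0.0)
    neg2 = conc[1] < 0
    if neg2.any():
        conc[1, neg2] = 0.0
        conc[0, neg2] = np.maximum(od[neg2] @ v1 / (v1 @ v1), 0.0)
    return conc


def estimate_stain_basis(
    image: np.ndarray,
    od_threshold: float = 0.15,
    angle_percentiles: tuple[float, float] = (1.0, 99.0),
    conc_percentile: float = 99.0,
) -> StainBasis:
    """Estimate the two-stain OD basis of an RGB image (Macenko's method).

    Background pixels (any OD channel below ``od_threshold``) are excluded;
    the remaining OD pixels are projected onto their top-2 principal plane,
    and the extreme-angle directions at the given percentiles become the
    stain vectors.
    """
    od = _rgb_to_od(np.asarray(image, dtype=np.float64)).reshape(-1, 3)
    tissue = od[(od > od_threshold).all(axis=1)]
    if tissue.shape[0] < 10:
        raise DataError(
            "too few tissue pixels above the OD threshold (background/white "
            "image?): cannot estimate a stain basis"
        )
    cov = np.cov(tissue.T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] <= 1e-12 * max(evals[2], 1e-300):
        raise DataError(
            "OD pixels span fewer than 2 significant directions (grayscale "
            "image?): no two-stain plane exists"
        )
    plane = evecs[:, [2, 1]]  # top-2 principal directions
    # orient the plane axes so tissue projections land in the right half
    proj = tissue @ plane
    for k in range(2):
        if proj[:, k].sum() < 0:
            plane[:, k] *= -1
    proj = tissue @ plane
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, angle_percentiles)
    v1 = plane @ np.array([np.cos(lo), np.sin(lo)])
    v2 = plane @ np.array([np.cos(hi), np.sin(hi)])
    for v in (v1, v2):
        if v.sum() < 0:
            v *= -1
    # hematoxylin is conventionally the vector with the larger first (red) OD
    he = np.column_stack([v1, v2] if v1[0] > v2[0] else [v2, v1])
    he /= np.linalg.norm(he, axis=0, keepdims=True)
    conc = _nnls_two_stain(he, od)
    max_c = np.percentile(conc, conc_percentile, axis=1)
    return StainBasis(vectors=he, max_concentrations=np.maximum(max_c, 1e-6))


def macenko_normalize(
    source: np.ndarray,
    reference: np.ndarray,
    od_threshold: float = 0.15,
    angle_percentiles: tuple[float, float] = (1.0, 99.0),
    conc_percentile: float = 99.0,
) -> np.ndarray:
    """Re-render ``source`` with the stain basis of ``reference``."""
    source = np.asarray(source, dtype=np.float64)
    basis_s = estimate_stain_basis(
        source, od_threshold, angle_percentiles, conc_percentile
    )
    basis_r = estimate_stain_basis(
        np.asarray(reference, dtype=np.float64),
        od_threshold,
        angle_percentiles,
        conc_percentile,
    )
    h, w, _ = source.shape
    od = _rgb_to_od(source).reshape(-1, 3)
    conc = _nnls_two_stain(basis_s.vectors, od)
    conc *= (basis_r.max_concentrations / basis_s.max_concentrations)[:, None]
    od_new = (basis_r.vectors @ conc).T.reshape(h, w, 3)
    return _od_to_rgb(od_new)


def normalize_with_template(
    method: str, source: np.ndarray, template: StainTemplate
) -> np.ndarray:
    """Run a classical method with a template mosaic as the reference image."""
    if method == "reinhard":
        return reinhard_normalize(source, template.mosaic)
    if method == "macenko":
        return macenko_normalize(source, template.mosaic)
    raise ConfigurationError(f"unknown baseline method {method!r}")
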