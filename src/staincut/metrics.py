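"""Full-reference image quality metrics and the batch evaluation harness.

PSNR, SSIM and FSIM score a stained image against its pixel-aligned ground
truth; the dice coefficient scores binary segmentation masks.  SSIM and FSIM
operate on the ITU-R BT.601 luminance of RGB inputs by default (a
``per_channel`` mode averages the per-channel scores instead).  LPIPS -- the
fourth metric used alongside these in the literature -- requires externally
trained perceptual-network weights and is deliberately reported as ``n/a``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import convolve, gaussian_filter, uniform_filter

from .exceptions import DataError
from .images import read_image

log = logging.getLogger("staincut.metrics")

BT601 = np.array([0.299, 0.587, 0.114])


def _luminance(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim == 3:
        return img @ BT601
    return img


# ---------------------------------------------------------------------------
# PSNR
# ---------------------------------------------------------------------------


def psnr(reference: np.ndarray, test: np.ndarray, max_value: float | None = None):
    """Peak signal-to-noise ratio in dB: ``10 log10(max^2 / MSE)``.

    MSE runs over all pixels and channels.  Identical images return ``inf``.
    ``max_value`` defaults to 255 for integer images and 1.0 for floats.
    """
    reference = np.asarray(reference)
    test = np.asarray(test)
    if reference.shape != test.shape:
        raise ValueError(f"shape mismatch: {reference.shape} vs {test.shape}")
    if max_value is None:
        max_value = 255.0 if np.issubdtype(reference.dtype, np.integer) else 1.0
    if max_value <= 0:
        raise ValueError("max_value must be positive")
    mse = np.mean((reference.astype(np.float64) - test.astype(np.float64)) ** 2)
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(max_value**2 / mse))


# ---------------------------------------------------------------------------
# SSIM
# ---------------------------------------------------------------------------


def ssim(
    reference: np.ndarray,
    test: np.ndarray,
    data_range: float | None = None,
    sigma: float = 1.5,
    win_size: int = 11,
    k1: float = 0.01,
    k2: float = 0.03,
    channel_mode: str = "luminance",
) -> float:
    """Mean structural similarity with a Gaussian window.

    Reference-standard constants: 11x11 Gaussian window with sigma 1.5,
    K1 = 0.01, K2 = 0.03, population (not sample) moments, and a border strip
    of half the window width excluded from the final average.
    """
    x = np.asarray(reference, dtype=np.float64)
    y = np.asarray(test, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if data_range is None:
        data_range = 255.0 if np.issubdtype(np.asarray(reference).dtype, np.integer) \
            else 1.0
    if x.ndim == 3:
        if channel_mode == "luminance":
            x, y = _luminance(x), _luminance(y)
        elif channel_mode == "per_channel":
            return float(np.mean([
                ssim(x[..., c], y[..., c], data_range, sigma, win_size, k1, k2)
                for c in range(x.shape[2])
            ]))
        else:
            raise ValueError(f"unknown channel_mode {channel_mode!r}")
    if min(x.shape) < win_size:
        raise ValueError(
            f"image {x.shape} smaller than the {win_size}x{win_size} window"
        )
    truncate = (win_size - 1) / 2 / sigma  # gaussian_filter radius -> win_size taps
    f = lambda a: gaussian_filter(a, sigma, truncate=truncate)
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    mx, my = f(x), f(y)
    vx = f(x * x) - mx * mx
    vy = f(y * y) - my * my
    cxy = f(x * y) - mx * my
    s = ((2 * mx * my + c1) * (2 * cxy + c2)) / (
        (mx * mx + my * my + c1) * (vx + vy + c2)
    )
    pad = (win_size - 1) // 2
    return float(s[pad:-pad, pad:-pad].mean())


# ---------------------------------------------------------------------------
# FSIM (phase congruency x gradient similarity)
# ---------------------------------------------------------------------------

_SCHARR_X = np.array([[3, 0, -3], [10, 0, -10], [3, 0, -3]]) / 16.0


def _lowpass(shape, cutoff=0.45, order=15):
    rows, cols = shape
    u = (np.arange(cols) - cols // 2) / cols
    v = (np.arange(rows) - rows // 2) / rows
    r = np.sqrt(u[None, :] ** 2 + v[:, None] ** 2)
    return np.fft.ifftshift(1.0 / (1.0 + (r / cutoff) ** (2 * order)))


def _phase_congruency(
    img: np.ndarray,
    nscale: int = 4,
    norient: int = 4,
    min_wavelength: float = 6.0,
    mult: float = 2.0,
    sigma_onf: float = 0.55,
    d_theta_sigma: float = 1.2,
    k_noise: float = 2.0,
) -> np.ndarray:
    """Phase congruency map from a log-Gabor filter bank (Kovesi's measure)."""
    rows, cols = img.shape
    eps = 1e-4
    fimg = np.fft.fft2(img)
    u = (np.arange(cols) - cols // 2) / cols
    v = (np.arange(rows) - rows // 2) / rows
    uu, vv = np.meshgrid(u, v)
    radius = np.fft.ifftshift(np.sqrt(uu**2 + vv**2))
    radius[0, 0] = 1.0
    theta = np.fft.ifftshift(np.arctan2(-vv, uu))
    sin_t, cos_t = np.sin(theta), np.cos(theta)
    lp = _lowpass((rows, cols))
    log_gabors = []
    for s in range(nscale):
        f0 = 1.0 / (min_wavelength * mult**s)
        g = np.exp(-(np.log(radius / f0) ** 2) / (2 * np.log(sigma_onf) ** 2))
        g *= lp
        g[0, 0] = 0.0
        log_gabors.append(g)
    theta_sigma = np.pi / norient / d_theta_sigma
    energy_all = np.zeros((rows, cols))
    an_all = np.zeros((rows, cols))
    for o in range(norient):
        angl = o * np.pi / norient
        ds = sin_t * np.cos(angl) - cos_t * np.sin(angl)
        dc = cos_t * np.cos(angl) + sin_t * np.sin(angl)
        dtheta = np.abs(np.arctan2(ds, dc))
        spread = np.exp(-(dtheta**2) / (2 * theta_sigma**2))
        sum_e = np.zeros((rows, cols))
        sum_o = np.zeros((rows, cols))
        sum_an = np.zeros((rows, cols))
        e_scale1_amp = None
        eo = []
        for s in range(nscale):
            filt = log_gabors[s] * spread
            response = np.fft.ifft2(fimg * filt)
            an = np.abs(response)
            sum_an += an
            sum_e += response.real
            sum_o += response.imag
            eo.append(response)
            if s == 0:
                e_scale1_amp = an
        x_energy = np.sqrt(sum_e**2 + sum_o**2) + eps
        mean_e, mean_o = sum_e / x_energy, sum_o / x_energy
        energy = np.zeros((rows, cols))
        for response in eo:
            e, od = response.real, response.imag
            energy += e * mean_e + od * mean_o - np.abs(e * mean_o - od * mean_e)
        # noise floor estimated from the smallest-scale response
        tau = np.median(e_scale1_amp) / np.sqrt(np.log(4))
        total_tau = tau * (1 - (1 / mult) ** nscale) / (1 - 1 / mult)
        noise_mean = total_tau * np.sqrt(np.pi / 2)
        noise_sigma = total_tau * np.sqrt((4 - np.pi) / 2)
        energy = np.maximum(energy - (noise_mean + k_noise * noise_sigma), 0.0)
        energy_all += energy
        an_all += sum_an
    return energy_all / (an_all + eps)


def fsim(reference: np.ndarray, test: np.ndarray, t1: float = 0.85,
         t2: float = 160.0) -> float:
    """Feature similarity on the luminance channel.

    Combines a phase-congruency similarity and a gradient-magnitude
    (Scharr) similarity, pooled with the maximum phase congruency as weight.
    Both images are smoothed and downsampled so the shorter side is ~256 px,
    following the metric's reference procedure.  Degenerate (near-constant)
    image pairs carry no phase congruency and return NaN with a warning.
    """
    x = _luminance(np.asarray(reference, dtype=np.float64))
    y = _luminance(np.asarray(test, dtype=np.float64))
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if x.max() <= 1.5:  # metric constants assume the 0..255 scale
        x, y = x * 255.0, y * 255.0
    f = max(1, int(round(min(x.shape) / 256)))
    if f > 1:
        x = uniform_filter(x, f)[f // 2 :: f, f // 2 :: f]
        y = uniform_filter(y, f)[f // 2 :: f, f // 2 :: f]
    pc1 = _phase_congruency(x)
    pc2 = _phase_congruency(y)
    pcm = np.maximum(pc1, pc2)
    if pcm.sum() < 1e-8:
        log.warning("fsim: phase congruency vanished (constant images?)")
        return float("nan")
    g1 = np.hypot(convolve(x, _SCHARR_X), convolve(x, _SCHARR_X.T))
    g2 = np.hypot(convolve(y, _SCHARR_X), convolve(y, _SCHARR_X.T))
    s_pc = (2 * pc1 * pc2 + t1) / (pc1**2 + pc2**2 + t1)
    s_g = (2 * g1 * g2 + t2) / (g1**2 + g2**2 + t2)
    return float((s_pc * s_g * pcm).sum() / pcm.sum())


# ---------------------------------------------------------------------------
# dice
# ---------------------------------------------------------------------------


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice overlap ``2|X n Y| / (|X| + |Y|)`` between binary masks."""
    x = np.asarray(pred)
    y = np.asarray(truth)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    for m in (x, y):
        vals = np.unique(m)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("masks must be strictly binary (0/1)")
    nx, ny = int(x.sum()), int(y.sum())
    if nx + ny == 0:
        log.info("dice: both masks empty, returning 1 by convention")
        return 1.0
    inter = int(np.logical_and(x, y).sum())
    return 2.0 * inter / (nx + ny)


# ---------------------------------------------------------------------------
# batch harness
# ---------------------------------------------------------------------------


@dataclass
class MetricReport:
    """Per-image full-reference scores plus mean/std aggregates."""

    rows: pd.DataFrame  # columns: image, psnr_db, ssim, fsim
    aggregates: pd.DataFrame  # index mean/std, same metric columns
    n_warnings: int = 0
    lpips: str = "n/a"  # needs pretrained perceptual weights; intentionally absent

    def __str__(self):
        lines = ["metric      mean        std"]
        for m in ("psnr_db", "ssim", "fsim"):
            lines.append(
                f"{m:10s} {self.aggregates.loc['mean', m]:10.4f} "
                f"{self.aggregates.loc['std', m]:10.4f}"
            )
        lines.append(f"{'lpips':10s} {self.lpips:>10s} {self.lpips:>10s}")
        return "\n".join(lines)


def _aggregate(rows: pd.DataFrame) -> pd.DataFrame:
    metrics = rows[["psnr_db", "ssim", "fsim"]]
    return pd.DataFrame(
        {c: [metrics[c].mean(), metrics[c].std(ddof=0)] for c in metrics},
        index=["mean", "std"],
    )


def evaluate_arrays(pairs: list[tuple[str, np.ndarray, np.ndarray]]) -> MetricReport:
    """Score (name, prediction, reference) triples already in memory."""
    records = []
    for name, pred, ref in pairs:
        records.append(
            {
                "image": name,
                "psnr_db": psnr(ref, pred),
                "ssim": ssim(ref, pred),
                "fsim": fsim(ref, pred),
            }
        )
    rows = pd.DataFrame.from_records(records)
    return MetricReport(rows=rows, aggregates=_aggregate(rows))


def evaluate_pairs(
    dir_pred: str | Path,
    dir_ref: str | Path,
    out_csv: str | Path | None = None,
) -> MetricReport:
    """Score every filename present in both directories; write a CSV report.

    Files present in only one directory are listed, skipped, and counted as
    warnings.  Ordering is deterministic (sorted by filename).
    """
    dir_pred, dir_ref = Path(dir_pred), Path(dir_ref)
    names_pred = {p.name for p in dir_pred.iterdir() if p.is_file()}
    names_ref = {p.name for p in dir_ref.iterdir() if p.is_file()}
    common = sorted(names_pred & names_ref)
    unmatched = sorted(names_pred ^ names_ref)
    for name in unmatched:
        log.warning("evaluate: unmatched file skipped: %s", name)
    if not common:
        raise DataError("no matching filenames between the two directories")
    pairs = [
        (name, read_image(dir_pred / name), read_image(dir_ref / name))
        for name in common
    ]
    report = evaluate_arrays(pairs)
    report.n_warnings = len(unmatched)
    if out_csv is not None:
        out_csv = Path(out_csv)
        out_csv.parent.mkdir(parents=True, exist_ok=True)
        body = report.rows.copy()
        agg = report.aggregates.reset_index(names="image")
        pd.concat([body, agg], ignore_index=True).to_csv(out_csv, index=False)
    return report
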