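"""Seeded synthetic pseudo-H&E images in two stain domains.

The generator emulates the situation the method is built for: the *same*
tissue digitized under two different color renderings (two scanners, two
labs).  A latent grayscale stain-density map -- elliptical nuclei over a
low-frequency textured background -- is rendered once per sample and pushed
through two different color palettes, yielding a pixel-aligned pair whose
geometry is bit-identical and whose colors differ.  Unpaired training sets
use different geometry seeds per domain; paired evaluation sets share them.

A palette is a 3x3 linear color matrix applied to the latent transmittance
(bright background, dark nuclei) followed by a per-channel gamma.  Palettes
must be invertible so that no color information is destroyed that the
translation model could not in principle recover.

Seeding is counter-based: one global integer seed fans out to per-image,
per-role (geometry / noise) seeds through ``numpy``'s ``SeedSequence``, so a
dataset of any size is reproducible and any single image can be regenerated
in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .exceptions import ConfigurationError
from .images import DomainImage, write_image

# Default palettes: domain A renders eosin-dominated (pink) tissue, domain B a
# cooler, hematoxylin-leaning rendering of the same structures.
DEFAULT_PALETTE_A = (
    np.array(
        [
            [0.95, 0.04, 0.01],
            [0.06, 0.74, 0.05],
            [0.05, 0.12, 0.78],
        ]
    ),
    np.array([1.0, 1.15, 1.05]),
)
DEFAULT_PALETTE_B = (
    np.array(
        [
            [0.55, 0.08, 0.10],
            [0.06, 0.46, 0.18],
            [0.12, 0.10, 0.72],
        ]
    ),
    np.array([1.40, 1.15, 0.80]),
)


@dataclass(frozen=True)
class Palette:
    """A 3x3 linear color matrix plus per-channel gamma."""

    matrix: np.ndarray
    gamma: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.float64)
        g = np.asarray(self.gamma, dtype=np.float64)
        if m.shape != (3, 3) or g.shape != (3,):
            raise ConfigurationError("palette needs a 3x3 matrix and 3 gammas")
        cond = np.linalg.cond(m)
        if not np.isfinite(cond) or cond > 1e8:
            raise ConfigurationError(
                f"palette matrix is not (numerically) invertible: cond={cond:.3g}"
            )
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "gamma", g)

    def apply(self, transmittance: np.ndarray) -> np.ndarray:
        """Color a latent transmittance field (H, W) into an (H, W, 3) image."""
        rgb = transmittance[..., None] * self.matrix.sum(axis=1)
        rgb = np.clip(rgb, 0.0, 1.0)
        return rgb ** self.gamma


@dataclass(frozen=True)
class SynthConfig:
    """Geometry, palettes and noise for one synthetic sample."""

    image_size: tuple[int, int] = (128, 128)
    n_nuclei: int = 40
    nucleus_radius_range: tuple[float, float] = (4.0, 12.0)
    domain_a_palette: Palette = field(
        default_factory=lambda: Palette(*DEFAULT_PALETTE_A)
    )
    domain_b_palette: Palette = field(
        default_factory=lambda: Palette(*DEFAULT_PALETTE_B)
    )
    noise_sigma: float = 0.02
    texture_amplitude: float = 0.08
    nucleus_density: float = 0.75
    seed: int = 0

    def __post_init__(self):
        h, w = self.image_size
        if h < 16 or w < 16:
            raise ConfigurationError("image_size must be at least 16x16")
        if self.n_nuclei < 0:
            raise ConfigurationError("n_nuclei must be >= 0")


@dataclass
class SynthSample:
    """A pixel-aligned pair of renderings of one latent tissue map."""

    image_a: DomainImage
    image_b: DomainImage
    latent_mask: np.ndarray  # uint8 nucleus/background label map
    density: np.ndarray  # latent stain density in [0, 1]


def _derived_seed(seed: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence((int(seed),) + tuple(int(k) for k in key))


def _latent_tissue(config: SynthConfig, rng: np.random.Generator):
    """Render the latent stain-density map and the nucleus label mask."""
    h, w = config.image_size
    density = np.zeros((h, w))
    if config.texture_amplitude > 0:
        noise = rng.standard_normal((h, w))
        tex = gaussian_filter(noise, sigma=max(h, w) / 16.0, mode="wrap")
        span = tex.max() - tex.min()
        if span > 0:
            tex = (tex - tex.min()) / span
        density += config.texture_amplitude * tex
    mask = np.zeros((h, w), dtype=np.uint8)
    yy, xx = np.mgrid[0:h, 0:w]
    rmin, rmax = config.nucleus_radius_range
    for _ in range(config.n_nuclei):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        r_major = rng.uniform(rmin, rmax)
        r_minor = r_major * rng.uniform(0.6, 1.0)
        theta = rng.uniform(0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        q = (u / r_major) ** 2 + (v / r_minor) ** 2
        # soft edge ~1 px wide gives an anti-aliased rim
        arg = np.clip((q - 1.0) * r_minor * 2.0, -60.0, 60.0)
        edge = 1.0 / (1.0 + np.exp(arg))
        density = np.maximum(density, config.nucleus_density * edge)
        mask |= (q <= 1.0).astype(np.uint8)
    return np.clip(density, 0.0, 1.0), mask


def render_tissue(config: SynthConfig) -> SynthSample:
    """Render one latent tissue map and color it with both palettes.

    Deterministic in ``config.seed``; the latent map (and hence the label
    mask) is bit-identical between the two domain images.
    """
    geom_rng = np.random.default_rng(_derived_seed(config.seed, 0))
    density, mask = _latent_tissue(config, geom_rng)
    transmittance = 1.0 - density
    images = []
    for k, palette in ((1, config.domain_a_palette), (2, config.domain_b_palette)):
        img = palette.apply(transmittance)
        if config.noise_sigma > 0:
            noise_rng = np.random.default_rng(_derived_seed(config.seed, k))
            img = img + noise_rng.normal(0.0, config.noise_sigma, size=img.shape)
        images.append(np.clip(img, 0.0, 1.0))
    return SynthSample(
        image_a=DomainImage(images[0], domain="A"),
        image_b=DomainImage(images[1], domain="B"),
        latent_mask=mask,
        density=density,
    )


def make_unpaired_dataset(
    config: SynthConfig, n_per_domain: int, disjoint_seeds: bool = True
) -> tuple[list[SynthSample], list[SynthSample]]:
    """Generate two stain-domain image collections.

    With ``disjoint_seeds`` (the training situation) the two domains show
    different tissue; without it each index is a pixel-aligned pair (the
    evaluation situation).  Returns ``(samples_a, samples_b)``; callers use
    ``image_a`` from the first list and ``image_b`` from the second.
    """
    if n_per_domain < 1:
        raise ConfigurationError("n_per_domain must be >= 1")
    samples_a, samples_b = [], []
    for i in range(n_per_domain):
        if disjoint_seeds:
            seed_a = int(_derived_seed(config.seed, i, 0).generate_state(1)[0] % 2**31)
            seed_b = int(_derived_seed(config.seed, i, 1).generate_state(1)[0] % 2**31)
            samples_a.append(render_tissue(replace(config, seed=seed_a)))
            samples_b.append(render_tissue(replace(config, seed=seed_b)))
        else:
            seed_i = int(_derived_seed(config.seed, i).generate_state(1)[0] % 2**31)
            s = render_tissue(replace(config, seed=seed_i))
            samples_a.append(s)
            samples_b.append(s)
    return samples_a, samples_b


def write_dataset(
    out_dir: str | Path,
    config: SynthConfig,
    n_per_domain: int,
    disjoint_seeds: bool = True,
) -> dict[str, list[Path]]:
    """Write a dataset as 8-bit PNGs under ``domainA/``, ``domainB/`` (+``masks/``).

    Paired sets (``disjoint_seeds=False``) also write the shared nucleus masks.
    A ``manifest.txt`` lists every written file, one path per line.
    """
    out_dir = Path(out_dir)
    samples_a, samples_b = make_unpaired_dataset(config, n_per_domain, disjoint_seeds)
    written: dict[str, list[Path]] = {"domainA": [], "domainB": [], "masks": []}
    for i, (sa, sb) in enumerate(zip(samples_a, samples_b)):
        pa = out_dir / "domainA" / f"img_{i:04d}.png"
        pb = out_dir / "domainB" / f"img_{i:04d}.png"
        write_image(pa, sa.image_a.pixels)
        write_image(pb, sb.image_b.pixels)
        written["domainA"].append(pa)
        written["domainB"].append(pb)
        if not disjoint_seeds:
            pm = out_dir / "masks" / f"img_{i:04d}.png"
            write_image(pm, np.stack([sa.latent_mask.astype(float)] * 3, axis=-1))
            written["masks"].append(pm)
    manifest = out_dir / "manifest.txt"
    manifest.parent.mkdir(parents=True, exist_ok=True)
    with open(manifest, "w") as fh:
        for group in ("domainA", "domainB", "masks"):
            for p in written[group]:
                fh.write(str(p.relative_to(out_dir)) + "\n")
    return written
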