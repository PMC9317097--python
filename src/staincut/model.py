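"""Model/Results objects presenting the stain-transfer workflow.

``StainCUT`` is constructed from two *unpaired* image collections (the source
and target stain domains); ``fit()`` runs the adversarial + contrastive
training protocol and returns ``StainCUTResults``, which carries the trained
generator, the loss trajectory, diagnostics, and the staining / evaluation
entry points.  The CLI wraps these same objects.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .inference import stain_image
from .losses import NCEConfig
from .metrics import MetricReport, evaluate_arrays
from .networks import count_parameters
from .training import TrainConfig, TrainState, train
from .training import _load_domain


class StainCUT:
    """Unpaired stain-transfer model (source domain A -> target domain B).

    Parameters
    ----------
    images_a, images_b : lists of (H, W, 3) float arrays in [0, 1]
        Unpaired training images for the two stain domains.
    config : TrainConfig, optional
        Training protocol; defaults follow the published recipe (30 epochs,
        batch 4, Adam lr 2e-4, 512 crops) and can be scaled down.
    """

    def __init__(self, images_a, images_b, config: TrainConfig | None = None):
        if not images_a or not images_b:
            raise ConfigurationError("both domains need at least one image")
        self.images_a = [np.asarray(im, dtype=np.float64) for im in images_a]
        self.images_b = [np.asarray(im, dtype=np.float64) for im in images_b]
        self.config = config or TrainConfig()

    @classmethod
    def from_directories(
        cls, domain_a_dir, domain_b_dir, config: TrainConfig | None = None
    ) -> "StainCUT":
        config = config or TrainConfig()
        return cls(
            _load_domain(domain_a_dir, config.crop_size),
            _load_domain(domain_b_dir, config.crop_size),
            config,
        )

    def fit(
        self,
        max_steps: int | None = None,
        out_dir=None,
        epoch_callback=None,
        state: TrainState | None = None,
    ) -> "StainCUTResults":
        state = train(
            self.config,
            images_a=self.images_a,
            images_b=self.images_b,
            out_dir=out_dir,
            state=state,
            max_steps=max_steps,
            epoch_callback=epoch_callback,
        )
        return StainCUTResults(state)


class StainCUTResults:
    """Fitted stain-transfer model: trained networks plus diagnostics."""

    def __init__(self, state: TrainState):
        self.state = state
        self.config = state.config

    @property
    def generator(self):
        return self.state.generator

    @property
    def history(self) -> pd.DataFrame:
        """Loss breakdown per training step."""
        return pd.DataFrame(self.state.history)

    def stain(self, image: np.ndarray, tile_size: int | None = None,
              stride: int | None = None) -> np.ndarray:
        """Translate a [0, 1] RGB image of any size into the target stain."""
        tile_size = tile_size or self.config.crop_size
        stride = stride or max(1, tile_size // 2)
        return stain_image(self.generator, image, tile_size, stride)

    def evaluate(self, pairs: list[tuple[np.ndarray, np.ndarray]],
                 tile_size: int | None = None) -> MetricReport:
        """Stain each source image and score it against its aligned target."""
        triples = []
        for i, (src, ref) in enumerate(pairs):
            triples.append((f"pair_{i:03d}", self.stain(src, tile_size), ref))
        return evaluate_arrays(triples)

    def save(self, path) -> None:
        self.state.save(path)

    @classmethod
    def load(cls, path) -> "StainCUTResults":
        return cls(TrainState.load(path))

    def summary(self) -> str:
        """Text summary: architecture accounting, protocol, final losses."""
        cfg = self.config
        n_g = count_parameters(self.state.generator)
        n_d = count_parameters(self.state.discriminator)
        n_h = count_parameters(self.state.heads)
        lines = [
            "Stain-transfer results (contrastive unpaired translation)",
            "=" * 60,
            f"generator          modified UNet, {cfg.n_blocks} blocks, "
            f"base {cfg.base_channels}, cap {cfg.max_channels}",
            f"params             G {n_g:,} | D {n_d:,} | heads {n_h:,} "
            f"| total {n_g + n_d + n_h:,}",
            f"feature layers     {self.state.layer_ids} "
            f"({cfg.n_feature_layers} evenly spaced encoder stages)",
            f"contrastive        tau={cfg.nce.tau}  n_locations={cfg.nce.n_locations}  "
            f"lambda_x={cfg.nce.lambda_x}  lambda_y={cfg.nce.lambda_y}",
            f"protocol           epochs={cfg.epochs}  batch={cfg.batch_size}  "
            f"lr={cfg.learning_rate}  crop={cfg.crop_size}  seed={cfg.seed}",
            f"progress           epoch {self.state.epoch}, "
            f"{self.state.step_count} steps",
        ]
        if self.state.history:
            last = self.state.history[-1]
            lines.append(
                "final losses       "
                f"D {last['loss_d']:.4f} | G_gan {last['loss_g_gan']:.4f} | "
                f"NCE_x {last['loss_nce_x']:.4f} | NCE_y {last['loss_nce_y']:.4f} | "
                f"total {last['loss_g_total']:.4f}"
            )
        return "\n".join(lines)
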