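"""Unpaired adversarial training with patch-wise contrastive content loss.

Each step alternates one discriminator update (real = a target-domain batch,
fake = the generator's translation of a source-domain batch, detached) with
one joint generator + projection-heads update on the total objective.  The
contrastive term samples the same spatial locations in the encoder features
of the input and of its translation; gradients flow into the generator both
through the synthesis path and through re-encoding the translated image.

All randomness (batch sampling, crops, flips, location sampling, weight
initialization) descends from a single integer seed, and a training run can
be checkpointed and resumed without changing the parameter trajectory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import ConfigurationError, DataError, NumericError
from .images import hwc_to_nchw, read_image, unit_to_tanh
from .losses import NCEConfig, _patchnce_core
from .networks import (
    DiscriminatorSpec,
    GeneratorSpec,
    PatchGANDiscriminator,
    ProjectionHeads,
    UNetGenerator,
    select_feature_layers,
)
from .nn import Adam

log = logging.getLogger("staincut.training")


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol hyperparameters.

    The published protocol trains for 30 epochs with batch size 4, Adam at
    learning rate 2e-4, and random 512x512 crops; reduced settings (smaller
    crops, narrower generators) train the same objective at desk scale.
    """

    epochs: int = 30
    batch_size: int = 4
    learning_rate: float = 2e-4
    adam_betas: tuple[float, float] = (0.5, 0.999)
    crop_size: int = 512
    n_blocks: int = 8
    base_channels: int = 64
    max_channels: int = 512
    n_feature_layers: int = 5
    nce: NCEConfig = field(default_factory=NCEConfig)
    gan_mode: str = "lsgan"
    flip_augment: bool = True
    lr_decay_steps: int | None = None  # linear decay to 0 over this many steps
    lr_decay_start: int = 0
    seed: int = 0

    def __post_init__(self):
        spec = self.generator_spec()
        if self.crop_size % spec.size_divisor:
            raise ConfigurationError(
                f"crop_size {self.crop_size} must be divisible by "
                f"2**(n_blocks+1) = {spec.size_divisor}"
            )
        if self.batch_size < 1 or self.epochs < 0:
            raise ConfigurationError("batch_size >= 1 and epochs >= 0 required")

    def generator_spec(self) -> GeneratorSpec:
        return GeneratorSpec(
            n_blocks=self.n_blocks,
            base_channels=self.base_channels,
            max_channels=self.max_channels,
        )


class TrainState:
    """Everything needed to continue (or replay) a training run."""

    def __init__(self, config: TrainConfig):
        self.config = config
        seed = np.random.SeedSequence(config.seed)
        s_g, s_d, s_h, s_loop = seed.spawn(4)
        self.generator = UNetGenerator(
            config.generator_spec(), np.random.default_rng(s_g)
        )
        self.discriminator = PatchGANDiscriminator(
            DiscriminatorSpec(), np.random.default_rng(s_d)
        )
        self.heads = ProjectionHeads()
        self._head_rng = np.random.default_rng(s_h)
        self.rng = np.random.default_rng(s_loop)
        self.layer_ids = select_feature_layers(
            config.generator_spec(), config.n_feature_layers
        )
        self.opt_g = Adam(
            self.generator.parameters(), config.learning_rate, config.adam_betas
        )
        self.opt_d = Adam(
            self.discriminator.parameters(), config.learning_rate, config.adam_betas
        )
        self.opt_h: Adam | None = None  # created once the lazy heads exist
        self.epoch = 0
        self.step_count = 0
        self.history: list[dict] = []

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays: dict[str, np.ndarray] = {}
        for tag, module in (
            ("g", self.generator),
            ("d", self.discriminator),
            ("h", self.heads),
        ):
            for name, p in module.named_parameters():
                arrays[f"{tag}::{name}"] = p.data
        for tag, opt in (("og", self.opt_g), ("od", self.opt_d), ("oh", self.opt_h)):
            if opt is None:
                continue
            for i, (m, v) in enumerate(zip(opt.m, opt.v)):
                arrays[f"{tag}::m{i}"] = m
                arrays[f"{tag}::v{i}"] = v
        meta = {
            "config": _config_dict(self.config),
            "epoch": self.epoch,
            "step": self.step_count,
            "layer_ids": self.layer_ids,
            "head_layers": self.heads.built_layers,
            "head_channels": {
                str(lid): self.heads._mlps[lid][0].cin for lid in self.heads.built_layers
            },
            "opt_t": {
                "og": self.opt_g.t,
                "od": self.opt_d.t,
                "oh": self.opt_h.t if self.opt_h else None,
            },
            "rng_state": self.rng.bit_generator.state,
            "head_rng_state": self._head_rng.bit_generator.state,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TrainState":
        with np.load(Path(path)) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            config = _config_from_dict(meta["config"])
            state = cls(config)
            state.epoch = meta["epoch"]
            state.step_count = meta["step"]
            state.layer_ids = list(meta["layer_ids"])
            if meta["head_layers"]:
                channels = {int(k): v for k, v in meta["head_channels"].items()}
                state.heads.build(channels, state._head_rng)
                state.opt_h = Adam(
                    state.heads.parameters(),
                    config.learning_rate,
                    config.adam_betas,
                )
            for tag, module in (
                ("g", state.generator),
                ("d", state.discriminator),
                ("h", state.heads),
            ):
                names = dict(module.named_parameters())
                for name, p in names.items():
                    p.data[...] = data[f"{tag}::{name}"]
            for tag, opt in (
                ("og", state.opt_g),
                ("od", state.opt_d),
                ("oh", state.opt_h),
            ):
                if opt is None:
                    continue
                opt.t = meta["opt_t"][tag] or 0
                for i in range(len(opt.m)):
                    if f"{tag}::m{i}" in data:
                        opt.m[i][...] = data[f"{tag}::m{i}"]
                        opt.v[i][...] = data[f"{tag}::v{i}"]
            state.rng.bit_generator.state = meta["rng_state"]
            state._head_rng.bit_generator.state = meta["head_rng_state"]
        return state


def _config_dict(config: TrainConfig) -> dict:
    d = asdict(config)
    d["nce"] = asdict(config.nce)
    return d


def _config_from_dict(d: dict) -> TrainConfig:
    d = dict(d)
    d["nce"] = NCEConfig(**d["nce"])
    d["adam_betas"] = tuple(d["adam_betas"])
    return TrainConfig(**d)


# ---------------------------------------------------------------------------
# the training step
# ---------------------------------------------------------------------------


def _lsgan_grad_and_loss(scores, target):
    diff = scores - target
    return float((diff**2).mean()), 2.0 * diff / scores.size


def _scatter_feature_grads(shape, idx, d_sel):
    """Inverse of the (B, C, H, W) -> sampled (B, n, C) selection."""
    b, c, h, w = shape
    flat = np.zeros((b, h * w, c))
    flat[:, idx, :] = d_sel
    return flat.reshape(b, h, w, c).transpose(0, 3, 1, 2)


def _nce_branch(state: TrainState, feats_src, fake, tau):
    """Compute one PatchNCE branch with gradients.

    ``feats_src`` are encoder stages of the branch input (from the generator
    forward cache); ``fake`` is its translation, re-encoded here.  Returns
    (loss, d_fake, src_feature_grads).
    """
    cfg = state.config
    heads = state.heads
    feats_out, enc_cache_out = state.generator.encode(fake)
    heads.build({lid: feats_src[lid].shape[1] for lid in state.layer_ids},
                state._head_rng)
    z_src, z_out = {}, {}
    caches_src, caches_out = {}, {}
    idx_by_layer = {}
    for lid in state.layer_ids:
        b, c, h, w = feats_src[lid].shape
        s_l = h * w
        n = min(cfg.nce.n_locations, s_l)
        if n == s_l:
            idx = np.arange(s_l, dtype=np.intp)
        else:
            idx = np.sort(state.rng.choice(s_l, size=n, replace=False)).astype(np.intp)
        idx_by_layer[lid] = idx
        sel_src = feats_src[lid].reshape(b, c, s_l).transpose(0, 2, 1)[:, idx, :]
        sel_out = feats_out[lid].reshape(b, c, s_l).transpose(0, 2, 1)[:, idx, :]
        z_src[lid], caches_src[lid] = heads.forward_layer(lid, sel_src)
        z_out[lid], caches_out[lid] = heads.forward_layer(lid, sel_out)
    loss, dz_src, dz_out = _patchnce_core(z_src, z_out, tau, want_grads=True)
    fg_src = {}
    fg_out = {}
    for lid in state.layer_ids:
        d_sel_src = heads.backward_layer(caches_src[lid], dz_src[lid])
        d_sel_out = heads.backward_layer(caches_out[lid], dz_out[lid])
        fg_src[lid] = _scatter_feature_grads(
            feats_src[lid].shape, idx_by_layer[lid], d_sel_src
        )
        fg_out[lid] = _scatter_feature_grads(
            feats_out[lid].shape, idx_by_layer[lid], d_sel_out
        )
    d_fake = state.generator.encode_backward(enc_cache_out, fg_out)
    return loss, d_fake, fg_src


def step(
    state: TrainState,
    batch_a: np.ndarray,
    batch_b: np.ndarray,
    update: bool = True,
) -> dict[str, float]:
    """One alternating update; returns the loss breakdown.

    With ``update=False`` all losses are evaluated at the current parameters
    and no optimizer runs; the RNG still advances identically.  Note that in
    a normal (updating) step the generator-side losses see the discriminator
    *after* its half-step, so replaying a logged step from a checkpoint means
    re-running ``step`` with updates on the reloaded state.  Gradient buffers
    are scratch space in either mode.
    """
    if batch_a.shape != batch_b.shape:
        raise ValueError("domain batches must share a shape")
    cfg = state.config
    g, d = state.generator, state.discriminator
    if update and cfg.lr_decay_steps:
        frac = (state.step_count - cfg.lr_decay_start) / cfg.lr_decay_steps
        lr = cfg.learning_rate * float(np.clip(1.0 - frac, 0.0, 1.0))
        for opt in (state.opt_d, state.opt_g, state.opt_h):
            if opt is not None:
                opt.lr = lr
    dtype = g.stem.weight.data.dtype
    batch_a = np.ascontiguousarray(batch_a, dtype=dtype)
    batch_b = np.ascontiguousarray(batch_b, dtype=dtype)

    # one generator forward feeds both half-steps: the discriminator update
    # treats `fake` as a constant, and does not touch generator parameters,
    # so the cached forward stays valid for the generator update below
    fake, cache_ga = g.forward(batch_a)

    # ---- discriminator half-step (fake detached) ----
    d.zero_grad()
    real_scores, cache_dr = d.forward(batch_b)
    fake_scores, cache_df = d.forward(fake)
    loss_dr, grad_r = _lsgan_grad_and_loss(real_scores, 1.0)
    loss_df, grad_f = _lsgan_grad_and_loss(fake_scores, 0.0)
    loss_d = 0.5 * (loss_dr + loss_df)
    if update:
        d.backward(cache_dr, 0.5 * grad_r)
        d.backward(cache_df, 0.5 * grad_f)
        state.opt_d.step()

    # ---- generator + heads half-step ----
    g.zero_grad()
    state.heads.zero_grad()
    scores, cache_ds = d.forward(fake)
    loss_g_gan, dscores = _lsgan_grad_and_loss(scores, 1.0)
    d.zero_grad()  # discard discriminator grads from the generator pass
    d_fake_gan = d.backward(cache_ds, dscores)
    d.zero_grad()

    tau = cfg.nce.tau
    feats_a = g.cache_features(cache_ga)
    loss_nce_x, d_fake_nce, fg_a = _nce_branch(state, feats_a, fake, tau)

    loss_nce_y = 0.0
    if cfg.nce.lambda_y > 0:
        fake_b, cache_gb = g.forward(batch_b)
        feats_b = g.cache_features(cache_gb)
        loss_nce_y, d_fakeb_nce, fg_b = _nce_branch(state, feats_b, fake_b, tau)

    total = loss_g_gan + cfg.nce.lambda_x * loss_nce_x + cfg.nce.lambda_y * loss_nce_y

    breakdown = {
        "step": state.step_count,
        "loss_d": loss_d,
        "loss_g_gan": loss_g_gan,
        "loss_nce_x": loss_nce_x,
        "loss_nce_y": loss_nce_y,
        "loss_g_total": total,
    }
    for key, value in breakdown.items():
        if not np.isfinite(value):
            raise NumericError(
                f"non-finite loss at step {state.step_count}: {key}={value}; "
                "inputs preserved on the state for inspection"
            )

    if update:
        dfake = d_fake_gan + cfg.nce.lambda_x * d_fake_nce
        g.backward(cache_ga, dfake,
                   {k: cfg.nce.lambda_x * v for k, v in fg_a.items()})
        if cfg.nce.lambda_y > 0:
            g.backward(cache_gb, cfg.nce.lambda_y * d_fakeb_nce,
                       {k: cfg.nce.lambda_y * v for k, v in fg_b.items()})
        if state.opt_h is None and state.heads.parameters():
            state.opt_h = Adam(
                state.heads.parameters(), cfg.learning_rate, cfg.adam_betas
            )
        state.opt_g.step()
        if state.opt_h is not None:
            state.opt_h.step()
        state.step_count += 1
        state.history.append(breakdown)
    log.info(
        "step=%d loss_d=%.5f loss_g_gan=%.5f nce_x=%.5f nce_y=%.5f total=%.5f",
        breakdown["step"], loss_d, loss_g_gan, loss_nce_x, loss_nce_y, total,
    )
    return breakdown


# ---------------------------------------------------------------------------
# the training loop
# ---------------------------------------------------------------------------


def _load_domain(path: str | Path, crop: int) -> list[np.ndarray]:
    path = Path(path)
    if not path.is_dir():
        raise ConfigurationError(f"domain directory does not exist: {path}")
    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff", ".jpg", ".jpeg")
    )
    images = []
    for f in files:
        img = read_image(f)
        if img.shape[0] < crop or img.shape[1] < crop:
            log.warning("skipping %s: %dx%d smaller than crop %d",
                        f.name, img.shape[0], img.shape[1], crop)
            continue
        images.append(img)
    if not images:
        raise ConfigurationError(
            f"domain directory {path} holds no usable image of size >= {crop}"
        )
    return images


def _make_batch(images, rng, batch_size, crop, flip):
    batch = []
    for _ in range(batch_size):
        img = images[int(rng.integers(len(images)))]
        top = int(rng.integers(img.shape[0] - crop + 1))
        left = int(rng.integers(img.shape[1] - crop + 1))
        patch = img[top : top + crop, left : left + crop]
        if flip:
            if rng.random() < 0.5:
                patch = patch[:, ::-1]
            if rng.random() < 0.5:
                patch = patch[::-1, :]
        batch.append(hwc_to_nchw(unit_to_tanh(patch))[0])
    return np.stack(batch)


def train(
    config: TrainConfig,
    domain_a_dir: str | Path | None = None,
    domain_b_dir: str | Path | None = None,
    out_dir: str | Path | None = None,
    images_a: list[np.ndarray] | None = None,
    images_b: list[np.ndarray] | None = None,
    state: TrainState | None = None,
    max_steps: int | None = None,
    epoch_callback=None,
) -> TrainState:
    """Run (or resume) the unpaired training protocol.

    Either directories or in-memory ``[0, 1]`` HWC image lists feed each
    domain.  A checkpoint ``ckpt_epoch_{k}.npz`` is written per epoch when
    ``out_dir`` is given.
    """
    if images_a is None:
        images_a = _load_domain(domain_a_dir, config.crop_size)
    if images_b is None:
        images_b = _load_domain(domain_b_dir, config.crop_size)
    if not images_a or not images_b:
        raise ConfigurationError("both domains need at least one image")
    if state is None:
        state = TrainState(config)
    out_dir = Path(out_dir) if out_dir is not None else None
    steps_per_epoch = max(1, min(len(images_a), len(images_b)) // config.batch_size)
    done = 0
    for epoch in range(state.epoch, config.epochs):
        for _ in range(steps_per_epoch):
            if max_steps is not None and done >= max_steps:
                state.epoch = epoch
                return state
            batch_a = _make_batch(images_a, state.rng, config.batch_size,
                                  config.crop_size, config.flip_augment)
            batch_b = _make_batch(images_b, state.rng, config.batch_size,
                                  config.crop_size, config.flip_augment)
            step(state, batch_a, batch_b)
            done += 1
        state.epoch = epoch + 1
        if out_dir is not None:
            state.save(out_dir / f"ckpt_epoch_{epoch + 1}.npz")
        if epoch_callback is not None:
            epoch_callback(state)
    return state
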