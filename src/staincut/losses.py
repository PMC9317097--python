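"""Objectives for contrastive unpaired stain transfer.

The total objective combines an adversarial term with a patch-wise
contrastive (PatchNCE) term on both translation and identity branches:

    L = L_GAN(G, D, X, Y) + lambda_X L_PatchNCE(G, H, X) + lambda_Y L_PatchNCE(G, H, Y)

PatchNCE matches the embedding of each sampled spatial location of the
*output* image's encoder features (the query) against the co-located
embedding of the *input* image (the positive); the other sampled locations of
the same layer and same input image act as negatives.  Dot products of the
L2-normalized embeddings are scaled by a temperature tau and fed through the
noise-contrastive (InfoNCE) log-softmax.

Per-location losses are averaged (not summed) over locations and layers so
the loss magnitude does not depend on the number of sampled locations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError
from .networks import ProjectionHeads, UNetGenerator

__all__ = [
    "NCEConfig",
    "FeatureStack",
    "nce_loss",
    "sample_patch_embeddings",
    "patchnce_loss",
    "gan_loss",
    "total_objective",
]


@dataclass(frozen=True)
class NCEConfig:
    """Contrastive-loss hyperparameters."""

    tau: float = 0.07
    n_locations: int = 256
    lambda_x: float = 1.0
    lambda_y: float = 1.0

    def __post_init__(self):
        if self.tau <= 0:
            raise ConfigurationError("tau must be > 0")
        if self.n_locations < 1:
            raise ConfigurationError("n_locations must be >= 1")
        if self.lambda_x < 0 or self.lambda_y < 0:
            raise ConfigurationError("lambda weights must be >= 0")


@dataclass
class FeatureStack:
    """Per-layer sampled, projected encoder features of one image (batch).

    ``embeddings[l]`` has shape (B, S_l, 256) with unit-norm rows;
    ``indices[l]`` holds the flattened spatial locations that were sampled,
    shared across the batch.  ``clamped`` records layers where the requested
    number of locations exceeded the layer's spatial size.
    """

    layer_ids: list[int]
    indices: dict[int, np.ndarray]
    embeddings: dict[int, np.ndarray]
    raw: dict[int, np.ndarray] = field(default_factory=dict)
    clamped: dict[int, int] = field(default_factory=dict)


def nce_loss(v, v_pos, v_negs, tau: float = 0.07) -> float:
    """InfoNCE: negative log-softmax of the positive among the negatives.

    Logits are dot products divided by ``tau``, stabilized by a max-shift.
    With zero negatives the softmax has a single class and the loss is 0.
    """
    if tau <= 0:
        raise ConfigurationError("tau must be > 0")
    v = np.asarray(v, dtype=np.float64)
    v_pos = np.asarray(v_pos, dtype=np.float64)
    if v.shape != v_pos.shape:
        raise ValueError(f"v and v_pos shapes differ: {v.shape} vs {v_pos.shape}")
    v_negs = np.asarray(v_negs, dtype=np.float64).reshape(-1, v.shape[-1]) \
        if np.size(v_negs) else np.empty((0, v.shape[-1]))
    pos_logit = float(v @ v_pos) / tau
    neg_logits = (v_negs @ v) / tau
    logits = np.concatenate([[pos_logit], neg_logits])
    m = logits.max()
    return float(m + np.log(np.exp(logits - m).sum()) - pos_logit)


def _flatten_feats(fmap: np.ndarray) -> np.ndarray:
    """(B, C, H, W) -> (B, H*W, C)."""
    b, c, h, w = fmap.shape
    return fmap.reshape(b, c, h * w).transpose(0, 2, 1)


def sample_patch_embeddings(
    gen_encoder: UNetGenerator,
    heads: ProjectionHeads,
    image: np.ndarray,
    layer_ids: list[int],
    n_locations: int = 256,
    location_indices: dict[int, np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
) -> FeatureStack:
    """Encode an image, sample spatial locations per layer, project to 256-d.

    When ``location_indices`` is given the same locations are reused -- the
    mechanism that co-locates positives between an input image and its
    translation.  Otherwise fresh locations are drawn uniformly without
    replacement from the seeded ``rng``.  Requests exceeding a layer's
    spatial size are clamped to it (and recorded in ``clamped``).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    batch = np.asarray(image, dtype=np.float64)
    if batch.ndim == 3:
        batch = batch[None]
    feats, _ = gen_encoder.encode(batch)
    # lazy head init draws from a spawned stream so that location sampling
    # consumes the same numbers whether or not the heads already exist
    heads.build({lid: feats[lid].shape[1] for lid in layer_ids}, rng.spawn(1)[0])
    indices: dict[int, np.ndarray] = {}
    embeddings: dict[int, np.ndarray] = {}
    raw: dict[int, np.ndarray] = {}
    clamped: dict[int, int] = {}
    for lid in layer_ids:
        flat = _flatten_feats(feats[lid])  # (B, S, C)
        s_l = flat.shape[1]
        if location_indices is not None:
            idx = np.asarray(location_indices[lid], dtype=np.intp)
            if idx.size and (idx.min() < 0 or idx.max() >= s_l):
                raise ValueError(
                    f"location indices out of range for layer {lid} (S={s_l})"
                )
        else:
            n = n_locations
            if n >= s_l:
                if n > s_l:
                    clamped[lid] = s_l
                idx = np.arange(s_l, dtype=np.intp)
            else:
                idx = np.sort(rng.choice(s_l, size=n, replace=False)).astype(np.intp)
        sel = flat[:, idx, :]
        z, _ = heads.forward_layer(lid, sel)
        indices[lid] = idx
        embeddings[lid] = z
        raw[lid] = sel
    return FeatureStack(list(layer_ids), indices, embeddings, raw, clamped)


def patchnce_loss(stack_src: FeatureStack, stack_out: FeatureStack) -> float:
    """PatchNCE: mean InfoNCE over layers and sampled locations.

    For every layer and location ``s`` the query is the output embedding at
    ``s``, the positive is the co-located source embedding, and the negatives
    are the source embeddings at the other sampled locations of the same
    layer and same image.
    """
    if stack_src.layer_ids != stack_out.layer_ids:
        raise ValueError("feature stacks were built from different layers")
    for lid in stack_src.layer_ids:
        if not np.array_equal(stack_src.indices[lid], stack_out.indices[lid]):
            raise ValueError(
                f"location indices differ at layer {lid}: positives would "
                "not be co-located"
            )
    loss, _, _ = _patchnce_core(
        {l: stack_src.embeddings[l] for l in stack_src.layer_ids},
        {l: stack_out.embeddings[l] for l in stack_out.layer_ids},
        tau=0.07,
        want_grads=False,
    )
    return loss


def _patchnce_core(z_src, z_out, tau, want_grads):
    """Shared forward (and optional gradient) of the PatchNCE objective.

    ``z_src``/``z_out`` map layer id -> (B, S, E) unit-norm embeddings.
    Returns (loss, dz_src, dz_out); the total is the mean over layers,
    batch and locations.
    """
    layer_ids = sorted(z_src)
    n_terms = sum(z_src[l].shape[0] * z_src[l].shape[1] for l in layer_ids)
    total = 0.0
    d_src = {} if want_grads else None
    d_out = {} if want_grads else None
    for lid in layer_ids:
        zs, zo = z_src[lid], z_out[lid]
        logits = np.matmul(zo, zs.transpose(0, 2, 1)) / tau  # (B, S, S)
        m = logits.max(axis=2, keepdims=True)
        e = np.exp(logits - m)
        denom = e.sum(axis=2, keepdims=True)
        logp = logits - m - np.log(denom)
        s = zs.shape[1]
        diag = np.arange(s)
        total += -logp[:, diag, diag].sum()
        if want_grads:
            p = e / denom
            p[:, diag, diag] -= 1.0
            p /= n_terms * tau
            d_out[lid] = np.matmul(p, zs)
            d_src[lid] = np.matmul(p.transpose(0, 2, 1), zo)
    return total / n_terms, d_src, d_out


def _score_map(discriminator, batch):
    out = discriminator.forward(batch) if hasattr(discriminator, "forward") \
        else discriminator(batch)
    if isinstance(out, tuple):
        out = out[0]
    return out


def gan_loss(discriminator, real_batch, fake_batch, side: str, mode: str = "lsgan"):
    """Adversarial loss averaged over the PatchGAN score map.

    ``mode='lsgan'`` (default): least squares -- the discriminator pushes real
    scores to 1 and fake scores to 0, the generator pushes fake scores to 1.
    ``mode='log'`` restores the literal cross-entropy form; score-map values
    are then read as probabilities and clipped away from {0, 1}.
    """
    if side not in ("generator", "discriminator"):
        raise ConfigurationError(f"side must be generator|discriminator, got {side!r}")
    if mode not in ("lsgan", "log"):
        raise ConfigurationError(f"unknown gan loss mode {mode!r}")
    fake = _score_map(discriminator, fake_batch)
    if mode == "lsgan":
        if side == "generator":
            return float(((fake - 1.0) ** 2).mean())
        real = _score_map(discriminator, real_batch)
        return float(0.5 * ((real - 1.0) ** 2).mean() + 0.5 * (fake**2).mean())
    eps = 1e-7
    fake = np.clip(fake, eps, 1 - eps)
    if side == "generator":
        return float(-np.log(fake).mean())
    real = np.clip(_score_map(discriminator, real_batch), eps, 1 - eps)
    return float(-np.log(real).mean() - np.log(1.0 - fake).mean())


def total_objective(
    gan: float,
    nce_x: float,
    nce_y: float,
    lambda_x: float = 1.0,
    lambda_y: float = 1.0,
) -> tuple[float, dict[str, float]]:
    """Weighted sum of the adversarial and the two PatchNCE terms."""
    if lambda_x < 0 or lambda_y < 0:
        raise ConfigurationError("lambda weights must be >= 0")
    breakdown = {
        "gan": float(gan),
        "nce_x": float(nce_x),
        "nce_y": float(nce_y),
        "lambda_x": lambda_x,
        "lambda_y": lambda_y,
    }
    total = float(gan + lambda_x * nce_x + lambda_y * nce_y)
    breakdown["total"] = total
    return total, breakdown
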