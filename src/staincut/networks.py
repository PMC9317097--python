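"""Network architectures for contrastive stain transfer.

The generator is a modified UNet: a single k=4/s=2/p=1 convolution per
downsampling step (instead of the classic pair of 3x3 convolutions), instance
normalization and LeakyReLU(0.2) after every inner convolution, transposed
convolutions of the same geometry for upsampling, and skip connections that
concatenate encoder features into the decoder.  An input stem convolution
lifts RGB to ``base_channels`` and the final transposed convolution returns to
3 channels through a Tanh, so a generator with ``n_blocks`` encoder blocks
downsamples ``n_blocks + 1`` times in total and requires input sizes divisible
by ``2**(n_blocks+1)``.

Frozen micro-choices (they fix the parameter count exactly):

* stem and final layers carry no normalization;
* every convolution has a bias; instance norm has no affine parameters;
* channel width after encoder block ``k`` is ``min(base * 2**k, max_channels)``;
* decoder step from level ``j`` outputs the encoder width of level ``j - 1``
  and then concatenates the level ``j - 1`` encoder features.

With the published widths (base 64, cap 512) the generator alone has
16,657,795 / 41,825,667 / 66,993,539 parameters for 4/6/8 blocks.  The full
trainable setup additionally holds a 70x70 PatchGAN discriminator (2,764,737)
and one two-layer MLP projection head per selected encoder stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError
from .nn import (
    Conv2d,
    ConvTranspose2d,
    InstanceNorm2d,
    LeakyReLU,
    Linear,
    Module,
    ReLU,
    Tanh,
    conv_out_size,
)
from .nn import count_parameters as _count_parameters

count_parameters = _count_parameters


@dataclass(frozen=True)
class GeneratorSpec:
    """Hyperparameters that fully determine the modified-UNet generator."""

    n_blocks: int = 8
    base_channels: int = 64
    max_channels: int = 512
    down_kernel: int = 4
    down_stride: int = 2
    down_padding: int = 1
    leaky_slope: float = 0.2
    init_std: float = 0.02

    def __post_init__(self):
        if self.n_blocks < 1:
            raise ConfigurationError("n_blocks must be >= 1")
        if self.base_channels < 1 or self.max_channels < self.base_channels:
            raise ConfigurationError("need 1 <= base_channels <= max_channels")

    def channels(self) -> list[int]:
        """Encoder stage widths: stem output plus each block output."""
        return [self.base_channels] + [
            min(self.base_channels * 2**i, self.max_channels)
            for i in range(1, self.n_blocks + 1)
        ]

    @property
    def n_stages(self) -> int:
        """Number of encoder feature stages (stem + blocks)."""
        return self.n_blocks + 1

    @property
    def size_divisor(self) -> int:
        return 2 ** (self.n_blocks + 1)


@dataclass(frozen=True)
class DiscriminatorSpec:
    """The standard 70x70 PatchGAN: widths 64-128-256-512, then a 1-channel map."""

    base_channels: int = 64
    n_layers: int = 3
    init_std: float = 0.02


class UNetGenerator(Module):
    """G = G_dec o G_enc with concatenating skip connections."""

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        c = spec.channels()
        k, s, p = spec.down_kernel, spec.down_stride, spec.down_padding
        std = spec.init_std
        self.stem = Conv2d(3, c[0], k, s, p, rng, init_std=std)
        self.enc_convs = [
            Conv2d(c[i - 1], c[i], k, s, p, rng, init_std=std)
            for i in range(1, spec.n_blocks + 1)
        ]
        self.enc_norms = [InstanceNorm2d(c[i]) for i in range(1, spec.n_blocks + 1)]
        self.dec_convs = []
        self.dec_norms = []
        din = c[spec.n_blocks]
        for j in range(spec.n_blocks, 0, -1):
            self.dec_convs = self.dec_convs + [
                ConvTranspose2d(din, c[j - 1], k, s, p, rng, init_std=std)
            ]
            self.dec_norms = self.dec_norms + [InstanceNorm2d(c[j - 1])]
            din = 2 * c[j - 1]  # decoder output concatenated with the skip
        self.final = ConvTranspose2d(din, 3, k, s, p, rng, init_std=std)
        self.act = LeakyReLU(spec.leaky_slope)
        self.tanh = Tanh()

    # -- validation ---------------------------------------------------------

    def _check_input(self, x):
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected (N, 3, H, W) input, got shape {x.shape}")
        d = self.spec.size_divisor
        if x.shape[2] % d or x.shape[3] % d:
            raise ValueError(
                f"input spatial size {x.shape[2]}x{x.shape[3]} must be divisible "
                f"by 2**(n_blocks+1) = {d} (stem + {self.spec.n_blocks} encoder "
                "blocks each halve the resolution)"
            )

    # -- encoder ------------------------------------------------------------

    def encode(self, x):
        """Run G_enc only.

        Returns
        -------
        feats : list of post-activation feature maps, one per stage
            (stem output first, bottleneck last).
        cache : opaque, for :meth:`encode_backward`.
        """
        self._check_input(x)
        feats = []
        caches = []
        h, c_stem = self.stem.forward(x)
        h, a_stem = self.act.forward(h)
        feats.append(h)
        caches.append(("stem", c_stem, a_stem))
        for conv, norm in zip(self.enc_convs, self.enc_norms):
            h, cc = conv.forward(h)
            h, cn = norm.forward(h)
            h, ca = self.act.forward(h)
            feats.append(h)
            caches.append(("block", cc, cn, ca))
        return feats, caches

    def encode_backward(self, caches, feature_grads):
        """Backpropagate gradients injected at the encoder stages.

        ``feature_grads`` maps stage index -> gradient array (stages without an
        entry contribute nothing).  Returns the gradient w.r.t. the input.
        """
        nb = self.spec.n_blocks
        d = None
        for i in range(nb, -1, -1):
            g = feature_grads.get(i)
            if d is None:
                d = np.zeros_like(g) if g is None else g.copy()
            elif g is not None:
                d = d + g
            entry = caches[i]
            if entry[0] == "block":
                _, cc, cn, ca = entry
                d = self.act.backward(ca, d)
                d = self.enc_norms[i - 1].backward(cn, d)
                d = self.enc_convs[i - 1].backward(cc, d)
            else:
                _, c_stem, a_stem = entry
                d = self.act.backward(a_stem, d)
                d = self.stem.backward(c_stem, d)
        return d

    # -- full generator -----------------------------------------------------

    def forward(self, x):
        feats, enc_caches = self.encode(x)
        nb = self.spec.n_blocks
        h = feats[nb]
        dec_caches = []
        for idx, (tconv, norm) in enumerate(zip(self.dec_convs, self.dec_norms)):
            level = nb - 1 - idx  # encoder stage concatenated after this step
            h, ct = tconv.forward(h)
            h, cn = norm.forward(h)
            h, ca = self.act.forward(h)
            skip = feats[level]
            h = np.concatenate([h, skip], axis=1)
            dec_caches.append((ct, cn, ca, skip.shape[1]))
        y, c_final = self.final.forward(h)
        y, c_tanh = self.tanh.forward(y)
        return y, (enc_caches, dec_caches, c_final, c_tanh, feats)

    @staticmethod
    def cache_features(cache) -> list[np.ndarray]:
        """Encoder stage outputs captured during a :meth:`forward` call."""
        return cache[4]

    def backward(self, cache, dy, feature_grads=None):
        """Backprop through the whole generator.

        ``feature_grads`` (stage index -> array) lets the contrastive loss
        inject gradients directly at the encoder stages of this same forward
        pass; they are combined with the gradients arriving through the
        decoder skip connections.
        """
        enc_caches, dec_caches, c_final, c_tanh, _ = cache
        nb = self.spec.n_blocks
        fg = {} if feature_grads is None else dict(feature_grads)
        d = self.tanh.backward(c_tanh, dy)
        d = self.final.backward(c_final, d)
        for idx in range(nb - 1, -1, -1):
            ct, cn, ca, skip_ch = dec_caches[idx]
            level = nb - 1 - idx
            d, d_skip = d[:, :-skip_ch], d[:, -skip_ch:]
            fg[level] = fg.get(level, 0) + d_skip
            d = self.act.backward(ca, d)
            d = self.dec_norms[idx].backward(cn, d)
            d = self.dec_convs[idx].backward(ct, d)
        fg[nb] = fg.get(nb, 0) + d
        return self.encode_backward(enc_caches, fg)


class PatchGANDiscriminator(Module):
    """70x70 PatchGAN: outputs one logit per overlapping 70x70 input patch."""

    def __init__(self, spec: DiscriminatorSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        b, std = spec.base_channels, spec.init_std
        widths = [b * min(2**i, 8) for i in range(spec.n_layers + 1)]
        layers = [Conv2d(3, b, 4, 2, 1, rng, init_std=std), LeakyReLU(0.2)]
        for i in range(1, spec.n_layers):
            layers += [
                Conv2d(widths[i - 1], widths[i], 4, 2, 1, rng, init_std=std),
                InstanceNorm2d(widths[i]),
                LeakyReLU(0.2),
            ]
        layers += [
            Conv2d(widths[spec.n_layers - 1], widths[spec.n_layers], 4, 1, 1, rng,
                   init_std=std),
            InstanceNorm2d(widths[spec.n_layers]),
            LeakyReLU(0.2),
            Conv2d(widths[spec.n_layers], 1, 4, 1, 1, rng, init_std=std),
        ]
        self.layers = layers

    def forward(self, x):
        caches = []
        for layer in self.layers:
            x, c = layer.forward(x)
            caches.append(c)
        return x, caches

    def backward(self, caches, dy):
        for layer, c in zip(reversed(self.layers), reversed(caches)):
            dy = layer.backward(c, dy)
        return dy


class ProjectionHeads(Module):
    """One two-layer MLP per selected encoder stage, mapping C_l -> 256.

    Heads are built lazily on first use because their input widths depend on
    which encoder stages are selected.  Outputs are L2-normalized so that the
    dot products in the contrastive loss are true cosine similarities.
    """

    def __init__(self, embed_dim: int = 256, init_std: float = 0.02):
        super().__init__()
        self.embed_dim = embed_dim
        self.init_std = init_std
        self._mlps: dict[int, tuple] = {}

    def build(self, layer_channels: dict[int, int], rng: np.random.Generator):
        for lid in sorted(layer_channels):
            if lid in self._mlps:
                continue
            cin = layer_channels[lid]
            fc1 = Linear(cin, self.embed_dim, rng, init_std=self.init_std)
            fc2 = Linear(self.embed_dim, self.embed_dim, rng, init_std=self.init_std)
            relu = ReLU()
            self._mlps[lid] = (fc1, relu, fc2)
            self._children[f"mlp{lid}.fc1"] = fc1
            self._children[f"mlp{lid}.fc2"] = fc2

    @property
    def built_layers(self) -> list[int]:
        return sorted(self._mlps)

    def forward_layer(self, lid: int, feats: np.ndarray):
        """Project (..., C_l) features to unit-norm (..., embed_dim) embeddings."""
        fc1, relu, fc2 = self._mlps[lid]
        h, c1 = fc1.forward(feats)
        h, cr = relu.forward(h)
        u, c2 = fc2.forward(h)
        norm = np.sqrt((u * u).sum(axis=-1, keepdims=True)) + 1e-12
        z = u / norm
        return z, (lid, c1, cr, c2, z, norm)

    def backward_layer(self, cache, dz):
        lid, c1, cr, c2, z, norm = cache
        fc1, relu, fc2 = self._mlps[lid]
        du = (dz - z * (z * dz).sum(axis=-1, keepdims=True)) / norm
        d = fc2.backward(c2, du)
        d = relu.backward(cr, d)
        return fc1.backward(c1, d)


# ---------------------------------------------------------------------------
# construction helpers and accounting
# ---------------------------------------------------------------------------


def build_generator(spec: GeneratorSpec, seed: int = 0) -> UNetGenerator:
    return UNetGenerator(spec, np.random.default_rng(seed))


def build_discriminator(
    spec: DiscriminatorSpec | None = None, seed: int = 0
) -> PatchGANDiscriminator:
    return PatchGANDiscriminator(spec or DiscriminatorSpec(), np.random.default_rng(seed))


def select_feature_layers(spec: GeneratorSpec, n_layers: int) -> list[int]:
    """Evenly spaced encoder stage indices, stem (0) through bottleneck.

    ``n_layers == 1`` selects the bottleneck alone; ``n_layers >= 2`` always
    includes both ends.
    """
    n_stages = spec.n_stages
    if not 1 <= n_layers <= n_stages:
        raise ConfigurationError(
            f"n_layers must be in [1, {n_stages}] for a {spec.n_blocks}-block "
            f"generator, got {n_layers}"
        )
    if n_layers == 1:
        return [spec.n_blocks]
    idx = np.rint(np.linspace(0, n_stages - 1, n_layers)).astype(int)
    return sorted(set(int(i) for i in idx))


def count_flops(net: Module, input_shape: tuple[int, int, int]) -> float:
    """Multiply-accumulate count of one forward pass, in giga-operations.

    One fused multiply-add in a convolutional, transposed-convolutional or
    linear layer counts as one operation, evaluated at the layer's *output*
    spatial size (the common profiler convention); normalization and
    activation costs are excluded.

    ``input_shape`` is (H, W, C).
    """
    h, w, c = input_shape
    total = 0

    def walk(layer, h, w, c):
        nonlocal total
        if isinstance(layer, Conv2d):
            if c != layer.cin:
                raise ValueError(f"expected {layer.cin} channels, got {c}")
            ho = conv_out_size(h, layer.k, layer.stride, layer.pad)
            wo = conv_out_size(w, layer.k, layer.stride, layer.pad)
            if ho < 1 or wo < 1:
                raise ValueError(f"input {h}x{w} too small for kernel {layer.k}")
            total += layer.k * layer.k * layer.cin * layer.cout * ho * wo
            return ho, wo, layer.cout
        if isinstance(layer, ConvTranspose2d):
            if c != layer.cin:
                raise ValueError(f"expected {layer.cin} channels, got {c}")
            ho, wo = layer.out_size(h), layer.out_size(w)
            total += layer.k * layer.k * layer.cin * layer.cout * ho * wo
            return ho, wo, layer.cout
        if isinstance(layer, Linear):
            total += layer.cin * layer.cout * h * w
            return h, w, layer.cout
        return h, w, c  # norms / activations are free

    if isinstance(net, UNetGenerator):
        nb = net.spec.n_blocks
        chans = net.spec.channels()
        h0, w0, c0 = walk(net.stem, h, w, c)
        stage_sizes = [(h0, w0)]
        for conv in net.enc_convs:
            h0, w0, c0 = walk(conv, h0, w0, c0)
            stage_sizes.append((h0, w0))
        for idx, tconv in enumerate(net.dec_convs):
            level = nb - 1 - idx
            h0, w0, c0 = walk(tconv, h0, w0, c0)
            c0 += chans[level]
        walk(net.final, h0, w0, c0)
    elif isinstance(net, PatchGANDiscriminator):
        for layer in net.layers:
            h, w, c = walk(layer, h, w, c)
    elif isinstance(net, (Conv2d, ConvTranspose2d, Linear)):
        walk(net, h, w, c)
    elif hasattr(net, "layers"):
        for layer in net.layers:
            h, w, c = walk(layer, h, w, c)
    else:
        raise TypeError(f"cannot count FLOPs for {type(net).__name__}")
    return total / 1e9
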