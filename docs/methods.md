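# Methods

## Problem and model

Hematoxylin–eosin (H&E) histology sections digitized in different
laboratories or on different scanners show systematic color differences —
brightness, contrast, saturation, and more complex style variation — that
degrade downstream models trained on one site and applied to another.
Stain normalization maps images from a source appearance domain $X$ to a
target appearance domain $Y$ while preserving tissue content.

This package implements an *unpaired* image-to-image translation approach:
no pixel-aligned (x, y) pairs are needed, only two collections of images,
one per domain.  A generator $G = G_{dec} \circ G_{enc}$ is trained against
a discriminator $D$ with the least-squares adversarial criterion, plus a
patch-wise contrastive content term on both the translation branch and the
identity branch:

$$\mathcal{L} = \mathcal{L}_{GAN}(G, D, X, Y)
  + \lambda_X \mathcal{L}_{PatchNCE}(G, H, X)
  + \lambda_Y \mathcal{L}_{PatchNCE}(G, H, Y).$$

PatchNCE selects $L$ evenly spaced stages of the encoder, samples up to 256
spatial locations per stage, projects the features of the input $x$ and of
the translation $\hat y = G(x)$ through per-stage two-layer MLPs $H_l$ into
unit-normalized 256-d embeddings, and applies the InfoNCE loss

$$\ell_{NCE}(v, v^+, v^-) = -\log
  \frac{e^{v\cdot v^+/\tau}}{e^{v\cdot v^+/\tau} + \sum_n e^{v\cdot v_n^-/\tau}},
  \qquad \tau = 0.07,$$

where the query $v$ is the embedding of $\hat y$ at a location, the positive
$v^+$ is the co-located embedding of $x$, and the negatives are the *other*
sampled locations of the same layer and same image ("internal" negatives
only).  Per-location losses are **averaged** over locations and layers (the
double sum admits either normalization; averaging makes the loss magnitude
independent of the sampling budget).  The identity term applies the same
machinery to $y$ and $G(y)$ with the same MLPs but freshly sampled
locations.

Assumptions worth stating: the two domains share content statistics (same
kind of tissue imaged two ways); the mapping is learned one-directionally
(no cycle constraint, hence no guarantee of invertibility); and content
preservation is enforced only statistically through PatchNCE — inputs far
outside the training distribution can be altered structurally.

## Architecture

**Generator** — a modified UNet.  Every downsampling step is a single
convolution with kernel 4, stride 2, padding 1 (not the classic pair of 3×3
convolutions), followed by instance normalization (no affine parameters) and
LeakyReLU(0.2); upsampling mirrors this with transposed convolutions of the
same geometry; skip connections concatenate encoder features into the
decoder.  A stem convolution (also k4/s2/p1, no normalization) lifts RGB to
64 channels, and a final transposed convolution returns to 3 channels
through a Tanh.  Channel width after encoder block $k$ is
$\min(64 \cdot 2^k, 512)$.  A depth of $n$ blocks therefore downsamples
$n{+}1$ times and requires input sides divisible by $2^{n+1}$.

With these choices frozen, the generator alone has exactly 16,657,795 /
41,825,667 / 66,993,539 parameters at 4/6/8 blocks, and one forward pass at
512×512 costs 65.16 / 72.21 / 72.65 G multiply–accumulates (counting one
MAC as one FLOP at each layer's output spatial size, the common profiler
convention; normalization and activations excluded).

**Discriminator** — the standard 70×70 PatchGAN (widths 64-128-256-512,
k4 throughout, strides 2/2/2/1/1), 2,764,737 parameters, emitting one logit
per overlapping 70×70 patch; no sigmoid is baked in, the loss decides.

**Projection heads** — per selected encoder stage, Linear($C_l$, 256) →
ReLU → Linear(256, 256), built lazily on first forward because the input
widths depend on which stages are selected; outputs are L2-normalized so the
dot products in $\ell_{NCE}$ are true cosine similarities.

**Published accounting.**  The parameter column of the published accounting
table that this family reproduces counts *all trainable networks of the
training setup* — generator + discriminator + projection heads — not the
generator alone (the comparison row for the cycle-consistent baseline
likewise matches the sum of both its generators and both discriminators).
Under that convention our 6- and 8-block totals agree with the published
45.298 M and 70.466 M to within 0.25%, and all three FLOP figures agree
within 2%.  The published 4-block parameter value (15.870 M) is not
reproducible under any consistent reading of the same architecture — the
generator alone is 16.658 M and the full setup 20.130 M — and we report our
computed values rather than force agreement.  `staincut profile` prints
both generator-only and total parameters for this reason.

## Training protocol

Defaults follow the published recipe: 30 epochs, batch size 4, Adam with
learning rate 2·10⁻⁴, random 512×512 crops, horizontal/vertical flips as
the only augmentation.  Choices the recipe leaves open, fixed here:

| parameter | default | rationale |
|---|---|---|
| Adam β₁, β₂ | 0.5, 0.999 | β₁ = 0.9 destabilizes alternating adversarial updates; 0.5 is the GAN-lineage standard |
| adversarial form | least squares (log form behind a flag) | the contrastive-translation lineage trains with least squares; the classic log form is available and tested |
| λ_X, λ_Y | 1.0, 1.0 | lineage defaults; configurable |
| τ (temperature) | 0.07 | published value |
| locations / stage | 256 (clamped to the stage size) | published value |
| selected stages L | 5, evenly spaced stem→bottleneck | count unstated in the recipe; 5 is the lineage default, configurable |
| update order | D first, then G+H jointly | standard alternating scheme |
| history buffer for D | none | contrastive-translation default |
| LR schedule | constant (linear decay to 0 available via `lr_decay_steps`) | recipe states a single rate; annealing is useful at reduced scale to quench late-training oscillation |

One generator forward per step feeds both half-steps: the discriminator
update treats the translation as a constant, so the cached forward remains
valid for the generator update.  Gradients for the contrastive term flow
into the generator through two routes — the synthesis path and the
re-encoding of the translation — and both are implemented exactly (verified
against finite differences at 10⁻⁵ relative tolerance on reduced networks).

All randomness (initialization, batch and crop sampling, flips, location
sampling) descends from one integer seed through `SeedSequence` spawning;
training is bit-reproducible, checkpoints carry optimizer and RNG state,
and an interrupted run resumed from a checkpoint follows the identical
parameter trajectory.

## Tiled whole-frame inference

Networks are trained on fixed crops but evaluation frames are larger
(1539×1376 in the motivating two-scanner setting).  A frame is split into
overlapping tiles on a regular grid with the last row/column clamped to the
frame edge; each tile is translated independently; each output pixel is the
weighted average $\sum_i w_i x_i / \sum_i w_i$ over the tiles containing
it.  The default weight is the separable product $(d_r+1)(d_c+1)$ with $d$
the pixel's distance to the nearest tile edge along each axis — the
simplest strictly positive window that is maximal at the center and
decreases monotonically outward, which suppresses seams.  Default tile 512,
stride 256 (50% overlap): the tile matches the training crop; the overlap
is a package choice, both configurable.  Accumulation runs in float64 at
full frame size; quantization to 8 bits happens only at file boundaries.
Blending is exact for agreeing contributions (integer-valued weights;
single-tile layouts bypass the accumulator entirely), and frames smaller
than one tile are reflect-padded, translated once, and cropped back.

## Evaluation metrics

*PSNR* — $10\log_{10}(\mathrm{max}^2/\mathrm{MSE})$ over all pixels and
channels, `max` = 255 for 8-bit images; identical images report `inf`.

*SSIM* — Gaussian-window (11×11, σ = 1.5) structural similarity with
K₁ = 0.01, K₂ = 0.03, population moments, and a half-window border strip
excluded; computed on BT.601 luminance of RGB by default, with a
per-channel-mean mode behind a flag.  Verified against an independent
reference implementation at 10⁻⁶.

*FSIM* — phase-congruency (log-Gabor bank: 4 scales, 4 orientations,
minimum wavelength 6, multiplier 2, σ_onf 0.55) and Scharr
gradient-magnitude similarity maps, pooled with the maximum phase
congruency as weight (T₁ = 0.85, T₂ = 160 on the 0–255 scale); images are
smoothed and downsampled so the short side is ≈256 px.  No independent
implementation is installable in this environment, so FSIM is validated by
its defining properties (self-similarity 1, joint-transform invariance,
monotone degradation under noise) rather than by cross-implementation
comparison.  Near-constant inputs carry no phase congruency and return NaN
with a warning.

*Dice* — $2|X \cap Y|/(|X|+|Y|)$ on strictly binary masks; both-empty
returns 1 by convention.

*LPIPS* is intentionally absent (it requires externally trained
perceptual-network weights); the report object lists it as `n/a`.

## Classical baselines

*Reinhard* statistics transfer operates in Ruderman's lαβ space (log-LMS
decorrelated) by default — the original method's space, often conflated
with CIELAB, which is provided as an alternative mode.  Zero-variance
source channels keep unit scale so constant images transfer cleanly.

*Macenko* stain separation works in optical density, $OD = -\log((I+1)/I_0)$
with $I_0 = 255$: background pixels (any OD channel < 0.15) are excluded,
the remaining pixels are projected onto their top-2 principal plane, the
1st/99th percentile extreme angles define the stain vectors (hematoxylin =
larger red-OD component), and concentrations are obtained by an exact
two-variable nonnegative least squares (active-set over the two single-stain
edges), scaled at the 99th percentile, and re-rendered in the reference
basis.  On synthetic images built as $I = I_0\,e^{-BC}$ from a known basis
with near-pure-stain pixels present, the recovered vectors agree with $B$
to well under 2° — note that tissue-realistic concentration ranges matter:
near-pure eosin pixels at low concentration fall below the background
threshold and would bias the percentile angles.

Template mosaics tile patches (resized to $\lfloor H/r\rfloor \times
\lfloor W/c\rfloor$, row-major, cycled, margin filled with cropped tiles)
into a single reference image of the declared size; the builder takes an
explicit ordered patch list rather than guessing a selection criterion.

## Synthetic data: what it emulates and what it does not

The generator emulates the core situation — the *same* tissue rendered in
two color styles.  A latent stain-density map (anti-aliased random ellipses
for nuclei over a low-frequency textured background) is rendered once per
sample; each domain's image is produced by a *palette*, a 3×3 linear color
matrix applied to the latent transmittance followed by per-channel gamma,
plus additive Gaussian pixel noise (σ = 0.02) drawn independently per
domain.  Palettes must be numerically invertible so no color information is
destroyed.  Default palettes render a bright eosin-leaning domain A and a
darker, blue-shifted, contrast-changed domain B — the kind of strong
brightness/hue difference two scanners produce.  Seeding is counter-based
(`SeedSequence(seed, index, role)`), so datasets of any size are
reproducible image-by-image, and paired evaluation sets share bit-identical
latent geometry across domains.

What it does *not* emulate: histological realism (cell types, mitoses,
texture families), scanner optics, registration misalignment, or spatial
noise correlation.  A passing pipeline therefore demonstrates that the
method recovers a nontrivial per-pixel color transformation while
preserving spatial structure under adversarial + contrastive training — it
does not certify performance on real whole-slide data.

## The end-to-end demo and its reduced scale

`staincut demo` (and the acceptance script) runs the full pipeline at desk
scale: 48 unpaired 64×64 training images per domain, a 4-block generator at
quarter width (base 16, cap 128), 600 training steps with the learning rate
annealed linearly to zero over the second half, then tiled staining (tile
64, stride 32) of eight held-out 96×96 paired frames.  These sizes are the
package's reduced study conditions; the full recipe (9000 patches of
600×600, 512 crops, 30 epochs) is days of CPU time away from this scale but
runs through the identical code path.  Training at this scale uses float32
parameters (`staincut.nn.set_default_dtype`); the library default is
float64, which keeps gradient checks and blending-exactness guarantees
trivial.

The demo's headline comparison — trained-model SSIM vs. identity-baseline
SSIM on held-out pairs — is computed **per RGB channel** (averaged), not on
luminance.  The reason is diagnostic, and worth recording: at the synthetic
noise level, luminance SSIM between any translation and the ground truth is
dominated by the two domains' uncorrelated noise instances (a perfect
translator scores ≈0.93 against a noisy target; smoothing both images
raises the trained model to ≈0.98 vs ≈0.95 for identity), and luminance
SSIM is nearly blind to the color mapping — the very quantity stain
transfer corrects.  Per-channel SSIM sees it.  Both variants are computed
and reported by the acceptance script.

## Known limitations

- No theoretical content-preservation guarantee: out-of-distribution inputs
  (e.g. large white regions) can acquire hallucinated tissue color.
- GAN training at the reduced demo scale is noisy; the annealing schedule
  quenches but does not eliminate run-to-run variation.
- One direction per trained model (A→B); normalizing a new source domain
  means training a new model.
- No pyramidal WSI container support; inputs are plain raster frames.
- FSIM lacks a cross-implementation oracle in this environment (property
  tests only).
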