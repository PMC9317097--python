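"""Contrastive and adversarial loss correctness against closed forms/oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from staincut.exceptions import ConfigurationError
from staincut.losses import (
    NCEConfig,
    gan_loss,
    nce_loss,
    patchnce_loss,
    sample_patch_embeddings,
    total_objective,
)
from staincut.networks import GeneratorSpec, ProjectionHeads, build_generator


def naive_nce(v, v_pos, v_negs, tau):
    """Direct evaluation of the InfoNCE formula without the max-shift."""
    num = np.exp(np.dot(v, v_pos) / tau)
    den = num + sum(np.exp(np.dot(v, vn) / tau) for vn in v_negs)
    return -np.log(num / den)


def _unit(rng, n, d):
    v = rng.normal(size=(n, d))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def test_nce_uniform_logits_is_log_n_plus_one(rng):
    v = _unit(rng, 1, 16)[0]
    negs = np.tile(v, (255, 1))
    assert nce_loss(v, v, negs, tau=0.07) == pytest.approx(np.log(256), abs=1e-12)


def test_nce_dominant_positive_vanishes(rng):
    v = _unit(rng, 1, 16)[0]
    assert nce_loss(v, v, np.tile(-v, (255, 1)), tau=0.07) < 1e-9


def test_nce_no_negatives_is_exactly_zero(rng):
    v = _unit(rng, 1, 8)[0]
    assert nce_loss(v, v, np.empty((0, 8)), tau=0.07) == 0.0


def test_nce_matches_naive_formula_on_random_instances(rng):
    for _ in range(200):
        vs = _unit(rng, 4, 8)
        got = nce_loss(vs[0], vs[1], vs[2:], tau=0.07)
        want = naive_nce(vs[0], vs[1], vs[2:], 0.07)
        assert got == pytest.approx(want, rel=1e-6)


def test_nce_invariant_under_orthogonal_rotation(rng):
    vs = _unit(rng, 6, 8)
    q, _ = np.linalg.qr(rng.normal(size=(8, 8)))
    before = nce_loss(vs[0], vs[1], vs[2:], tau=0.07)
    rotated = vs @ q.T
    after = nce_loss(rotated[0], rotated[1], rotated[2:], tau=0.07)
    assert after == pytest.approx(before, abs=1e-5)


def test_nce_monotone_in_positive_similarity(rng):
    """Loss strictly decreases as v.v+ rises with the negatives held fixed."""
    d = 8
    negs = _unit(rng, 5, d)
    v = np.zeros(d)
    v[0] = 1.0
    losses = []
    for cos in np.linspace(-0.9, 0.9, 7):
        v_pos = np.zeros(d)
        v_pos[0], v_pos[1] = cos, np.sqrt(1 - cos**2)
        losses.append(nce_loss(v, v_pos, negs, tau=0.07))
    assert all(a > b for a, b in zip(losses, losses[1:]))


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_stable_softmax_agrees_with_naive_for_bounded_logits(seed):
    """Max-shifted and direct evaluations agree whenever |logits| <= 30."""
    rng = np.random.default_rng(seed)
    vs = _unit(rng, 5, 6)
    tau = 1.0 / 30.0  # unit vectors: |dot/tau| <= 30
    got = nce_loss(vs[0], vs[1], vs[2:], tau=tau)
    want = naive_nce(vs[0], vs[1], vs[2:], tau)
    assert got == pytest.approx(want, rel=1e-6)


# ---------------------------------------------------------------------------
# sampling + patchnce
# ---------------------------------------------------------------------------


def _encoder_and_heads():
    gen = build_generator(GeneratorSpec(n_blocks=2, base_channels=4, max_channels=8))
    return gen, ProjectionHeads()


def test_sampling_exhaustive_when_n_equals_spatial_size(rng):
    gen, heads = _encoder_and_heads()
    img = rng.normal(size=(3, 32, 32))
    stack = sample_patch_embeddings(gen, heads, img, [0, 2], n_locations=256, rng=rng)
    assert sorted(stack.indices[0]) == list(range(256))  # stage 0 is 16x16
    assert stack.clamped.get(2) == 16  # bottleneck 4x4 clamps 256 -> 16


def test_sampling_deterministic_under_seed(rng):
    gen, heads = _encoder_and_heads()
    img = rng.normal(size=(3, 32, 32))
    s1 = sample_patch_embeddings(gen, heads, img, [0], 32,
                                 rng=np.random.default_rng(5))
    s2 = sample_patch_embeddings(gen, heads, img, [0], 32,
                                 rng=np.random.default_rng(5))
    np.testing.assert_array_equal(s1.indices[0], s2.indices[0])
    np.testing.assert_array_equal(s1.embeddings[0], s2.embeddings[0])


def test_sampled_embeddings_unit_norm(rng):
    gen, heads = _encoder_and_heads()
    img = rng.normal(size=(3, 32, 32))
    stack = sample_patch_embeddings(gen, heads, img, [0, 1], 16, rng=rng)
    for lid in (0, 1):
        np.testing.assert_allclose(
            np.linalg.norm(stack.embeddings[lid], axis=-1), 1.0, atol=1e-6
        )


def test_location_reuse_colocates_positives(rng):
    gen, heads = _encoder_and_heads()
    img = rng.normal(size=(3, 32, 32))
    s1 = sample_patch_embeddings(gen, heads, img, [0], 16, rng=rng)
    s2 = sample_patch_embeddings(gen, heads, img, [0], 16,
                                 location_indices=s1.indices)
    np.testing.assert_array_equal(s1.indices[0], s2.indices[0])
    np.testing.assert_allclose(s1.embeddings[0], s2.embeddings[0], atol=1e-12)


def test_patchnce_zero_for_identical_single_location(rng):
    gen, heads = _encoder_and_heads()
    img = rng.normal(size=(3, 32, 32))
    stack = sample_patch_embeddings(gen, heads, img, [0, 1], 1, rng=rng)
    assert patchnce_loss(stack, stack) == pytest.approx(0.0, abs=1e-12)


def test_patchnce_orthogonal_closed_form():
    """Identical stacks of mutually orthogonal embeddings: the positive logit
    is 1/tau, every negative logit is 0, so the per-location loss is
    -log(e^{1/tau} / (e^{1/tau} + (S-1)))."""
    from staincut.losses import FeatureStack

    s, tau = 256, 0.07
    z = np.eye(s, 256)[None]  # orthonormal rows
    stack = FeatureStack([0], {0: np.arange(s)}, {0: z})
    expected = -np.log(np.exp(1 / tau) / (np.exp(1 / tau) + (s - 1)))
    assert patchnce_loss(stack, stack) == pytest.approx(expected, rel=1e-9)


def test_patchnce_equals_per_location_loop_oracle(rng):
    """3 layers x 7 locations == mean of 21 independent nce_loss calls."""
    from staincut.losses import FeatureStack

    layers, s = [0, 1, 2], 7
    src = {l: _unit(rng, s, 16)[None] for l in layers}
    out = {l: _unit(rng, s, 16)[None] for l in layers}
    idx = {l: np.arange(s) for l in layers}
    stack_src = FeatureStack(layers, idx, src)
    stack_out = FeatureStack(layers, idx, out)
    got = patchnce_loss(stack_src, stack_out)
    terms = []
    for l in layers:
        for i in range(s):
            negs = np.delete(src[l][0], i, axis=0)
            terms.append(nce_loss(out[l][0, i], src[l][0, i], negs, tau=0.07))
    assert got == pytest.approx(np.mean(terms), rel=1e-9)


def test_patchnce_identical_stacks_lower_bound(rng):
    """With negatives fixed, perturbing the output stack cannot reduce the loss."""
    from staincut.losses import FeatureStack

    s = 12
    src = {0: _unit(rng, s, 16)[None]}
    idx = {0: np.arange(s)}
    stack_src = FeatureStack([0], idx, src)
    base = patchnce_loss(stack_src, stack_src)
    for _ in range(10):
        pert = src[0][0] + 0.3 * rng.normal(size=(s, 16))
        pert /= np.linalg.norm(pert, axis=1, keepdims=True)
        perturbed = FeatureStack([0], idx, {0: pert[None]})
        assert patchnce_loss(stack_src, perturbed) >= base - 1e-12


def test_patchnce_rejects_mismatched_indices(rng):
    from staincut.losses import FeatureStack

    z = _unit(rng, 4, 8)[None]
    a = FeatureStack([0], {0: np.array([0, 1, 2, 3])}, {0: z})
    b = FeatureStack([0], {0: np.array([0, 1, 2, 4])}, {0: z})
    with pytest.raises(ValueError, match="co-located"):
        patchnce_loss(a, b)


# ---------------------------------------------------------------------------
# adversarial + total
# ---------------------------------------------------------------------------


class _ConstD:
    def __init__(self, value):
        self.value = value

    def __call__(self, batch):
        return np.full((batch.shape[0], 1, 4, 4), self.value)


def test_gan_loss_perfect_discriminator_is_zero(rng):
    x = rng.normal(size=(2, 3, 8, 8))

    class PerfectD:
        def __call__(self, batch):
            target = 1.0 if batch is x else 0.0
            return np.full((2, 1, 4, 4), target)

    fake = rng.normal(size=(2, 3, 8, 8))
    assert gan_loss(PerfectD(), x, fake, side="discriminator") == 0.0


def test_gan_loss_lsgan_half_half_closed_form(rng):
    x = rng.normal(size=(2, 3, 8, 8))
    assert gan_loss(_ConstD(0.5), x, x, side="discriminator") == pytest.approx(0.25)
    assert gan_loss(_ConstD(0.5), x, x, side="generator") == pytest.approx(0.25)


def test_gan_loss_literal_log_form(rng):
    x = rng.normal(size=(2, 3, 8, 8))
    loss_d = gan_loss(_ConstD(0.5), x, x, side="discriminator", mode="log")
    assert loss_d == pytest.approx(2 * np.log(2), rel=1e-9)  # ln 2 per term
    loss_g = gan_loss(_ConstD(0.5), x, x, side="generator", mode="log")
    assert loss_g == pytest.approx(np.log(2), rel=1e-9)


def test_total_objective_weights_and_linearity():
    total, parts = total_objective(1.5, 2.5, 3.5, lambda_x=0.0, lambda_y=0.0)
    assert total == 1.5
    total, parts = total_objective(1.5, 2.5, 3.5, lambda_x=1.0, lambda_y=1.0)
    assert total == pytest.approx(7.5)
    assert parts["total"] == total and parts["gan"] == 1.5


def test_total_objective_rejects_negative_lambdas():
    with pytest.raises(ConfigurationError):
        total_objective(1.0, 1.0, 1.0, lambda_x=-0.1)
    with pytest.raises(ConfigurationError):
        NCEConfig(lambda_y=-1.0)
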