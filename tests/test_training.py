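"""Training-loop contracts: determinism, isolation, replay, persistence."""

import hashlib

import numpy as np
import pytest

from staincut.exceptions import ConfigurationError, NumericError
from staincut.losses import NCEConfig
from staincut.synthdata import SynthConfig, make_unpaired_dataset
from staincut.training import TrainConfig, TrainState, step, train


def tiny_config(**kw):
    base = dict(
        epochs=1,
        batch_size=2,
        crop_size=32,
        n_blocks=3,
        base_channels=8,
        max_channels=32,
        n_feature_layers=3,
        nce=NCEConfig(n_locations=32),
        seed=7,
    )
    base.update(kw)
    return TrainConfig(**base)


@pytest.fixture
def batches(rng):
    a = rng.uniform(-1, 1, size=(2, 3, 32, 32))
    b = rng.uniform(-1, 1, size=(2, 3, 32, 32))
    return a, b


def param_hash(module):
    h = hashlib.sha256()
    for name, p in sorted(module.named_parameters()):
        h.update(name.encode())
        h.update(np.ascontiguousarray(p.data).tobytes())
    return h.hexdigest()


def test_step_losses_finite_and_logged(batches):
    state = TrainState(tiny_config())
    a, b = batches
    for _ in range(2):
        breakdown = step(state, a, b)
        for key in ("loss_d", "loss_g_gan", "loss_nce_x", "loss_nce_y",
                    "loss_g_total"):
            assert np.isfinite(breakdown[key])
    assert state.step_count == 2
    assert len(state.history) == 2


def test_zero_learning_rate_keeps_parameters(batches):
    state = TrainState(tiny_config(learning_rate=0.0))
    a, b = batches
    before_g = param_hash(state.generator)
    before_d = param_hash(state.discriminator)
    step(state, a, b)
    assert param_hash(state.generator) == before_g
    assert param_hash(state.discriminator) == before_d


def test_half_steps_touch_only_their_networks(batches):
    """The D update moves no generator/head weight and vice versa."""
    state = TrainState(tiny_config())
    a, b = batches
    step(state, a, b)  # heads now exist
    g_hash = param_hash(state.generator)
    d_hash = param_hash(state.discriminator)
    h_hash = param_hash(state.heads)
    # freeze the generator optimizer: D half-step still runs
    state.opt_g.lr = 0.0
    if state.opt_h is not None:
        state.opt_h.lr = 0.0
    step(state, a, b)
    assert param_hash(state.generator) == g_hash
    assert param_hash(state.heads) == h_hash
    assert param_hash(state.discriminator) != d_hash
    # and the reverse
    d_hash = param_hash(state.discriminator)
    state.opt_d.lr = 0.0
    state.opt_g.lr = state.config.learning_rate
    if state.opt_h is not None:
        state.opt_h.lr = state.config.learning_rate
    step(state, a, b)
    assert param_hash(state.discriminator) == d_hash
    assert param_hash(state.generator) != g_hash


def test_training_bitwise_reproducible(batches):
    a, b = batches

    def run():
        state = TrainState(tiny_config())
        for _ in range(3):
            step(state, a, b)
        return param_hash(state.generator), param_hash(state.discriminator)

    assert run() == run()


def test_generator_moves_under_gan_term_alone(batches):
    """With both contrastive weights zero, the adversarial term still trains G."""
    cfg = tiny_config(nce=NCEConfig(n_locations=32, lambda_x=0.0, lambda_y=0.0))
    state = TrainState(cfg)
    a, b = batches
    before = param_hash(state.generator)
    breakdown = step(state, a, b)
    assert breakdown["loss_nce_y"] == 0.0
    assert breakdown["loss_g_total"] == pytest.approx(breakdown["loss_g_gan"])
    assert param_hash(state.generator) != before


def test_replay_from_checkpoint_reproduces_losses(tmp_path, batches):
    """Loss breakdown recomputed from a saved state matches the logged one."""
    state = TrainState(tiny_config())
    a, b = batches
    step(state, a, b)  # build heads
    ckpt = tmp_path / "state.npz"
    state.save(ckpt)
    logged = step(state, a, b)
    reloaded = TrainState.load(ckpt)
    replayed = step(reloaded, a, b)  # full re-execution from the saved state
    for key in ("loss_d", "loss_g_gan", "loss_nce_x", "loss_nce_y", "loss_g_total"):
        assert replayed[key] == pytest.approx(logged[key], abs=1e-5)


def test_resume_matches_uninterrupted_run(tmp_path, batches):
    a, b = batches
    # uninterrupted: 4 steps
    s1 = TrainState(tiny_config())
    for _ in range(4):
        step(s1, a, b)
    # interrupted: 2 steps, checkpoint, reload, 2 more
    s2 = TrainState(tiny_config())
    for _ in range(2):
        step(s2, a, b)
    s2.save(tmp_path / "mid.npz")
    s3 = TrainState.load(tmp_path / "mid.npz")
    for _ in range(2):
        step(s3, a, b)
    assert param_hash(s1.generator) == param_hash(s3.generator)
    assert param_hash(s1.discriminator) == param_hash(s3.discriminator)
    assert param_hash(s1.heads) == param_hash(s3.heads)


def test_nan_loss_aborts_with_numeric_error(batches):
    state = TrainState(tiny_config())
    a, b = batches
    state.generator.stem.weight.data[...] = np.nan
    with pytest.raises(NumericError, match="non-finite"):
        step(state, a, b)


def test_train_smoke_on_synthetic_images(tmp_path):
    """Two epochs on 8+8 synthetic images: finite losses, checkpoints written."""
    cfg = SynthConfig(image_size=(32, 32), n_nuclei=4,
                      nucleus_radius_range=(2, 5), seed=3)
    sa, sb = make_unpaired_dataset(cfg, 8, disjoint_seeds=True)
    state = train(
        tiny_config(epochs=2, batch_size=4),
        images_a=[s.image_a.pixels for s in sa],
        images_b=[s.image_b.pixels for s in sb],
        out_dir=tmp_path,
    )
    assert state.epoch == 2
    assert all(np.isfinite(h["loss_g_total"]) for h in state.history)
    assert (tmp_path / "ckpt_epoch_1.npz").exists()
    assert (tmp_path / "ckpt_epoch_2.npz").exists()


def test_train_rejects_empty_domain(tmp_path):
    (tmp_path / "empty").mkdir()
    with pytest.raises(ConfigurationError):
        train(tiny_config(), domain_a_dir=tmp_path / "empty",
              domain_b_dir=tmp_path / "empty")


def test_images_smaller_than_crop_skipped(tmp_path, caplog):
    from staincut.images import write_image
    from staincut.training import _load_domain

    d = tmp_path / "dom"
    write_image(d / "small.png", np.random.default_rng(0).random((16, 16, 3)))
    write_image(d / "ok.png", np.random.default_rng(1).random((48, 48, 3)))
    images = _load_domain(d, crop=32)
    assert len(images) == 1


def test_crop_size_must_match_generator_divisor():
    with pytest.raises(ConfigurationError, match="divisible"):
        tiny_config(crop_size=24)
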