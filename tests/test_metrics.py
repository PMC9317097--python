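"""Metric closed forms, the skimage SSIM cross-check, and the batch harness."""

import numpy as np
import pandas as pd
import pytest
from skimage.metrics import structural_similarity

from staincut.images import write_image
from staincut.metrics import dice, evaluate_pairs, fsim, psnr, ssim


# ---------------------------------------------------------------------------
# psnr
# ---------------------------------------------------------------------------


def test_psnr_uniform_difference_closed_form(rng):
    a = rng.integers(0, 240, size=(64, 64, 3)).astype(np.uint8)
    b = (a + 16).astype(np.uint8)
    assert psnr(a, b) == pytest.approx(10 * np.log10(255**2 / 256), abs=1e-12)


def test_psnr_identical_is_infinite(rng):
    a = rng.integers(0, 256, size=(32, 32, 3)).astype(np.uint8)
    assert psnr(a, a) == float("inf")


def test_psnr_symmetric(rng):
    a = rng.integers(0, 256, size=(32, 32, 3)).astype(np.uint8)
    b = rng.integers(0, 256, size=(32, 32, 3)).astype(np.uint8)
    assert psnr(a, b) == psnr(b, a)


def test_psnr_monotone_in_noise_amplitude(rng):
    a = rng.random((48, 48, 3))
    values = []
    for amp in (0.02, 0.05, 0.1, 0.2, 0.4):
        noisy = np.clip(a + rng.uniform(-amp, amp, a.shape), 0, 1)
        values.append(psnr(a, noisy, max_value=1.0))
    assert all(x > y for x, y in zip(values, values[1:]))


def test_psnr_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        psnr(np.zeros((4, 4)), np.zeros((5, 5)))


# ---------------------------------------------------------------------------
# ssim
# ---------------------------------------------------------------------------


def test_ssim_self_similarity_is_one(rng):
    a = rng.random((48, 48, 3))
    assert ssim(a, a) == 1.0


def test_ssim_matches_reference_implementation(rng):
    """Independent cross-check against skimage at its reference settings."""
    for _ in range(5):
        x = rng.random((56, 56))
        y = np.clip(x + rng.normal(0, 0.08, x.shape), 0, 1)
        want = structural_similarity(
            x, y, data_range=1.0, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False,
        )
        assert ssim(x, y, data_range=1.0) == pytest.approx(want, abs=1e-6)


def test_ssim_constant_images_stabilized_formula(rng):
    """Two different constants: only the stabilizing terms survive."""
    a = np.full((32, 32), 0.25)
    b = np.full((32, 32), 0.75)
    want = structural_similarity(
        a, b, data_range=1.0, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False,
    )
    assert ssim(a, b, data_range=1.0) == pytest.approx(want, abs=1e-6)


def test_ssim_monotone_under_increasing_noise(rng):
    a = rng.random((48, 48))
    values = []
    for amp in (0.02, 0.05, 0.1, 0.2, 0.4):
        noisy = np.clip(a + np.random.default_rng(7).normal(0, amp, a.shape), 0, 1)
        values.append(ssim(a, noisy, data_range=1.0))
    assert all(x > y for x, y in zip(values, values[1:]))


def test_ssim_rejects_images_smaller_than_window():
    with pytest.raises(ValueError, match="window"):
        ssim(np.zeros((8, 8)), np.zeros((8, 8)))


# ---------------------------------------------------------------------------
# fsim
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def structured_pair():
    rng = np.random.default_rng(3)
    base = rng.random((128, 128, 3))
    from scipy.ndimage import gaussian_filter

    img = gaussian_filter(base, (3, 3, 0))
    img = (img - img.min()) / (img.max() - img.min())
    noisy = np.clip(img + rng.normal(0, 0.05, img.shape), 0, 1)
    return img, noisy


def test_fsim_self_similarity(structured_pair):
    img, _ = structured_pair
    assert fsim(img, img) == pytest.approx(1.0, abs=1e-6)


def test_fsim_in_unit_interval(structured_pair):
    img, noisy = structured_pair
    value = fsim(img, noisy)
    assert 0.0 < value < 1.0


def test_fsim_invariant_under_joint_rotation(structured_pair):
    img, noisy = structured_pair
    direct = fsim(img, noisy)
    rotated = fsim(np.rot90(img, 2).copy(), np.rot90(noisy, 2).copy())
    assert rotated == pytest.approx(direct, abs=1e-9)


def test_fsim_monotone_under_degradation(structured_pair):
    img, _ = structured_pair
    rng = np.random.default_rng(11)
    noise = rng.normal(0, 1, img.shape)
    values = [fsim(img, np.clip(img + amp * noise, 0, 1))
              for amp in (0.02, 0.08, 0.2)]
    assert values[0] > values[1] > values[2]


def test_fsim_constant_images_return_sentinel():
    value = fsim(np.full((64, 64, 3), 0.5), np.full((64, 64, 3), 0.5))
    assert np.isnan(value)


# ---------------------------------------------------------------------------
# dice
# ---------------------------------------------------------------------------


def test_dice_formula_instantiations():
    x = np.zeros((20, 20), dtype=int)
    x[:10] = 1
    assert dice(x, x) == 1.0
    assert dice(x, 1 - x) == 0.0
    a = np.zeros(200, dtype=int)
    b = np.zeros(200, dtype=int)
    a[:100] = 1
    b[50:150] = 1
    assert dice(a, b) == 0.5


def test_dice_symmetric_and_bounded(rng):
    for _ in range(10):
        a = (rng.random((16, 16)) > 0.5).astype(int)
        b = (rng.random((16, 16)) > 0.5).astype(int)
        d = dice(a, b)
        assert 0.0 <= d <= 1.0
        assert d == dice(b, a)


def test_dice_both_empty_is_one_by_convention():
    z = np.zeros((8, 8), dtype=int)
    assert dice(z, z) == 1.0


def test_dice_rejects_non_binary():
    with pytest.raises(ValueError, match="binary"):
        dice(np.full((4, 4), 2), np.zeros((4, 4), dtype=int))


# ---------------------------------------------------------------------------
# harness
# ---------------------------------------------------------------------------


def _write_pairs(tmp_path, images, noise=0.0):
    rng = np.random.default_rng(0)
    (tmp_path / "pred").mkdir()
    (tmp_path / "ref").mkdir()
    for i, img in enumerate(images):
        write_image(tmp_path / "ref" / f"{i}.png", img)
        pred = np.clip(img + rng.normal(0, noise, img.shape), 0, 1) if noise else img
        write_image(tmp_path / "pred" / f"{i}.png", pred)


def test_evaluate_identical_pairs_ssim_one(tmp_path, rng):
    _write_pairs(tmp_path, [rng.random((48, 48, 3)) for _ in range(3)])
    report = evaluate_pairs(tmp_path / "pred", tmp_path / "ref")
    assert report.aggregates.loc["mean", "ssim"] == 1.0
    assert report.aggregates.loc["std", "ssim"] == 0.0
    assert len(report.rows) == 3


def test_evaluate_single_pair_std_zero(tmp_path, rng):
    _write_pairs(tmp_path, [rng.random((48, 48, 3))], noise=0.05)
    report = evaluate_pairs(tmp_path / "pred", tmp_path / "ref")
    assert (report.aggregates.loc["std"] == 0.0).all()


def test_evaluate_aggregates_recomputable_from_csv(tmp_path, rng):
    _write_pairs(tmp_path, [rng.random((48, 48, 3)) for _ in range(4)], noise=0.05)
    csv = tmp_path / "report.csv"
    report = evaluate_pairs(tmp_path / "pred", tmp_path / "ref", out_csv=csv)
    table = pd.read_csv(csv)
    body = table[~table["image"].isin(["mean", "std"])]
    for metric in ("psnr_db", "ssim", "fsim"):
        assert body[metric].mean() == pytest.approx(
            report.aggregates.loc["mean", metric], abs=1e-9
        )
        assert body[metric].std(ddof=0) == pytest.approx(
            report.aggregates.loc["std", metric], abs=1e-9
        )


def test_evaluate_unmatched_files_counted(tmp_path, rng):
    _write_pairs(tmp_path, [rng.random((48, 48, 3)) for _ in range(2)])
    write_image(tmp_path / "pred" / "extra.png", rng.random((48, 48, 3)))
    report = evaluate_pairs(tmp_path / "pred", tmp_path / "ref")
    assert report.n_warnings == 1
    assert len(report.rows) == 2
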