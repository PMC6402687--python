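import numpy as np
import pytest

from phasecell.evaluation import SSIMParams, one_way_anova, psnr, quality_report, ssim_global
from phasecell.fixtures import make_dataset
from phasecell.image_io import load_dataset, read_gray_image, resize_to_crop


def test_ssim_constants():
    p = SSIMParams()
    assert p.C1 == pytest.approx(6.5025)
    assert p.C2 == pytest.approx(58.5225)


def test_ssim_identical_images_is_one(rng):
    x = rng.integers(0, 256, (64, 64)).astype(float)
    assert ssim_global(x, x) == pytest.approx(1.0)


def test_ssim_black_vs_white_closed_form():
    x = np.zeros((32, 32))
    y = np.full((32, 32), 255.0)
    expected = SSIMParams().C1 / (255.0 ** 2 + SSIMParams().C1)
    assert ssim_global(x, y) == pytest.approx(expected, rel=1e-9)
    assert expected == pytest.approx(1.0e-4, rel=0.01)


def test_ssim_symmetry(rng):
    for _ in range(5):
        x = rng.integers(0, 256, (16, 16)).astype(float)
        y = rng.integers(0, 256, (16, 16)).astype(float)
        assert ssim_global(x, y) == pytest.approx(ssim_global(y, x), rel=1e-12)


def test_ssim_shape_mismatch():
    with pytest.raises(ValueError):
        ssim_global(np.zeros((4, 4)), np.zeros((5, 5)))


def test_psnr_identities(rng):
    x = rng.integers(0, 256, (32, 32)).astype(float)
    assert psnr(x, x) == np.inf
    assert psnr(np.zeros((8, 8)), np.full((8, 8), 255.0)) == pytest.approx(0.0)
    y = x.copy()
    y[0, 0] += np.sqrt(x.size)  # MSE exactly 1
    assert psnr(x, y) == pytest.approx(10 * np.log10(255 ** 2), abs=1e-9)
    assert psnr(x, y) == pytest.approx(48.13, abs=0.01)


def test_psnr_matches_skimage(rng):
    from skimage.metrics import peak_signal_noise_ratio

    x = rng.integers(0, 256, (32, 32)).astype(float)
    y = np.clip(x + rng.normal(0, 10, x.shape), 0, 255)
    assert psnr(x, y) == pytest.approx(peak_signal_noise_ratio(x, y, data_range=255), rel=1e-9)


def test_psnr_decreases_with_noise_amplitude(rng):
    x = np.full((64, 64), 128.0)
    values = [psnr(x, np.clip(x + rng.normal(0, s, x.shape), 0, 255))
              for s in (2, 8, 32)]
    assert values[0] > values[1] > values[2]


def test_quality_report_matches_brute_force(tmp_path):
    syn = make_dataset(tmp_path / "syn", {"CC": 2, "DEB": 0, "UN": 0, "AT": 0, "DYN": 0, "APO": 0}, seed=5)
    real = make_dataset(tmp_path / "real", {"CC": 3, "DEB": 0, "UN": 0, "AT": 0, "DYN": 0, "APO": 0}, seed=6)
    report = quality_report(syn, real)
    syn_imgs = [resize_to_crop(read_gray_image(p)) for p in syn.files["CC"]]
    real_imgs = [resize_to_crop(read_gray_image(p)) for p in real.files["CC"]]
    brute_ssim = np.mean([np.mean([ssim_global(s, r) for r in real_imgs]) for s in syn_imgs])
    brute_psnr = np.mean([np.mean([psnr(s, r) for r in real_imgs]) for s in syn_imgs])
    assert report["CC"]["ssim"] == pytest.approx(brute_ssim, rel=1e-12)
    assert report["CC"]["psnr"] == pytest.approx(brute_psnr, rel=1e-12)
    assert list(report) == ["CC"]


def test_quality_report_identical_single_image(tmp_path):
    real = make_dataset(tmp_path / "r", {"UN": 1, "CC": 0, "DEB": 0, "AT": 0, "DYN": 0, "APO": 0}, seed=7)
    report = quality_report(real, load_dataset(tmp_path / "r"))
    assert report["UN"]["ssim"] == pytest.approx(1.0)
    assert np.isinf(report["UN"]["psnr"])


def test_anova_hand_worked_example():
    # SSB = 13.5 with df 1; SSW/df = 1 -> F = 13.5
    f, p = one_way_anova([1, 2, 3], [4, 5, 6])
    assert f == pytest.approx(13.5)
    assert 0 < p < 0.05


def test_anova_identical_groups():
    f, p = one_way_anova([2.0, 2.0, 2.0], [2.0, 2.0])
    assert (f, p) == (0.0, 1.0)
    f2, p2 = one_way_anova([1.0, 2.0], [1.0, 2.0])
    assert f2 == pytest.approx(0.0)
    assert p2 == pytest.approx(1.0)


def test_anova_group_order_invariance():
    f1, _ = one_way_anova([1, 2, 3], [7, 9, 11])
    f2, _ = one_way_anova([7, 9, 11], [1, 2, 3])
    assert f1 == pytest.approx(f2)
    with pytest.raises(ValueError):
        one_way_anova([1.0], [1, 2])
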