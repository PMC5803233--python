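"""PSNR, SSIM (global + map), volume reports and histogram mode detection."""

import numpy as np
import pytest

from tomoenhance.metrics import (
    histogram_modes,
    psnr,
    ssim,
    ssim_map,
    volume_report,
)


def _gaussian_window(size=11, sigma=1.5):
    ax = np.arange(size) - size // 2
    g = np.exp(-(ax**2) / (2 * sigma**2))
    w = np.outer(g, g)
    return w / w.sum()


def _ssim_loop_oracle(a, b, data_range=1.0, size=11, sigma=1.5):
    """Brute-force windowed SSIM: one window per interior pixel."""
    w = _gaussian_window(size, sigma)
    half = size // 2
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    vals = []
    for i in range(half, a.shape[0] - half):
        for j in range(half, a.shape[1] - half):
            pa = a[i - half : i + half + 1, j - half : j + half + 1]
            pb = b[i - half : i + half + 1, j - half : j + half + 1]
            mua, mub = (w * pa).sum(), (w * pb).sum()
            va = (w * pa * pa).sum() - mua**2
            vb = (w * pb * pb).sum() - mub**2
            cov = (w * pa * pb).sum() - mua * mub
            vals.append(
                ((2 * mua * mub + c1) * (2 * cov + c2))
                / ((mua**2 + mub**2 + c1) * (va + vb + c2))
            )
    return float(np.mean(vals))


class TestPsnr:
    def test_identical_images_capped_at_100db(self, random_image):
        assert psnr(random_image, random_image) == 100.0

    def test_closed_form_mse(self):
        a = np.zeros((16, 16))
        b = np.full((16, 16), 0.1)
        assert psnr(b, a, data_range=1.0) == pytest.approx(20.0, abs=1e-9)

    def test_constant_offset_oracle(self, random_image):
        img = random_image / random_image.max()  # unit range
        assert psnr(img + 0.1, img, data_range=1.0) == pytest.approx(20.0, abs=1e-5)

    def test_symmetry(self, rng):
        a, b = rng.random((8, 8)), rng.random((8, 8))
        assert psnr(a, b) == pytest.approx(psnr(b, a))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            psnr(np.zeros((4, 4)), np.zeros((5, 4)))


class TestSsim:
    def test_identical_images_map_is_one(self, random_image):
        m = ssim_map(random_image, random_image)
        assert np.allclose(m, 1.0)

    def test_negated_image_is_dissimilar(self, rng):
        img = rng.random((32, 32))
        assert ssim_map(1.0 - img, img).mean() < 0.2

    def test_valid_window_map_mean_equals_global_score(self, rng):
        # the global score averages the per-window values, i.e. the map
        # away from the half-window border
        a, b = rng.random((40, 40)), rng.random((40, 40))
        half = 5
        interior = ssim_map(a, b)[half:-half, half:-half].mean()
        assert interior == pytest.approx(ssim(a, b), abs=1e-9)

    def test_matches_brute_force_window_oracle(self, rng):
        a = rng.random((24, 24))
        b = a + rng.normal(0, 0.2, a.shape)
        got = ssim_map(a, b)
        half = 5
        interior = got[half:-half, half:-half].mean()
        oracle = _ssim_loop_oracle(a, b)
        assert interior == pytest.approx(oracle, abs=1e-3)

    def test_symmetry(self, rng):
        a, b = rng.random((24, 24)), rng.random((24, 24))
        assert ssim(a, b) == pytest.approx(ssim(b, a))

    def test_joint_shift_invariance(self, rng):
        a, b = rng.random((24, 24)), rng.random((24, 24))
        # luminance term uses absolute means, so shift both AND keep range
        assert ssim(a + 5.0, b + 5.0) != pytest.approx(ssim(a, b), abs=1e-6)
        # but a common positive rescale with matching data_range is invariant
        assert ssim(2 * a, 2 * b, data_range=2.0) == pytest.approx(
            ssim(a, b, data_range=1.0), abs=1e-9
        )

    def test_window_validation(self, rng):
        a = rng.random((16, 16))
        with pytest.raises(ValueError):
            ssim_map(a, a, window=10)
        with pytest.raises(ValueError):
            ssim_map(a, a, window=21)


class TestVolumeReport:
    def test_self_report_is_perfect(self, rng):
        vol = rng.random((4, 32, 32)).astype(np.float32)
        rep = volume_report(vol, vol.copy())
        assert rep.ssim_mean == 1.0
        assert rep.ssim_std == 0.0
        assert rep.psnr_mean == 100.0
        assert len(rep.per_slice) == 4

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            volume_report(rng.random((2, 8, 8)), rng.random((3, 8, 8)))


class TestHistogramModes:
    def test_constant_volume_has_single_mode(self):
        _, _, n = histogram_modes(np.full((16, 16, 16), 0.3))
        assert n == 1

    def test_planted_three_gaussian_mixture_recovered(self):
        rng = np.random.default_rng(0)
        vol = np.concatenate(
            [
                rng.normal(0.0, 0.02, 60000),
                rng.normal(0.3, 0.02, 30000),
                rng.normal(1.0, 0.02, 10000),
            ]
        ).reshape(100, 100, 10)
        _, _, n = histogram_modes(vol)
        assert n == 3

    def test_empty_volume_rejected(self):
        with pytest.raises(ValueError):
            histogram_modes(np.zeros((0, 4, 4)))
        with pytest.raises(ValueError):
            histogram_modes(np.zeros((4, 4, 4)), n_bins=4)
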