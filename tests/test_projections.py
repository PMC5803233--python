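"""Forward projection and the low-dose noise model."""

import numpy as np
import pytest
from scipy.ndimage import rotate

from tomoenhance.phantom import Phantom, generate_phantom
from tomoenhance.projections import ProjectionSet, add_noise, forward_project


def _phantom_from(vox):
    vox = np.asarray(vox, dtype=np.float32)
    return Phantom(voxels=vox, size=vox.shape[0])


def test_one_projection_per_angle(small_projections):
    assert small_projections.n_angles == 91
    assert small_projections.images.shape == (91, 64, 64)
    assert small_projections.role == "clean"


def test_zero_phantom_projects_to_zero():
    ph = _phantom_from(np.zeros((16, 16, 16)))
    p = forward_project(ph, np.linspace(0, 180, 7))
    assert np.allclose(p.images, 0.0, atol=1e-5)


def test_axis_aligned_projections_are_axis_sums(small_phantom):
    p = forward_project(small_phantom, np.array([0.0, 90.0]))
    vol = small_phantom.voxels
    col = vol.sum(axis=1)  # integrate along y -> detector = x
    row = vol.sum(axis=2)  # integrate along x at 90 degrees
    scale = np.abs(col).max()
    assert np.abs(p.images[0] - col).max() < 5e-3 * scale
    assert np.abs(p.images[1] - row).max() < 5e-3 * scale


def test_oblique_projection_matches_rotated_ray_sums(small_phantom):
    # independent oracle: rotate the slice, then sum columns
    z = 32
    sl = small_phantom.voxels[z]
    p = forward_project(small_phantom, np.array([30.0])).images[0, z]
    # pad by one so scipy's rotation center (N-1)/2 falls on the projector's
    # rotation axis at index N//2
    padded = np.pad(sl, ((0, 1), (0, 1)))
    oracle = rotate(padded, 30.0, reshape=False, order=3)[:64, :64].sum(axis=0)
    assert np.corrcoef(p, oracle)[0, 1] > 0.9995
    assert np.abs(p - oracle).max() < 0.05 * np.abs(oracle).max()


def test_projection_is_linear():
    rng = np.random.default_rng(0)
    v1 = rng.random((16, 16, 16)).astype(np.float32)
    v2 = rng.random((16, 16, 16)).astype(np.float32)
    angles = np.array([10.0, 77.0, 140.0])
    p1 = forward_project(_phantom_from(v1), angles).images
    p2 = forward_project(_phantom_from(v2), angles).images
    p12 = forward_project(_phantom_from(2.0 * v1 + 0.5 * v2), angles).images
    assert np.allclose(p12, 2.0 * p1 + 0.5 * p2, atol=1e-3 * np.abs(p12).max())


def test_mass_conservation_across_angles(small_projections):
    # the ray-sum total of each slice is angle-independent
    totals = small_projections.images.sum(axis=2)  # (angles, slices)
    mid = totals[:, 20:44]  # slices with object content
    spread = (mid.max(axis=0) - mid.min(axis=0)) / np.abs(mid.mean(axis=0))
    assert spread.max() < 5e-3


def test_empty_or_out_of_range_angles_rejected(small_phantom):
    with pytest.raises(ValueError):
        forward_project(small_phantom, np.array([]))
    with pytest.raises(ValueError):
        forward_project(small_phantom, np.array([-5.0, 90.0]))


class TestNoise:
    def test_zero_level_is_identity(self, small_projections):
        out = add_noise(small_projections, 0.0, seed=1)
        assert np.array_equal(out.images, small_projections.images)
        assert out.role == "clean"

    def test_noise_std_matches_level_times_range(self, small_projections):
        level = 0.30
        out = add_noise(small_projections, level, seed=5)
        assert out.role == "noisy"
        assert out.noise_level == level
        rng_span = small_projections.images.max() - small_projections.images.min()
        resid = out.images - small_projections.images
        assert resid.std() == pytest.approx(level * rng_span, rel=0.01)
        assert abs(resid.mean()) < 0.01 * level * rng_span

    def test_deterministic_for_fixed_seed(self, small_projections):
        a = add_noise(small_projections, 0.1, seed=9).images
        b = add_noise(small_projections, 0.1, seed=9).images
        assert np.array_equal(a, b)

    def test_averaging_realizations_converges_like_sqrt_n(self, small_projections):
        level = 0.2
        base = small_projections.images
        resids = []
        for n in (4, 16):
            acc = np.zeros_like(base)
            for k in range(n):
                acc += add_noise(small_projections, level, seed=100 + n * 31 + k).images
            resids.append(np.std(acc / n - base))
        # residual ratio should be ~ sqrt(16/4) = 2
        assert resids[0] / resids[1] == pytest.approx(2.0, rel=0.1)

    def test_negative_level_rejected(self, small_projections):
        with pytest.raises(ValueError):
            add_noise(small_projections, -0.1, seed=0)

    def test_noisy_role_requires_positive_level(self):
        with pytest.raises(ValueError):
            ProjectionSet(
                images=np.zeros((2, 8, 8)),
                angles=np.array([0.0, 90.0]),
                role="noisy",
                noise_level=0.0,
            )
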