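"""Two-step normalization and patch extraction/reassembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tomoenhance.preprocess import (
    apply_normalization,
    denormalize,
    extract_patches,
    normalize_two_step,
    reassemble_patches,
)


class TestNormalize:
    def test_output_spans_unit_interval(self, random_image):
        out, _ = normalize_two_step(random_image)
        assert out.min() == 0.0
        assert out.max() == pytest.approx(1.0, abs=1e-6)

    def test_two_value_image_maps_to_endpoints(self):
        img = np.array([[0.0, 1.0]], dtype=np.float32)
        out, _ = normalize_two_step(img)
        assert np.allclose(sorted(out.ravel()), [0.0, 1.0])

    def test_round_trip_inverts_exactly(self, random_image):
        out, params = normalize_two_step(random_image)
        back = denormalize(out, params)
        err = np.abs(back - random_image).max() / np.abs(random_image).max()
        assert err <= 1e-6

    def test_affine_input_invariance(self, random_image):
        # normalize(a*I + b) == normalize(I) for a > 0
        base, _ = normalize_two_step(random_image)
        shifted, _ = normalize_two_step(3.7 * random_image - 11.0)
        assert np.allclose(base, shifted, atol=1e-5)

    def test_apply_normalization_reuses_parameters(self, random_image):
        _, params = normalize_two_step(random_image)
        other = random_image * 0.5 + 2.0
        out = apply_normalization(other, params)
        assert np.allclose(denormalize(out, params), other, atol=1e-4)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            normalize_two_step(np.full((8, 8), 3.0))


class TestPatches:
    def test_single_patch_equals_image(self, rng):
        img = rng.random((64, 64)).astype(np.float32)
        patches, grid = extract_patches(img, 64, 16)
        assert patches.shape == (1, 64, 64)
        assert np.array_equal(patches[0], img)

    def test_patch_count_matches_anchor_enumeration(self, rng):
        img = rng.random((512, 512)).astype(np.float32)
        patches, grid = extract_patches(img, 64, 16)
        # oracle: enumerate anchors by loop with edge clamping
        anchors = []
        for r in range(0, 512 - 64 + 1, 16):
            for c in range(0, 512 - 64 + 1, 16):
                anchors.append((r, c))
        assert len(patches) == len(anchors) == 29 * 29 == 841
        assert tuple(grid.origins) == tuple(anchors)

    def test_every_pixel_is_covered_with_clamped_edges(self, rng):
        img = rng.random((70, 53)).astype(np.float32)
        patches, grid = extract_patches(img, 24, 16)
        cover = np.zeros_like(img)
        for r, c in grid.origins:
            cover[r : r + 24, c : c + 24] += 1
        assert cover.min() >= 1

    def test_patch_count_nonincreasing_in_stride(self, rng):
        img = rng.random((96, 96)).astype(np.float32)
        counts = [len(extract_patches(img, 32, s)[0]) for s in (4, 8, 16, 32)]
        assert counts == sorted(counts, reverse=True)

    def test_non_multiple_of_8_rejected(self, rng):
        with pytest.raises(ValueError):
            extract_patches(rng.random((64, 64)), 30, 8)

    def test_reassembly_round_trip_is_identity(self, rng):
        img = rng.random((80, 80)).astype(np.float32)
        patches, grid = extract_patches(img, 32, 8)
        back = reassemble_patches(patches, grid)
        assert np.abs(back - img).max() <= 1e-6

    def test_overlap_averaging(self):
        # two half-overlapping constant patches of 0 and 1 average to 0.5
        img = np.zeros((8, 16), dtype=np.float32)
        _, grid = extract_patches(img, 8, 8)
        assert grid.origins == ((0, 0), (0, 8))
        from dataclasses import replace

        grid2 = replace(grid, origins=((0, 0), (0, 4)), source_shape=(8, 12))
        patches = np.stack([np.zeros((8, 8)), np.ones((8, 8))]).astype(np.float32)
        out = reassemble_patches(patches, grid2)
        assert np.allclose(out[:, 4:8], 0.5)
        assert np.allclose(out[:, :4], 0.0)
        assert np.allclose(out[:, 8:], 1.0)

    def test_accumulation_matches_loop_oracle(self, rng):
        img = rng.random((40, 48)).astype(np.float32)
        patches, grid = extract_patches(img, 16, 8)
        jitter = patches + rng.normal(0, 0.1, patches.shape).astype(np.float32)
        out = reassemble_patches(jitter, grid)
        acc = np.zeros_like(img, dtype=np.float64)
        cnt = np.zeros_like(img, dtype=np.float64)
        for (r, c), p in zip(grid.origins, jitter):
            acc[r : r + 16, c : c + 16] += p
            cnt[r : r + 16, c : c + 16] += 1
        assert np.allclose(out, acc / cnt, atol=1e-6)

    def test_mismatched_grid_rejected(self, rng):
        img = rng.random((32, 32)).astype(np.float32)
        patches, grid = extract_patches(img, 16, 16)
        with pytest.raises(ValueError):
            reassemble_patches(patches[:-1], grid)


@settings(max_examples=25, deadline=None)
@given(
    h=st.integers(24, 70),
    w=st.integers(24, 70),
    stride=st.integers(1, 16),
)
def test_extract_reassemble_identity_property(h, w, stride):
    rng = np.random.default_rng(h * 1000 + w * 10 + stride)
    img = rng.random((h, w)).astype(np.float32)
    patches, grid = extract_patches(img, 16, stride)
    assert np.abs(reassemble_patches(patches, grid) - img).max() <= 1e-6
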