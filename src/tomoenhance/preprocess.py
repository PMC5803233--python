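"""Two-step intensity normalization and overlapping patch extraction.

Images are normalized per projection in two steps: standardization
(subtract mean, divide by standard deviation) followed by an affine rescale
of the result to [0, 1].  The recorded parameters invert the composite map
exactly, and the same parameters can be applied to a paired image so that a
training target lives on the input image's normalized scale.

Patches are extracted on a regular stride grid with the last anchor clamped
to the image edge, so every pixel is covered; reassembly averages all
patches covering a pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NormalizationParams",
    "normalize_two_step",
    "apply_normalization",
    "denormalize",
    "PatchGrid",
    "extract_patches",
    "reassemble_patches",
]


@dataclass(frozen=True)
class NormalizationParams:
    """Parameters of the two-step normalization (mean/std, then min/max)."""

    mean: float
    std: float
    post_min: float
    post_max: float

    def __post_init__(self) -> None:
        if not self.std > 0:
            raise ValueError("std must be positive")
        if not self.post_max > self.post_min:
            raise ValueError("post_max must exceed post_min")


def normalize_two_step(image: np.ndarray) -> tuple[np.ndarray, NormalizationParams]:
    """Normalize one image; returns the [0, 1] image and the inverse params."""
    image = np.asarray(image, dtype=np.float32)
    std = float(image.std())
    if std == 0:
        raise ValueError("constant image cannot be normalized (std = 0)")
    mean = float(image.mean())
    step1 = (image - mean) / std
    lo, hi = float(step1.min()), float(step1.max())
    params = NormalizationParams(mean=mean, std=std, post_min=lo, post_max=hi)
    return ((step1 - lo) / (hi - lo)).astype(np.float32), params


def apply_normalization(image: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Apply a previously computed normalization to another image."""
    step1 = (np.asarray(image, dtype=np.float32) - params.mean) / params.std
    return ((step1 - params.post_min) / (params.post_max - params.post_min)).astype(
        np.float32
    )


def denormalize(image: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Exact inverse of :func:`apply_normalization`."""
    step1 = (
        np.asarray(image, dtype=np.float64) * (params.post_max - params.post_min)
        + params.post_min
    )
    return (step1 * params.std + params.mean).astype(np.float32)


@dataclass(frozen=True)
class PatchGrid:
    """Bookkeeping for overlapping patch extraction/reassembly."""

    patch_edge: int
    stride: int
    origins: tuple  # ((row, col), ...) top-left anchors
    source_shape: tuple  # (H, W)


def _anchors(extent: int, patch: int, stride: int) -> list[int]:
    pos = list(range(0, extent - patch + 1, stride))
    if pos[-1] != extent - patch:  # clamp a final anchor to cover the edge
        pos.append(extent - patch)
    return pos


def extract_patches(
    image: np.ndarray, patch_edge: int, stride: int
) -> tuple[np.ndarray, PatchGrid]:
    """Extract overlapping square patches on a stride grid.

    ``patch_edge`` must be a multiple of 8 (the enhancement network halves
    the spatial size three times) and must fit in the image.
    """
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 2:
        raise ValueError("expected a 2-D image")
    h, w = image.shape
    if patch_edge % 8 != 0:
        raise ValueError("patch_edge must be a multiple of 8")
    if patch_edge > min(h, w):
        raise ValueError("patch_edge exceeds the image size")
    if not 1 <= stride <= patch_edge:
        raise ValueError("stride must be in [1, patch_edge] so patches cover the image")
    origins = [
        (r, c) for r in _anchors(h, patch_edge, stride) for c in _anchors(w, patch_edge, stride)
    ]
    patches = np.empty((len(origins), patch_edge, patch_edge), dtype=np.float32)
    for i, (r, c) in enumerate(origins):
        patches[i] = image[r : r + patch_edge, c : c + patch_edge]
    grid = PatchGrid(
        patch_edge=patch_edge,
        stride=stride,
        origins=tuple(origins),
        source_shape=(h, w),
    )
    return patches, grid


def reassemble_patches(patches: np.ndarray, grid: PatchGrid) -> np.ndarray:
    """Average overlapping patches back into a full image."""
    patches = np.asarray(patches, dtype=np.float32)
    if len(patches) != len(grid.origins):
        raise ValueError("patch count does not match the grid")
    if patches.shape[1:] != (grid.patch_edge, grid.patch_edge):
        raise ValueError("patch size does not match the grid")
    h, w = grid.source_shape
    acc = np.zeros((h, w), dtype=np.float64)
    cnt = np.zeros((h, w), dtype=np.float64)
    e = grid.patch_edge
    for (r, c), p in zip(grid.origins, patches):
        acc[r : r + e, c : c + e] += p
        cnt[r : r + e, c : c + e] += 1.0
    return (acc / cnt).astype(np.float32)
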