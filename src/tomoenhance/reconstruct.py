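"""Tomographic reconstruction of projection stacks (GridRec, Parzen filter)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fourier import filtered_backproject_slices
from .projections import ProjectionSet

__all__ = ["Volume", "reconstruct", "FILTERS"]

FILTERS = ("parzen", "ramp", "shepp", "cosine", "hann")


@dataclass
class Volume:
    """Reconstructed 3-D image.

    ``voxels`` has shape (slice, row, col): one square slice per detector
    row, in-plane size equal to the detector width.
    """

    voxels: np.ndarray
    source_role: str = "clean"
    n_angles: int = 0

    @property
    def shape(self) -> tuple:
        return self.voxels.shape


def reconstruct(
    projections: ProjectionSet,
    filter_name: str = "parzen",
    center: float | None = None,
    chunk: int = 32,
) -> Volume:
    """Slice-wise GridRec reconstruction of a projection stack.

    The rotation center defaults to the detector midline used by the
    synthetic projector (``width // 2``); pass ``center`` to override for
    measured data.
    """
    if filter_name not in FILTERS:
        raise ValueError(f"unknown filter {filter_name!r}; choose from {FILTERS}")
    if projections.n_angles < 2:
        raise ValueError("need at least two angles to reconstruct")
    span = abs(projections.angles[-1] - projections.angles[0])
    if span <= 0:
        raise ValueError("angles must span a positive range")
    if np.isnan(projections.images).any():
        raise ValueError("projections contain NaN pixels")
    vox = filtered_backproject_slices(
        projections.images,
        projections.angles,
        filter_name=filter_name,
        center=center,
        chunk=chunk,
    )
    return Volume(voxels=vox, source_role=projections.role, n_angles=projections.n_angles)
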