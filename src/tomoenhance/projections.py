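"""Projection stacks: forward Radon transform and low-dose noise model."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .fourier import project_slices
from .phantom import Phantom

__all__ = ["ProjectionSet", "forward_project", "add_noise", "ROLES"]

ROLES = ("clean", "noisy", "enhanced", "measured_short", "measured_long")


@dataclass
class ProjectionSet:
    """Angle-indexed stack of 2-D projections.

    Attributes
    ----------
    images : (n_angles, height, width) float32 array of line integrals.
    angles : rotation angles in degrees over [0, 180].
    role : one of ``ROLES``.
    noise_level : noise fraction (0 for clean stacks).
    exposure_s : exposure time in seconds, or None for synthetic data.
    """

    images: np.ndarray
    angles: np.ndarray
    role: str = "clean"
    noise_level: float = 0.0
    exposure_s: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float32)
        self.angles = np.asarray(self.angles, dtype=np.float64)
        if self.images.ndim != 3:
            raise ValueError("images must be a (n_angles, H, W) stack")
        if len(self.images) != len(self.angles):
            raise ValueError("number of images must equal number of angles")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.role == "noisy" and not self.noise_level > 0:
            raise ValueError("role='noisy' requires noise_level > 0")

    @property
    def n_angles(self) -> int:
        return len(self.angles)

    @property
    def shape(self) -> tuple:
        return self.images.shape


def forward_project(phantom: Phantom, angles: np.ndarray) -> ProjectionSet:
    """Parallel-beam projections of a phantom, one per angle.

    Each horizontal slice (fixed z) is projected independently; the
    projection value is the line integral of the voxel values along rays at
    the given angle (degrees, counter-clockwise, 0 deg along +x so the
    0-degree projection is the straight axis sum).
    """
    angles = np.asarray(angles, dtype=np.float64)
    if angles.size == 0:
        raise ValueError("empty angle list")
    if angles.min() < 0 or angles.max() > 180:
        raise ValueError("angles must lie within [0, 180] degrees")
    imgs = project_slices(phantom.voxels, angles)  # (A, z, x)
    return ProjectionSet(images=imgs, angles=angles, role="clean")


def add_noise(projections: ProjectionSet, level: float, seed: int = 0) -> ProjectionSet:
    """Additive Gaussian noise emulating a short-exposure acquisition.

    The noise is zero-mean with standard deviation
    ``level * (max - min)`` of the whole clean stack, applied identically to
    every projection; ``level`` is the "percent noise" of the benchmark.
    """
    if level < 0:
        raise ValueError("noise level must be non-negative")
    if projections.role != "clean":
        raise ValueError("noise is added to clean projections")
    if level == 0:
        return replace(projections, images=projections.images.copy())
    rng = np.random.default_rng(seed)
    scale = float(projections.images.max() - projections.images.min())
    sigma = level * scale
    noisy = projections.images + rng.normal(
        0.0, sigma, size=projections.images.shape
    ).astype(np.float32)
    return ProjectionSet(
        images=noisy,
        angles=projections.angles,
        role="noisy",
        noise_level=level,
        exposure_s=projections.exposure_s,
    )
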