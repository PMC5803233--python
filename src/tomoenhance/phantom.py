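"""Synthetic sphere-in-cube phantom.

The benchmark object is a solid cube (gray value 0.3) floating in empty
space (0.0), filled with randomly placed spherical particles (1.0) with
diameters between 4 and 20 voxels.  The cube edge is ``floor(size/sqrt(2))``
so that its rotated shadow always fits on a detector as wide as the volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Phantom", "generate_phantom", "BACKGROUND", "CUBE", "PARTICLE"]

BACKGROUND = 0.0
CUBE = 0.3
PARTICLE = 1.0


@dataclass
class Phantom:
    """Labeled ground-truth volume.

    Attributes
    ----------
    voxels : (size, size, size) float32 array, values in {0.0, 0.3, 1.0}
        Axis order is (z, y, x); z is the rotation axis.
    size : edge length of the volume in voxels.
    sphere_params : list of ((cz, cy, cx), diameter) in voxel units.
    seed : RNG seed the phantom was generated from.
    """

    voxels: np.ndarray
    size: int
    sphere_params: list = field(default_factory=list)
    seed: int = 0


def generate_phantom(
    size: int,
    n_spheres: int,
    d_min: float = 4.0,
    d_max: float = 20.0,
    seed: int = 0,
) -> Phantom:
    """Generate the sphere-in-cube phantom.

    Sphere centers are uniform inside the cube region and diameters uniform
    on ``[d_min, d_max]``; overlapping spheres simply overwrite.  The result
    is deterministic for a fixed ``seed``.
    """
    if n_spheres < 0:
        raise ValueError("n_spheres must be non-negative")
    if not (0 < d_min <= d_max):
        raise ValueError("need 0 < d_min <= d_max")
    if d_max > size:
        raise ValueError("d_max exceeds the volume edge")

    rng = np.random.default_rng(seed)
    vox = np.zeros((size, size, size), dtype=np.float32)

    edge = int(size / np.sqrt(2.0))  # rotated cube stays inside the detector
    lo = (size - edge) // 2
    hi = lo + edge
    vox[lo:hi, lo:hi, lo:hi] = CUBE

    spheres: list = []
    if n_spheres:
        centers = rng.uniform(lo, hi, size=(n_spheres, 3))
        diams = rng.uniform(d_min, d_max, size=n_spheres)
        for c, d in zip(centers, diams):
            r = d / 2.0
            zlo, zhi = int(np.floor(c[0] - r)), int(np.ceil(c[0] + r)) + 1
            ylo, yhi = int(np.floor(c[1] - r)), int(np.ceil(c[1] + r)) + 1
            xlo, xhi = int(np.floor(c[2] - r)), int(np.ceil(c[2] + r)) + 1
            zlo, ylo, xlo = max(zlo, 0), max(ylo, 0), max(xlo, 0)
            zhi, yhi, xhi = min(zhi, size), min(yhi, size), min(xhi, size)
            zz, yy, xx = np.ogrid[zlo:zhi, ylo:yhi, xlo:xhi]
            mask = (
                (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
            ) <= r**2
            vox[zlo:zhi, ylo:yhi, xlo:xhi][mask] = PARTICLE
            spheres.append((tuple(c), float(d)))

    return Phantom(voxels=vox, size=size, sphere_params=spheres, seed=seed)
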