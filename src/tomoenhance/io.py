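"""Reading and writing projection stacks and volumes.

Two on-disk layouts are supported:

* multi-page TIFF (one float32 page per angle) with a sidecar text file
  ``<stem>.angles.txt`` holding one angle in degrees per line;
* HDF5 following the Scientific Data Exchange layout with ``/exchange/data``
  shaped (angle, row, column) and ``/exchange/theta`` (degrees unless its
  ``units`` attribute says radians).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import tifffile

from .projections import ProjectionSet
from .reconstruct import Volume

__all__ = ["read_stack", "write_stack", "read_volume", "write_volume"]

_TIFF_SUFFIXES = {".tif", ".tiff"}
_HDF5_SUFFIXES = {".h5", ".hdf5", ".hdf"}


def _angles_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".angles.txt")


def write_stack(projections: ProjectionSet, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF + angle sidecar, or HDF5 exchange."""
    path = Path(path)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        tifffile.imwrite(
            path, projections.images.astype(np.float32), photometric="minisblack"
        )
        np.savetxt(_angles_path(path), projections.angles, fmt="%.8g")
    elif path.suffix.lower() in _HDF5_SUFFIXES:
        with h5py.File(path, "w") as f:
            d = f.create_dataset(
                "/exchange/data", data=projections.images.astype(np.float32)
            )
            t = f.create_dataset("/exchange/theta", data=projections.angles)
            t.attrs["units"] = "degrees"
            d.attrs["role"] = projections.role
            d.attrs["noise_level"] = projections.noise_level
            if projections.exposure_s is not None:
                d.attrs["exposure_s"] = projections.exposure_s
    else:
        raise ValueError(f"unsupported stack format: {path.suffix!r}")
    return path


def read_stack(path: str | Path, role: str = "clean") -> ProjectionSet:
    """Read a projection stack written by :func:`write_stack` (or compatible)."""
    path = Path(path)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        images = np.asarray(tifffile.imread(path), dtype=np.float32)
        if images.ndim == 2:
            images = images[None]
        ap = _angles_path(path)
        if not ap.exists():
            raise FileNotFoundError(f"missing angle sidecar {ap}")
        angles = np.atleast_1d(np.loadtxt(ap, dtype=np.float64))
        meta: dict = {}
        noise_level = 0.0
        exposure = None
    elif path.suffix.lower() in _HDF5_SUFFIXES:
        with h5py.File(path, "r") as f:
            if "/exchange/data" not in f or "/exchange/theta" not in f:
                raise KeyError("file lacks /exchange/data or /exchange/theta")
            d = f["/exchange/data"]
            images = np.asarray(d, dtype=np.float32)
            theta = f["/exchange/theta"]
            angles = np.asarray(theta, dtype=np.float64)
            units = theta.attrs.get("units", "degrees")
            if isinstance(units, bytes):
                units = units.decode()
            if str(units).lower().startswith("rad"):
                angles = np.rad2deg(angles)
            role = str(d.attrs.get("role", role))
            noise_level = float(d.attrs.get("noise_level", 0.0))
            exposure = d.attrs.get("exposure_s")
            exposure = float(exposure) if exposure is not None else None
            meta = {}
    else:
        raise ValueError(f"unsupported stack format: {path.suffix!r}")
    if len(images) != len(angles):
        raise ValueError("angle list length does not match page count")
    return ProjectionSet(
        images=images,
        angles=angles,
        role=role,
        noise_level=noise_level,
        exposure_s=exposure,
        meta=meta,
    )


def write_volume(volume: Volume, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix.lower() not in _TIFF_SUFFIXES:
        raise ValueError("volumes are written as multi-page TIFF")
    tifffile.imwrite(path, volume.voxels.astype(np.float32), photometric="minisblack")
    return path


def read_volume(path: str | Path) -> Volume:
    vox = np.asarray(tifffile.imread(Path(path)), dtype=np.float32)
    if vox.ndim == 2:
        vox = vox[None]
    return Volume(voxels=vox)
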