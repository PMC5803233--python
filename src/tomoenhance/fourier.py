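"""Fourier-domain parallel-beam projection and GridRec reconstruction.

Both directions of the Radon transform are evaluated in the Fourier domain
using the central-slice theorem.  The spectrum of each slice lives on a 2x
zero-padded Cartesian grid; polar samples along the central slice of every
projection angle are related to that grid by a Kaiser--Bessel
interpolation/gridding kernel with analytic deapodization.  Because the
resampling geometry depends only on the detector width and the angle list,
it is captured once in a sparse matrix and applied to all slices of a
volume as a single sparse-dense product, which is what makes full-scale
(512^3, 721 angles) runs tractable on one CPU.

Filtered backprojection is obtained by weighting the polar samples with a
windowed ramp before gridding them back (GridRec).  The forward and adjoint
paths share the same sparse operator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft as _fft
import scipy.sparse as sp
from scipy.special import i0 as _bessel_i0

__all__ = ["GridOperator", "project_slices", "filtered_backproject_slices", "ramp_window"]

# Kaiser-Bessel kernel: 4-tap support on the 2x-oversampled grid.  beta from
# Beatty et al.'s minimal-aliasing formula for width 4, oversampling 2.
_KB_WIDTH = 4
_KB_BETA = float(np.pi * np.sqrt((_KB_WIDTH / 2.0 * 1.5) ** 2 - 0.8))


def _kb_kernel(u: np.ndarray) -> np.ndarray:
    """Kaiser-Bessel kernel value at offset ``u`` (grid cells, |u| <= W/2)."""
    z = 1.0 - (2.0 * u / _KB_WIDTH) ** 2
    out = np.zeros_like(u, dtype=np.float64)
    ok = z > 0
    out[ok] = _bessel_i0(_KB_BETA * np.sqrt(z[ok])) / _bessel_i0(_KB_BETA)
    return out


def _kb_transform(xi: np.ndarray) -> np.ndarray:
    """Continuous Fourier transform of the kernel at ``xi`` cycles/cell."""
    arg = _KB_BETA**2 - (np.pi * _KB_WIDTH * xi) ** 2
    out = np.empty_like(arg)
    pos = arg > 0
    sq = np.sqrt(np.abs(arg))
    out[pos] = np.sinh(sq[pos]) / sq[pos]
    out[~pos] = np.sinc(sq[~pos] / np.pi)  # sin(x)/x branch
    return out * (_KB_WIDTH / _bessel_i0(_KB_BETA))


def ramp_window(name: str, rel_freq: np.ndarray) -> np.ndarray:
    """Apodizing window for the ramp filter.

    ``rel_freq`` is frequency relative to the detector Nyquist, in [0, 1].
    Supported windows: ``ramp`` (none), ``parzen``, ``shepp``, ``cosine``,
    ``hann``.
    """
    q = np.clip(np.abs(rel_freq), 0.0, 1.0)
    if name == "ramp":
        return np.ones_like(q)
    if name == "parzen":
        w = np.where(q <= 0.5, 1.0 - 6.0 * q**2 * (1.0 - q), 2.0 * (1.0 - q) ** 3)
        return w
    if name == "shepp":
        return np.sinc(q / 2.0)
    if name == "cosine":
        return np.cos(np.pi * q / 2.0)
    if name == "hann":
        return 0.5 * (1.0 + np.cos(np.pi * q))
    raise ValueError(f"unknown filter window: {name!r}")


@dataclass
class GridOperator:
    """Sparse polar<->Cartesian resampler for one (detector, angles) geometry."""

    n_det: int
    angles_deg: np.ndarray
    gather: sp.csr_matrix  # (n_angles * n_pad, n_pad**2)
    deapod_2d: np.ndarray  # (n_pad, n_pad) spatial correction, centered
    deapod_1d: np.ndarray  # (n_pad,) correction along the detector
    freqs: np.ndarray  # (n_pad,) integer frequency index m, centered

    @property
    def n_pad(self) -> int:
        return 2 * self.n_det

    @classmethod
    def build(cls, n_det: int, angles_deg: np.ndarray) -> "GridOperator":
        angles_deg = np.asarray(angles_deg, dtype=np.float64)
        n_pad = 2 * n_det
        m = np.arange(-n_det, n_det, dtype=np.float64)  # frequency index
        theta = np.deg2rad(angles_deg)
        # sample coordinates on the padded grid, centered at n_pad//2
        gu = m[None, :] * np.cos(theta)[:, None] + n_pad // 2  # axis 1 (cols)
        gv = m[None, :] * np.sin(theta)[:, None] + n_pad // 2  # axis 0 (rows)
        n_rows = gu.size
        gu = gu.ravel()
        gv = gv.ravel()

        half = _KB_WIDTH // 2
        base_u = np.floor(gu).astype(np.int64)
        base_v = np.floor(gv).astype(np.int64)
        offs = np.arange(1 - half, half + 1, dtype=np.int64)  # e.g. [-1,0,1,2]
        iu = base_u[:, None] + offs[None, :]
        iv = base_v[:, None] + offs[None, :]
        wu = _kb_kernel(iu - gu[:, None])
        wv = _kb_kernel(iv - gv[:, None])
        # clip out-of-range taps (their weight is zeroed)
        for idx, w in ((iu, wu), (iv, wv)):
            bad = (idx < 0) | (idx >= n_pad)
            w[bad] = 0.0
            np.clip(idx, 0, n_pad - 1, out=idx)

        rows = np.repeat(np.arange(n_rows, dtype=np.int64), _KB_WIDTH**2)
        cols = (iv[:, :, None] * n_pad + iu[:, None, :]).ravel()
        vals = (wv[:, :, None] * wu[:, None, :]).ravel()
        keep = vals != 0.0
        mat = sp.csr_matrix(
            (vals[keep].astype(np.float32), (rows[keep], cols[keep].astype(np.int64))),
            shape=(n_rows, n_pad * n_pad),
        )

        x = np.arange(n_pad, dtype=np.float64) - n_pad // 2
        dea = _kb_transform(x / n_pad)
        return cls(
            n_det=n_det,
            angles_deg=angles_deg,
            gather=mat,
            deapod_2d=np.outer(dea, dea),
            deapod_1d=dea,
            freqs=m,
        )


_OP_CACHE: dict[tuple, GridOperator] = {}


def get_operator(n_det: int, angles_deg: np.ndarray) -> GridOperator:
    key = (n_det, np.asarray(angles_deg, dtype=np.float64).tobytes())
    op = _OP_CACHE.get(key)
    if op is None:
        if len(_OP_CACHE) > 4:  # bound the cache; operators can be large
            _OP_CACHE.clear()
        op = GridOperator.build(n_det, angles_deg)
        _OP_CACHE[key] = op
    return op


def _embed(slices: np.ndarray, n_pad: int) -> np.ndarray:
    """Zero-pad (S, N, N) slices to (S, n_pad, n_pad), centers aligned."""
    s, n, _ = slices.shape
    off = n_pad // 2 - n // 2
    out = np.zeros((s, n_pad, n_pad), dtype=np.float32)
    out[:, off : off + n, off : off + n] = slices
    return out


def project_slices(
    slices: np.ndarray, angles_deg: np.ndarray, chunk: int = 32
) -> np.ndarray:
    """Parallel-beam Radon transform of a stack of square slices.

    Parameters
    ----------
    slices : (S, N, N) array
        Image slices; the rotation axis passes through pixel index N//2.
    angles_deg : (A,) array
        Projection angles in degrees (counter-clockwise; at 0 deg the ray
        integrates along axis 0, so the projection is the column sum).

    Returns
    -------
    (A, S, N) array of line integrals (detector pixel = image pixel pitch).
    """
    slices = np.asarray(slices, dtype=np.float32)
    if slices.ndim != 3 or slices.shape[1] != slices.shape[2]:
        raise ValueError("expected a (S, N, N) stack of square slices")
    n = slices.shape[1]
    op = get_operator(n, angles_deg)
    n_pad = op.n_pad
    n_ang = len(op.angles_deg)
    off = n_pad // 2 - n // 2
    dea = op.deapod_2d[off : off + n, off : off + n].astype(np.float32)

    out = np.empty((n_ang, slices.shape[0], n), dtype=np.float32)
    for lo in range(0, slices.shape[0], chunk):
        blk = slices[lo : lo + chunk] / dea
        emb = _embed(blk, n_pad)
        spec = _fft.fft2(_fft.ifftshift(emb, axes=(1, 2)), axes=(1, 2), workers=1)
        spec = _fft.fftshift(spec, axes=(1, 2)).astype(np.complex64)
        b = spec.reshape(spec.shape[0], -1).T.copy()  # (n_pad^2, S)
        polar = op.gather @ b  # (A*n_pad, S) complex64
        polar = polar.reshape(n_ang, n_pad, -1)
        p = _fft.ifft(_fft.ifftshift(polar, axes=1), axis=1, workers=1)
        p = _fft.fftshift(p, axes=1).real.astype(np.float32)
        out[:, lo : lo + blk.shape[0], :] = np.swapaxes(
            p[:, off : off + n, :], 1, 2
        )
    return out


def _angle_weights(angles_deg: np.ndarray) -> np.ndarray:
    """Trapezoid-style weights in radians for the angular integral."""
    a = np.asarray(angles_deg, dtype=np.float64)
    if a.size < 2:
        raise ValueError("need at least two angles")
    d = np.deg2rad(np.diff(a))
    w = np.empty_like(a)
    w[0] = d[0] / 2
    w[-1] = d[-1] / 2
    w[1:-1] = (d[:-1] + d[1:]) / 2
    span = abs(a[-1] - a[0])
    if span < 179.0:  # partial coverage: keep total weight at pi
        w *= np.pi / w.sum()
    return w


def filtered_backproject_slices(
    sinos: np.ndarray,
    angles_deg: np.ndarray,
    filter_name: str = "parzen",
    center: float | None = None,
    chunk: int = 32,
) -> np.ndarray:
    """GridRec reconstruction of a stack of sinograms.

    Parameters
    ----------
    sinos : (A, S, N) array
        Projections (angle, slice, detector).
    angles_deg : (A,) array
    filter_name : window applied to the ramp filter (default ``parzen``).
    center : rotation-axis position in detector pixels (default N//2).

    Returns
    -------
    (S, N, N) reconstructed slices.
    """
    sinos = np.asarray(sinos, dtype=np.float32)
    if sinos.ndim != 3:
        raise ValueError("expected (A, S, N) sinogram stack")
    if np.isnan(sinos).any():
        raise ValueError("sinograms contain NaN")
    n_ang, n_sl, n = sinos.shape
    if n_ang != len(angles_deg):
        raise ValueError("angle count does not match projection count")
    op = get_operator(n, angles_deg)
    n_pad = op.n_pad
    off = n_pad // 2 - n // 2

    m = op.freqs
    w_ang = _angle_weights(angles_deg)
    filt = np.abs(m) / n_pad**2 * ramp_window(filter_name, m / n)
    weight = (w_ang[:, None] * filt[None, :]).astype(np.float32)  # (A, n_pad)
    if center is not None and center != n // 2:
        phase = np.exp(-2j * np.pi * m * (center - n // 2) / n_pad).astype(np.complex64)
    else:
        phase = None

    dea = op.deapod_2d[off : off + n, off : off + n].astype(np.float32)
    scatter = op.gather.T.tocsr()
    out = np.empty((n_sl, n, n), dtype=np.float32)
    for lo in range(0, n_sl, chunk):
        blk = sinos[:, lo : lo + chunk, :]  # (A, s, N)
        pad = np.zeros((n_ang, blk.shape[1], n_pad), dtype=np.float32)
        pad[:, :, off : off + n] = blk
        spec = _fft.fft(_fft.ifftshift(pad, axes=2), axis=2, workers=1)
        spec = _fft.fftshift(spec, axes=2).astype(np.complex64)  # (A, s, n_pad)
        if phase is not None:
            spec *= phase[None, None, :]
        spec *= weight[:, None, :]
        flat = np.swapaxes(spec, 1, 2).reshape(n_ang * n_pad, -1)
        q = scatter @ flat  # (n_pad^2, s)
        q = q.T.reshape(-1, n_pad, n_pad)
        img = _fft.ifft2(_fft.ifftshift(q, axes=(1, 2)), axes=(1, 2), workers=1)
        img = _fft.fftshift(img, axes=(1, 2)).real.astype(np.float32) * n_pad**2
        out[lo : lo + img.shape[0]] = img[:, off : off + n, off : off + n] / dea
    return out
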