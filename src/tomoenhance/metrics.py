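"""Image-quality evaluation: PSNR, SSIM maps, per-slice reports, histograms.

Evaluation PSNR uses the conventional ``data_range**2 / MSE`` form; with
unit-range reconstructions this coincides with the network objective's
unsquared peak value.  SSIM follows the standard Gaussian-windowed
definition (11x11, sigma 1.5, K1 = 0.01, K2 = 0.03).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from skimage.metrics import structural_similarity

from .reconstruct import Volume

__all__ = [
    "psnr",
    "ssim",
    "ssim_map",
    "QualityReport",
    "volume_report",
    "histogram_modes",
]

PSNR_CAP = 100.0  # dB reported for identical images


def psnr(test: np.ndarray, reference: np.ndarray, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio, 10*log10(data_range^2 / MSE), in dB."""
    test = np.asarray(test, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if test.shape != reference.shape:
        raise ValueError("shape mismatch")
    mse = float(np.mean((test - reference) ** 2))
    if mse == 0:
        return PSNR_CAP
    return min(10.0 * np.log10(data_range**2 / mse), PSNR_CAP)


_SSIM_KW = dict(gaussian_weights=True, sigma=1.5, win_size=11, K1=0.01, K2=0.03)


def ssim(test: np.ndarray, reference: np.ndarray, data_range: float = 1.0) -> float:
    """Global SSIM score (mean of the SSIM map)."""
    return float(
        structural_similarity(
            np.asarray(test, np.float64),
            np.asarray(reference, np.float64),
            data_range=data_range,
            **_SSIM_KW,
        )
    )


def ssim_map(
    test: np.ndarray,
    reference: np.ndarray,
    window: int = 11,
    data_range: float = 1.0,
) -> np.ndarray:
    """Per-pixel SSIM map with a Gaussian window (sigma 1.5)."""
    test = np.asarray(test, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if test.shape != reference.shape:
        raise ValueError("shape mismatch")
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > min(test.shape):
        raise ValueError("window larger than the image")
    kw = dict(_SSIM_KW)
    kw["win_size"] = window
    _, smap = structural_similarity(
        test, reference, data_range=data_range, full=True, **kw
    )
    return smap


@dataclass
class QualityReport:
    """Slice-wise PSNR/SSIM summary for a reconstructed volume."""

    psnr_mean: float
    psnr_std: float
    ssim_mean: float
    ssim_std: float
    per_slice: list  # (slice index, psnr, ssim)

    def as_dict(self) -> dict:
        return {
            "psnr_mean": self.psnr_mean,
            "psnr_std": self.psnr_std,
            "ssim_mean": self.ssim_mean,
            "ssim_std": self.ssim_std,
            "per_slice": [list(t) for t in self.per_slice],
        }


def volume_report(
    test: Volume | np.ndarray,
    reference: Volume | np.ndarray,
    data_range: float = 1.0,
) -> QualityReport:
    """Per-slice PSNR/SSIM of two volumes plus means and spreads."""
    tv = test.voxels if isinstance(test, Volume) else np.asarray(test)
    rv = reference.voxels if isinstance(reference, Volume) else np.asarray(reference)
    if tv.shape != rv.shape:
        raise ValueError("volume shapes differ")
    rows = []
    for i in range(tv.shape[0]):
        rows.append(
            (i, psnr(tv[i], rv[i], data_range), ssim(tv[i], rv[i], data_range))
        )
    ps = np.array([r[1] for r in rows])
    ss = np.array([r[2] for r in rows])
    return QualityReport(
        psnr_mean=float(ps.mean()),
        psnr_std=float(ps.std()),
        ssim_mean=float(ss.mean()),
        ssim_std=float(ss.std()),
        per_slice=rows,
    )


def histogram_modes(
    volume: Volume | np.ndarray,
    n_bins: int = 256,
    smooth: int = 5,
    prominence_frac: float = 0.01,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Gray-value histogram of a volume and its detected mode count.

    The histogram is smoothed with a fixed ``smooth``-bin moving average and
    local maxima with prominence at least ``prominence_frac`` of the tallest
    (smoothed) bin are counted as modes; histogram-edge maxima count.
    """
    vox = volume.voxels if isinstance(volume, Volume) else np.asarray(volume)
    if vox.size == 0:
        raise ValueError("empty volume")
    if n_bins < 8:
        raise ValueError("need at least 8 bins")
    counts, edges = np.histogram(vox, bins=n_bins)
    sm = np.convolve(counts.astype(np.float64), np.ones(smooth) / smooth, mode="same")
    padded = np.concatenate([[0.0], sm, [0.0]])  # let edge peaks register
    peaks, _ = find_peaks(padded, prominence=prominence_frac * sm.max())
    return edges, counts, int(len(peaks))
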