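"""Convolution primitives (im2col/GEMM) for the enhancement network.

All convolutions use 3x3 kernels with 'same'-style padding of 1.  A strided
convolution halves even spatial sizes; its exact adjoint (used both as the
transpose-convolution forward pass and as the gradient of the convolution
input) doubles them.  The adjoint is realised by zero-stuffing to the target
size followed by a stride-1 convolution with the spatially flipped,
channel-transposed kernel, which keeps every hot path inside BLAS.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

K = 3  # kernel edge
PAD = 1


def im2col(x: np.ndarray, stride: int) -> tuple[np.ndarray, tuple[int, int]]:
    """(B, C, H, W) -> (B, Ho*Wo, C*9) patch matrix for a 3x3 conv."""
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (PAD, PAD), (PAD, PAD)))
    win = sliding_window_view(xp, (K, K), axis=(2, 3))  # (B, C, H, W, 3, 3)
    win = win[:, :, ::stride, ::stride]
    ho, wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b, ho * wo, c * K * K)
    return np.ascontiguousarray(cols), (ho, wo)


def conv_forward(
    x: np.ndarray, w: np.ndarray, bias: np.ndarray, stride: int
) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """3x3 convolution; returns output, cached columns and spatial size."""
    cout = w.shape[0]
    cols, (ho, wo) = im2col(x, stride)
    y = cols @ w.reshape(cout, -1).T + bias
    y = y.transpose(0, 2, 1).reshape(x.shape[0], cout, ho, wo)
    return y, cols, (ho, wo)


def conv_weight_grad(cols: np.ndarray, gy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of kernel and bias from cached columns and output grad.

    ``gy`` is (B, Cout, Ho, Wo); returns (Cout, Cin*9) and (Cout,).
    """
    b, cout = gy.shape[0], gy.shape[1]
    g = gy.reshape(b, cout, -1).transpose(0, 2, 1).reshape(-1, cout)
    gw = g.T @ cols.reshape(-1, cols.shape[-1])
    return gw, gy.sum(axis=(0, 2, 3))


def _stuff(x: np.ndarray, stride: int, out_hw: tuple[int, int]) -> np.ndarray:
    """Insert stride-1 zeros so that x[i] lands at output index i*stride."""
    if stride == 1:
        return x
    b, c = x.shape[:2]
    out = np.zeros((b, c, out_hw[0], out_hw[1]), dtype=x.dtype)
    out[:, :, :: stride, :: stride] = x
    return out


def conv_backward_data(
    gy: np.ndarray, w: np.ndarray, stride: int, out_hw: tuple[int, int]
) -> np.ndarray:
    """Adjoint of :func:`conv_forward` with respect to its input.

    Maps a (B, Cout, Ho, Wo) tensor back to (B, Cin, *out_hw).  This is also
    the forward pass of a 3x3 transpose convolution.
    """
    wt = np.ascontiguousarray(w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
    stuffed = _stuff(gy, stride, out_hw)
    cin = wt.shape[0]
    cols, (ho, wo) = im2col(stuffed, 1)
    y = cols @ wt.reshape(cin, -1).T
    return y.transpose(0, 2, 1).reshape(gy.shape[0], cin, ho, wo)
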