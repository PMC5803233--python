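"""Trainable layers with explicit forward/backward passes."""

from __future__ import annotations

import numpy as np

from . import ops


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Layer:
    """Base: parameters live in ``params`` (dict name -> array), gradients in
    ``grads`` with matching keys after a backward pass."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class Conv2d(Layer):
    """3x3 convolution (+ ReLU) with stride 1 or 2."""

    def __init__(self, c_in: int, c_out: int, stride: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out, self.stride = c_in, c_out, stride
        self.params["w"] = _he_init(rng, (c_out, c_in, 3, 3), fan_in=c_in * 9)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)
        self._cols: np.ndarray | None = None
        self._in_hw: tuple[int, int] = (0, 0)
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_hw = x.shape[2:]
        y, self._cols, _ = ops.conv_forward(
            x, self.params["w"], self.params["b"], self.stride
        )
        self._mask = y > 0
        return _relu(y)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gy = gy * self._mask
        gw, gb = ops.conv_weight_grad(self._cols, gy)
        self.grads["w"] = gw.reshape(self.params["w"].shape)
        self.grads["b"] = gb
        self._cols = None
        return ops.conv_backward_data(gy, self.params["w"], self.stride, self._in_hw)


class ConvTranspose2d(Layer):
    """3x3 transpose convolution (+ ReLU); stride 2 doubles H and W."""

    def __init__(self, c_in: int, c_out: int, stride: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out, self.stride = c_in, c_out, stride
        # stored in the layout of the convolution whose adjoint this is
        self.params["w"] = _he_init(rng, (c_in, c_out, 3, 3), fan_in=c_in * 9)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)
        self._x: np.ndarray | None = None
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        out_hw = (x.shape[2] * self.stride, x.shape[3] * self.stride)
        y = ops.conv_backward_data(x, self.params["w"], self.stride, out_hw)
        y += self.params["b"][None, :, None, None]
        self._mask = y > 0
        return _relu(y)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gy = gy * self._mask
        self.grads["b"] = gy.sum(axis=(0, 2, 3))
        cols, _ = ops.im2col(gy, self.stride)
        gw, _ = ops.conv_weight_grad(cols, self._x)
        self.grads["w"] = gw.reshape(self.params["w"].shape)
        gx, _, _ = ops.conv_forward(
            gy, self.params["w"], np.zeros(self.c_in, np.float32), self.stride
        )
        self._x = None
        return gx


class Dense(Layer):
    """Fully connected bottleneck (+ ReLU) acting on flattened feature maps."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.params["w"] = _he_init(rng, (n_in, n_out), fan_in=n_in)
        self.params["b"] = np.zeros(n_out, dtype=np.float32)
        self._x: np.ndarray | None = None
        self._mask: np.ndarray | None = None
        self._shape: tuple = ()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        flat = x.reshape(x.shape[0], -1)
        self._x = flat
        y = flat @ self.params["w"] + self.params["b"]
        self._mask = y > 0
        return _relu(y).reshape(self._shape)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = gy.reshape(gy.shape[0], -1) * self._mask
        self.grads["w"] = self._x.T @ g
        self.grads["b"] = g.sum(axis=0)
        gx = g @ self.params["w"].T
        self._x = None
        return gx.reshape(self._shape)
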