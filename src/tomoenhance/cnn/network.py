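"""Encoder-decoder network with scale-matched skip merges.

The encoder is 8 convolutional layers (3x3 kernels, kernel counts rising
16 -> 64, three of them with stride 2) followed by a shape-preserving fully
connected bottleneck at 1/8 spatial scale.  The decoder is 9 transpose-
convolutional layers (kernel counts falling 64 -> 1, three with stride 2).
After each upsampling deconvolution the feature maps are concatenated with
the encoder feature maps of the same spatial scale, so the decoder sees
every resolution of the input; ReLU activations throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import Conv2d, ConvTranspose2d, Dense, Layer

DEFAULT_ENCODER = ((16, 1), (16, 2), (32, 1), (32, 2), (32, 1), (64, 2), (64, 1), (64, 1))
DEFAULT_DECODER = ((64, 1), (64, 1), (32, 2), (32, 1), (32, 2), (16, 1), (16, 2), (16, 1), (1, 1))
# (encoder layer, decoder layer), 1-based: concatenate the encoder output
# with the decoder output of the same spatial scale.
DEFAULT_MERGES = ((5, 3), (3, 5), (1, 7))


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description: (n_kernels, stride) per layer."""

    encoder_layers: tuple = DEFAULT_ENCODER
    decoder_layers: tuple = DEFAULT_DECODER
    merge_links: tuple = DEFAULT_MERGES
    activation: str = "relu"
    merges_enabled: bool = True

    def validate(self) -> None:
        if len(self.encoder_layers) != 8:
            raise ValueError("encoder must have 8 convolutional layers")
        if sum(1 for _, s in self.encoder_layers if s == 2) != 3:
            raise ValueError("encoder must have exactly 3 stride-2 layers")
        if len(self.decoder_layers) != 9:
            raise ValueError("decoder must have 9 deconvolutional layers")
        if sum(1 for _, s in self.decoder_layers if s == 2) != 3:
            raise ValueError("decoder must have exactly 3 stride-2 layers")
        if self.decoder_layers[-1][0] != 1:
            raise ValueError("final decoder layer must have a single kernel")
        if not all(16 <= k <= 64 for k, _ in self.encoder_layers):
            raise ValueError("encoder kernel counts must lie in [16, 64]")
        if self.activation != "relu":
            raise ValueError("only rectified-linear activation is supported")


class EncoderDecoder:
    """The assembled network; operates on (B, 1, E, E) patches."""

    def __init__(self, spec: NetworkSpec, patch_edge: int, seed: int = 0):
        spec.validate()
        if patch_edge % 8 != 0 or patch_edge <= 0:
            raise ValueError("patch edge must be a positive multiple of 8")
        self.spec = spec
        self.patch_edge = patch_edge
        rng = np.random.default_rng(seed)

        self.encoder: list[Layer] = []
        c = 1
        enc_out_channels = []
        for k, s in spec.encoder_layers:
            self.encoder.append(Conv2d(c, k, s, rng))
            c = k
            enc_out_channels.append(k)

        bott_edge = patch_edge // 8
        n_flat = bott_edge * bott_edge * c
        self.bottleneck = Dense(n_flat, n_flat, rng)

        self._merge_after: dict[int, int] = {}  # decoder idx (1-based) -> encoder idx
        if spec.merges_enabled:
            for enc_i, dec_i in spec.merge_links:
                self._merge_after[dec_i] = enc_i

        self.decoder: list[Layer] = []
        for i, (k, s) in enumerate(spec.decoder_layers, start=1):
            self.decoder.append(ConvTranspose2d(c, k, s, rng))
            c = k
            if i in self._merge_after:
                c += enc_out_channels[self._merge_after[i] - 1]

    # -- execution ---------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim == 3:
            x = x[:, None]
        if x.shape[2] % 8 or x.shape[3] % 8:
            raise ValueError("input edge must be divisible by 8")
        h = x.astype(np.float32)
        self._enc_out: list[np.ndarray] = []
        for layer in self.encoder:
            h = layer.forward(h)
            self._enc_out.append(h)
        h = self.bottleneck.forward(h)
        self._merge_channels: dict[int, int] = {}
        for i, layer in enumerate(self.decoder, start=1):
            h = layer.forward(h)
            if i in self._merge_after:
                skip = self._enc_out[self._merge_after[i] - 1]
                self._merge_channels[i] = h.shape[1]
                h = np.concatenate([h, skip], axis=1)
        return h[:, 0]

    def backward(self, gy: np.ndarray) -> None:
        g = gy[:, None].astype(np.float32)
        skip_grads: dict[int, np.ndarray] = {}
        for i in range(len(self.decoder), 0, -1):
            if i in self._merge_after:
                c = self._merge_channels[i]
                skip_grads[self._merge_after[i]] = g[:, c:]
                g = np.ascontiguousarray(g[:, :c])
            g = self.decoder[i - 1].backward(g)
        g = self.bottleneck.backward(g)
        for i in range(len(self.encoder), 0, -1):
            if i in skip_grads:
                g = g + skip_grads[i]
            g = self.encoder[i - 1].backward(g)

    # -- parameter access --------------------------------------------------
    def _named_layers(self):
        for i, layer in enumerate(self.encoder):
            yield f"enc{i + 1}", layer
        yield "fc", self.bottleneck
        for i, layer in enumerate(self.decoder):
            yield f"dec{i + 1}", layer

    def parameters(self) -> dict[str, np.ndarray]:
        return {
            f"{name}.{p}": arr
            for name, layer in self._named_layers()
            for p, arr in layer.params.items()
        }

    def gradients(self) -> dict[str, np.ndarray]:
        return {
            f"{name}.{p}": arr
            for name, layer in self._named_layers()
            for p, arr in layer.grads.items()
        }

    def set_parameters(self, values: dict[str, np.ndarray]) -> None:
        own = self.parameters()
        for k, v in values.items():
            if k not in own:
                raise KeyError(f"unknown parameter {k}")
            if own[k].shape != v.shape:
                raise ValueError(f"shape mismatch for {k}")
            own[k][...] = v
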