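"""Training and inference for the projection-enhancement network.

The network learns the mapping f from short-exposure (noisy) to
long-exposure (clean) projections of the same object.  A handful of angle
pairs is enough: both images of a pair are normalized with the
short-exposure image's two-step parameters, decomposed into overlapping
patches, and the network is fit by minimizing 1/PSNR of the predicted
patches.  At inference every projection is normalized, enhanced patch by
patch, reassembled by averaging, and de-normalized with its own input
parameters, so enhanced stacks come back on the physical scale of the
input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cnn.network import EncoderDecoder, NetworkSpec
from .cnn.optim import Adam
from .preprocess import (
    apply_normalization,
    denormalize,
    extract_patches,
    normalize_two_step,
    reassemble_patches,
)
from .projections import ProjectionSet

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "TrainedModel",
    "build_network",
    "psnr_loss",
    "train",
    "enhance",
    "save_model",
    "load_model",
]

MSE_EPS = 1e-12  # floor keeping the objective finite for perfect predictions
_PSNR_FLOOR = 0.5  # dB; keeps 1/PSNR bounded for catastrophic predictions


@dataclass
class TrainConfig:
    """Optimization settings for :func:`train`."""

    epochs: int = 40
    batch_size: int = 32
    learning_rate: float = 1e-3
    stride: int = 16
    val_fraction: float = 0.1
    seed: int = 0


@dataclass
class TrainedModel:
    """Network spec plus fitted weights and the training log."""

    spec: NetworkSpec
    net: EncoderDecoder
    patch_edge: int
    seed: int
    training_log: list = field(default_factory=list)

    @property
    def is_trained(self) -> bool:
        return len(self.training_log) > 0


def build_network(
    spec: NetworkSpec | None = None, patch_edge: int = 64, seed: int = 0
) -> TrainedModel:
    """Instantiate an untrained model with deterministic initialization."""
    spec = spec or NetworkSpec()
    net = EncoderDecoder(spec, patch_edge=patch_edge, seed=seed)
    return TrainedModel(spec=spec, net=net, patch_edge=patch_edge, seed=seed)


def psnr_loss(
    prediction: np.ndarray, target: np.ndarray, i_max: float = 1.0
) -> float:
    """Training objective 1/PSNR with PSNR = 10*log10(i_max / MSE).

    The unsquared ``i_max`` follows the objective as stated for the network;
    with normalized unit-range patches (i_max = 1) it coincides with the
    conventional definition used for evaluation.
    """
    if prediction.shape != target.shape:
        raise ValueError("shape mismatch")
    if not i_max > 0:
        raise ValueError("i_max must be positive")
    mse = max(float(np.mean((prediction - target) ** 2)), MSE_EPS)
    psnr = max(10.0 * np.log10(i_max / mse), _PSNR_FLOOR)
    return 1.0 / psnr


def _psnr_loss_grad(
    prediction: np.ndarray, target: np.ndarray, i_max: float = 1.0
) -> tuple[float, np.ndarray]:
    diff = prediction - target
    mse = max(float(np.mean(diff**2)), MSE_EPS)
    psnr = 10.0 * np.log10(i_max / mse)
    if psnr <= _PSNR_FLOOR:  # clamped region: fall back to MSE descent
        return 1.0 / _PSNR_FLOOR, (2.0 / diff.size) * diff
    # d(1/PSNR)/dMSE = 10 / (PSNR^2 * MSE * ln 10)
    scale = 10.0 / (psnr**2 * mse * np.log(10.0))
    return 1.0 / psnr, scale * (2.0 / diff.size) * diff


def _make_patch_pairs(
    pairs, patch_edge: int, stride: int
) -> tuple[np.ndarray, np.ndarray]:
    xs, ts = [], []
    for short_img, long_img in pairs:
        short_img = np.asarray(short_img, dtype=np.float32)
        long_img = np.asarray(long_img, dtype=np.float32)
        if short_img.shape != long_img.shape:
            raise ValueError("images within a pair must share a shape")
        norm_in, params = normalize_two_step(short_img)
        norm_tg = apply_normalization(long_img, params)
        px, _ = extract_patches(norm_in, patch_edge, stride)
        pt, _ = extract_patches(norm_tg, patch_edge, stride)
        xs.append(px)
        ts.append(pt)
    return np.concatenate(xs), np.concatenate(ts)


def train(
    model: TrainedModel,
    pairs: list[tuple[np.ndarray, np.ndarray]],
    config: TrainConfig | None = None,
) -> TrainedModel:
    """Fit the model on (short-exposure, long-exposure) image pairs.

    Logs per-epoch mean training MSE, validation MSE and mean 1/PSNR loss in
    ``model.training_log``.  Deterministic for a fixed config seed.
    """
    config = config or TrainConfig()
    if not pairs:
        raise ValueError("need at least one training pair")
    x, t = _make_patch_pairs(pairs, model.patch_edge, config.stride)
    if len(x) == 0:
        raise ValueError("no training patches")

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(x))
    n_val = int(round(config.val_fraction * len(x)))
    n_val = min(n_val, len(x) - 1)
    val_idx, train_idx = order[:n_val], order[n_val:]
    xv, tv = x[val_idx], t[val_idx]
    xt, tt = x[train_idx], t[train_idx]

    opt = Adam(model.net.parameters(), lr=config.learning_rate)
    bs = config.batch_size
    for epoch in range(config.epochs):
        perm = rng.permutation(len(xt))
        mse_sum = 0.0
        loss_sum = 0.0
        n_batches = 0
        for lo in range(0, len(xt), bs):
            sel = perm[lo : lo + bs]
            pred = model.net.forward(xt[sel])
            loss, grad = _psnr_loss_grad(pred, tt[sel])
            model.net.backward(grad.astype(np.float32))
            opt.step(model.net.gradients())
            mse_sum += float(np.mean((pred - tt[sel]) ** 2))
            loss_sum += loss
            n_batches += 1
        val_mse = _eval_mse(model.net, xv, tv, bs) if n_val else float("nan")
        model.training_log.append(
            {
                "epoch": epoch + 1,
                "train_mse": mse_sum / n_batches,
                "val_mse": val_mse,
                "loss": loss_sum / n_batches,
            }
        )
    return model


def _eval_mse(net: EncoderDecoder, x: np.ndarray, t: np.ndarray, bs: int) -> float:
    tot = 0.0
    for lo in range(0, len(x), bs):
        pred = net.forward(x[lo : lo + bs])
        tot += float(np.sum((pred - t[lo : lo + bs]) ** 2))
    return tot / t.size


def enhance(
    model: TrainedModel,
    projections: ProjectionSet,
    stride: int | None = None,
    batch_size: int = 128,
) -> ProjectionSet:
    """Run the trained network over a full projection stack.

    Each image is normalized, split into overlapping patches (default
    stride = patch_edge / 2), passed through the network, reassembled by
    averaging, and mapped back to the input's intensity scale.  The output
    stack has identical geometry and angles with role ``enhanced``.
    """
    if not model.is_trained:
        raise ValueError("model has not been trained")
    stride = stride or model.patch_edge // 2
    out = np.empty_like(projections.images)
    for i, img in enumerate(projections.images):
        norm, params = normalize_two_step(img)
        patches, grid = extract_patches(norm, model.patch_edge, stride)
        pred = np.empty_like(patches)
        for lo in range(0, len(patches), batch_size):
            pred[lo : lo + batch_size] = model.net.forward(patches[lo : lo + batch_size])
        out[i] = denormalize(reassemble_patches(pred, grid), params)
    return ProjectionSet(
        images=out,
        angles=projections.angles.copy(),
        role="enhanced",
        noise_level=projections.noise_level,
        exposure_s=projections.exposure_s,
    )


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Save spec + weights + log as a single .npz archive."""
    import json

    spec = model.spec
    meta = {
        "encoder_layers": [list(t) for t in spec.encoder_layers],
        "decoder_layers": [list(t) for t in spec.decoder_layers],
        "merge_links": [list(t) for t in spec.merge_links],
        "activation": spec.activation,
        "merges_enabled": spec.merges_enabled,
        "patch_edge": model.patch_edge,
        "seed": model.seed,
        "training_log": model.training_log,
    }
    arrays = {f"param/{k}": v for k, v in model.net.parameters().items()}
    np.savez_compressed(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8
    ), **arrays)


def load_model(path: str | Path) -> TrainedModel:
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        spec = NetworkSpec(
            encoder_layers=tuple(tuple(t) for t in meta["encoder_layers"]),
            decoder_layers=tuple(tuple(t) for t in meta["decoder_layers"]),
            merge_links=tuple(tuple(t) for t in meta["merge_links"]),
            activation=meta["activation"],
            merges_enabled=meta["merges_enabled"],
        )
        model = build_network(spec, patch_edge=meta["patch_edge"], seed=meta["seed"])
        model.net.set_parameters(
            {k[len("param/") :]: data[k] for k in data.files if k.startswith("param/")}
        )
        model.training_log = meta["training_log"]
    return model
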