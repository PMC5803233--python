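"""The synthetic evaluation benchmark at full or reduced scale.

The reference experiment uses a 512^3 phantom with 1000 spheres, 721
equispaced angles over [0, 180] degrees, Gaussian noise at 5-30%% of the
clean stack's range, training pairs at 0 and 45 degrees, and GridRec
reconstruction with a Parzen filter.  ``benchmark_params`` scales these
conditions self-similarly to smaller volumes: sphere density (spheres per
voxel) and the angle-count-to-detector-width ratio are preserved, so a
128^3 surrogate keeps the statistical character of the full-size run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import TrainConfig, TrainedModel, build_network, enhance, train
from .phantom import Phantom, generate_phantom
from .projections import ProjectionSet, add_noise, forward_project
from .reconstruct import Volume, reconstruct

__all__ = ["benchmark_params", "BenchmarkParams", "simulate_clean", "train_for_level"]

FULL_SIZE = 512
FULL_SPHERES = 1000
FULL_ANGLES = 721
TRAIN_ANGLES_DEG = (0.0, 45.0)
NOISE_LEVELS = (0.05, 0.10, 0.20, 0.30)


@dataclass(frozen=True)
class BenchmarkParams:
    size: int
    n_spheres: int
    n_angles: int
    d_min: float = 4.0
    d_max: float = 20.0
    filter_name: str = "parzen"


def benchmark_params(size: int = FULL_SIZE) -> BenchmarkParams:
    """Benchmark conditions at a given volume edge (density-preserving)."""
    frac = size / FULL_SIZE
    n_spheres = max(1, round(FULL_SPHERES * frac**3))
    n_angles = round((FULL_ANGLES - 1) * frac) + 1
    return BenchmarkParams(size=size, n_spheres=n_spheres, n_angles=n_angles)


def simulate_clean(
    params: BenchmarkParams, seed: int = 0
) -> tuple[Phantom, ProjectionSet, Volume]:
    """Phantom, clean projections P_o and their reconstruction R_o."""
    ph = generate_phantom(
        params.size, params.n_spheres, params.d_min, params.d_max, seed=seed
    )
    angles = np.linspace(0.0, 180.0, params.n_angles)
    p_o = forward_project(ph, angles)
    r_o = reconstruct(p_o, filter_name=params.filter_name)
    return ph, p_o, r_o


def noisy_set(p_o: ProjectionSet, level: float, seed: int) -> ProjectionSet:
    return add_noise(p_o, level, seed=seed)


def training_pairs(
    p_n: ProjectionSet, p_o: ProjectionSet, angles_deg=TRAIN_ANGLES_DEG
) -> list[tuple[np.ndarray, np.ndarray]]:
    """(short, long) image pairs at the benchmark's training angles."""
    pairs = []
    for a in angles_deg:
        i = int(np.argmin(np.abs(p_n.angles - a)))
        pairs.append((p_n.images[i], p_o.images[i]))
    return pairs


def train_for_level(
    p_n: ProjectionSet,
    p_o: ProjectionSet,
    patch_edge: int = 64,
    epochs: int = 40,
    stride: int = 16,
    seed: int = 0,
) -> TrainedModel:
    """Train one enhancement model on the 0/45-degree pairs of one level."""
    model = build_network(patch_edge=patch_edge, seed=seed)
    cfg = TrainConfig(epochs=epochs, stride=stride, seed=seed)
    return train(model, training_pairs(p_n, p_o), cfg)


def enhanced_reconstruction(
    model: TrainedModel, p_n: ProjectionSet, filter_name: str = "parzen"
) -> tuple[ProjectionSet, Volume]:
    p_e = enhance(model, p_n)
    return p_e, reconstruct(p_e, filter_name=filter_name)
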