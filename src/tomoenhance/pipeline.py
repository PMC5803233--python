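"""End-to-end synthetic experiment: simulate -> train -> enhance ->
reconstruct -> evaluate, with a reproducibility manifest."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .baselines import BaselineConfig, denoise_stack
from .benchmark import BenchmarkParams, benchmark_params, training_pairs
from .io import write_stack, write_volume
from .metrics import histogram_modes, volume_report
from .model import TrainConfig, build_network, enhance, save_model, train
from .phantom import generate_phantom
from .projections import add_noise, forward_project
from .reconstruct import reconstruct

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("tomoenhance")


@dataclass
class RunConfig:
    """Full description of one synthetic experiment."""

    name: str = "synthetic"
    size: int = 128
    n_spheres: int | None = None  # default: density-scaled from the 512^3 benchmark
    n_angles: int | None = None  # default: angle density of the 721-angle benchmark
    d_min: float = 4.0
    d_max: float = 20.0
    noise_levels: tuple = (0.05, 0.10, 0.20, 0.30)
    train_angles: tuple = (0.0, 45.0)
    patch_edge: int = 32
    train_stride: int = 8
    epochs: int = 20
    batch_size: int = 16
    learning_rate: float = 1e-3
    filter_name: str = "parzen"
    baselines: tuple = ()  # e.g. ("median", "tv")
    seed: int = 0
    out_dir: str = "runs/synthetic"
    save_stacks: bool = False  # write P/R stacks as TIFF (large)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**known)
        for tup in ("noise_levels", "train_angles", "baselines"):
            setattr(cfg, tup, tuple(getattr(cfg, tup)))
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f, sort_keys=False)

    def resolved_params(self) -> BenchmarkParams:
        base = benchmark_params(self.size)
        return BenchmarkParams(
            size=self.size,
            n_spheres=self.n_spheres if self.n_spheres is not None else base.n_spheres,
            n_angles=self.n_angles if self.n_angles is not None else base.n_angles,
            d_min=self.d_min,
            d_max=self.d_max,
            filter_name=self.filter_name,
        )


def _seeds(master: int) -> dict[str, int]:
    ss = np.random.SeedSequence(master)
    names = ("phantom", "noise", "init", "shuffle")
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def run_pipeline(config: RunConfig) -> Path:
    """Run the full synthetic experiment described by ``config``.

    Writes quality reports, training logs, optional stacks/volumes and a
    manifest (seeds, versions, timings, outputs) to the output directory and
    returns that directory.  Any stage failure is re-raised with the stage
    name after the manifest written so far is persisted.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.resolved_params()
    seeds = _seeds(config.seed)
    manifest: dict = {
        "name": config.name,
        "version": __version__,
        "config": asdict(config),
        "resolved_params": asdict(params),
        "seeds": seeds,
        "stages": {},
        "outputs": {},
        "reports": {},
    }
    config.to_yaml(out / "config.yaml")

    def _stage(name):
        def deco(fn):
            t0 = time.time()
            log.info("stage %s ...", name)
            try:
                fn()
            except Exception as exc:
                manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                _write_manifest(out, manifest)
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = {
                "status": "ok",
                "wall_s": round(time.time() - t0, 2),
            }

        return deco

    state: dict = {}

    @_stage("simulate")
    def _():
        ph = generate_phantom(
            params.size, params.n_spheres, params.d_min, params.d_max,
            seed=seeds["phantom"],
        )
        angles = np.linspace(0.0, 180.0, params.n_angles)
        state["p_o"] = forward_project(ph, angles)
        state["r_o"] = reconstruct(state["p_o"], params.filter_name)
        if config.save_stacks:
            manifest["outputs"]["P_o"] = str(write_stack(state["p_o"], out / "P_o.tif"))
            manifest["outputs"]["R_o"] = str(write_volume(state["r_o"], out / "R_o.tif"))

    for level in config.noise_levels:
        tag = f"{int(round(level * 100)):02d}"

        @_stage(f"noise_{tag}")
        def _(level=level, tag=tag):
            state["p_n"] = add_noise(state["p_o"], level, seed=seeds["noise"])
            state["r_n"] = reconstruct(state["p_n"], params.filter_name)
            if config.save_stacks:
                manifest["outputs"][f"P_n{tag}"] = str(
                    write_stack(state["p_n"], out / f"P_n{tag}.tif")
                )
                manifest["outputs"][f"R_n{tag}"] = str(
                    write_volume(state["r_n"], out / f"R_n{tag}.tif")
                )

        @_stage(f"train_{tag}")
        def _(level=level, tag=tag):
            model = build_network(patch_edge=config.patch_edge, seed=seeds["init"])
            cfg = TrainConfig(
                epochs=config.epochs,
                batch_size=config.batch_size,
                learning_rate=config.learning_rate,
                stride=config.train_stride,
                seed=seeds["shuffle"],
            )
            train(model, training_pairs(state["p_n"], state["p_o"], config.train_angles), cfg)
            state["model"] = model
            (out / f"training_log_{tag}.json").write_text(
                json.dumps(model.training_log, indent=1)
            )
            save_model(model, out / f"model_{tag}.npz")
            manifest["outputs"][f"model_{tag}"] = str(out / f"model_{tag}.npz")

        @_stage(f"enhance_{tag}")
        def _(level=level, tag=tag):
            state["p_e"] = enhance(state["model"], state["p_n"])
            state["r_e"] = reconstruct(state["p_e"], params.filter_name)
            if config.save_stacks:
                manifest["outputs"][f"P_e{tag}"] = str(
                    write_stack(state["p_e"], out / f"P_e{tag}.tif")
                )
                manifest["outputs"][f"R_e{tag}"] = str(
                    write_volume(state["r_e"], out / f"R_e{tag}.tif")
                )

        @_stage(f"evaluate_{tag}")
        def _(level=level, tag=tag):
            rep = {
                "noise_level": level,
                "R_n_vs_R_o": volume_report(state["r_n"], state["r_o"]).as_dict(),
                "R_e_vs_R_o": volume_report(state["r_e"], state["r_o"]).as_dict(),
                "modes_R_n": histogram_modes(state["r_n"])[2],
                "modes_R_e": histogram_modes(state["r_e"])[2],
            }
            for method in config.baselines:
                p_b = denoise_stack(state["p_n"], BaselineConfig(method=method))
                r_b = reconstruct(p_b, params.filter_name)
                rep[f"R_{method}_vs_R_o"] = volume_report(r_b, state["r_o"]).as_dict()
            manifest["reports"][tag] = rep
            (out / f"report_{tag}.json").write_text(json.dumps(rep, indent=1))

    _write_manifest(out, manifest)
    return out


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
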