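"""End-to-end pipeline: simulate -> train -> denoise -> unmix -> evaluate.

A single :class:`RunConfig` drives every stage.  One global seed spawns
independent per-stage substreams, every artifact is written with a
provenance sidecar (stage, seed, config hash), and a ``manifest.json``
records enough to re-execute the run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import io as srsio
from .metrics import evaluate_pair, snr_measure
from .simulate import (
    HyperspectralStack,
    build_phantom,
    default_library,
    fingerprint_axis,
    make_pair,
    random_cell_scene,
    render_clean_stack,
)
from .ssresnet import DenoiserConfig, denoise, save_model, train_denoiser
from .unmix import UnmixConfig, unmix_stack

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full synthetic pipeline run."""

    seed: int = 0
    scene_shape: tuple[int, int] = (64, 64)
    n_cells: int = 3
    morphology: str = "cells"
    baseline_amplitude: float = 0.0
    library_names: tuple[str, ...] = ("bsa", "triglyceride", "cholesterol")
    n_channels: int = 32
    target_snr: float = 1.4
    n_avg: int = 100
    n_train_pairs: int = 4
    denoiser: DenoiserConfig = field(
        default_factory=lambda: DenoiserConfig(
            n_levels=2, blocks_per_level=2, base_channels=8,
            learning_rate=1e-3, batch_size=2, n_epochs=10, steps_per_epoch=8,
            patch_shape=(16, 32, 32),
        )
    )
    unmix: UnmixConfig = field(default_factory=lambda: UnmixConfig(beta=1e-3, nonnegative=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "denoiser" in d:
            dn = dict(d["denoiser"])
            if "patch_shape" in dn:
                dn["patch_shape"] = tuple(dn["patch_shape"])
            d["denoiser"] = DenoiserConfig(**dn)
        if "unmix" in d:
            d["unmix"] = UnmixConfig(**d["unmix"])
        for key in ("scene_shape", "library_names"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _provenance(config: RunConfig, stage: str, seed: int) -> dict:
    return {"stage": stage, "seed": seed, "config_hash": config.config_hash()}


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all stages, write artifacts under ``out_dir``, return the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
        "stages": {},
    }
    stage_seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ("simulate", "train", "denoise", "unmix", "evaluate"),
            np.random.SeedSequence(config.seed).spawn(5),
        )
    }

    # ----- simulate -------------------------------------------------------
    stage = "simulate"
    try:
        seed = stage_seeds[stage]
        rng = np.random.default_rng(seed)
        axis = fingerprint_axis(config.n_channels)
        library = default_library(config.library_names, axis)
        library.to_csv(out / "library.csv")

        def _scene_pair(pair_seed: int):
            scene = random_cell_scene(
                config.scene_shape, library.n_components, rng,
                n_cells=config.n_cells, morphology=config.morphology,
                baseline_amplitude=config.baseline_amplitude,
            )
            maps = build_phantom(scene, library.n_components)
            clean = render_clean_stack(maps, library, scene.baseline_amplitude)
            mask = maps.sum(axis=2) > 0
            return clean, mask, make_pair(
                clean, config.n_avg, config.target_snr, pair_seed, mask,
            )

        pair_seeds = [int(rng.integers(2**31)) for _ in range(config.n_train_pairs + 1)]
        train_pairs = []
        for ps in pair_seeds[:-1]:
            _, _, pair = _scene_pair(ps)
            train_pairs.append(pair)
        val_clean, val_mask, val_pair = _scene_pair(pair_seeds[-1])

        srsio.write_stack(val_pair.raw, out / "validation_raw.tif",
                          _provenance(config, stage, seed))
        srsio.write_stack(val_pair.ground_truth, out / "validation_gt.tif",
                          _provenance(config, stage, seed))
        manifest["stages"][stage] = {
            "seed": seed,
            "outputs": ["library.csv", "validation_raw.tif", "validation_gt.tif"],
        }
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ----- train ----------------------------------------------------------
    stage = "train"
    try:
        seed = stage_seeds[stage]
        dn_cfg = DenoiserConfig(**{**asdict(config.denoiser), "seed": seed,
                                   "patch_shape": config.denoiser.patch_shape})
        model = train_denoiser(train_pairs, dn_cfg)
        save_model(model, out / "model.npz")
        manifest["stages"][stage] = {
            "seed": seed,
            "outputs": ["model.npz"],
            "final_loss": model.training_history[-1],
        }
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ----- denoise --------------------------------------------------------
    stage = "denoise"
    try:
        seed = stage_seeds[stage]
        denoised = denoise(val_pair.raw, model)
        srsio.write_stack(denoised, out / "denoised.tif", _provenance(config, stage, seed))
        manifest["stages"][stage] = {"seed": seed, "outputs": ["denoised.tif"]}
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ----- unmix ----------------------------------------------------------
    stage = "unmix"
    try:
        seed = stage_seeds[stage]
        maps = unmix_stack(denoised, library, config.unmix)
        outputs = []
        for k, name in enumerate(maps.names):
            comp = HyperspectralStack(
                data=maps.maps[None, :, :, k].astype(np.float32),
                axis=fingerprint_axis(1, 0.0, 1.0),
            )
            fname = f"concentration_{name}.tif"
            srsio.write_stack(comp, out / fname, _provenance(config, stage, seed))
            outputs.append(fname)
        manifest["stages"][stage] = {"seed": seed, "outputs": outputs}
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ----- evaluate -------------------------------------------------------
    stage = "evaluate"
    try:
        seed = stage_seeds[stage]
        gt = val_pair.ground_truth.data
        report = {
            "raw_vs_gt": evaluate_pair(val_pair.raw.data, gt).to_dict(),
            "denoised_vs_gt": evaluate_pair(denoised.data, gt).to_dict(),
            "raw_snr": snr_measure(
                val_pair.raw.data, val_pair.raw.n_channels // 2,
                val_mask, ~val_mask,
            ),
            "denoised_snr": snr_measure(
                denoised.data, denoised.n_channels // 2, val_mask, ~val_mask,
            ),
        }
        report["provenance"] = _provenance(config, stage, seed)
        (out / "metrics.json").write_text(json.dumps(report, indent=2))
        manifest["stages"][stage] = {"seed": seed, "outputs": ["metrics.json"],
                                     "metrics": {k: v for k, v in report.items()
                                                 if k != "provenance"}}
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
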