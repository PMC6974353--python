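"""Configuration-driven orchestration of the paired-architecture experiment.

A pipeline run is described by a single YAML/dict config, validated
strictly (unknown keys are rejected, every random stage's seed is
recorded), executed stage by stage, and summarized in a JSON manifest with
SHA-256 checksums of every artifact so that a rerun with the same config
is verifiably identical for deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .errors import ConfigError
from .mie import fusion_series
from .phantom import ChromatinParams, generate_packed_nuclei
from .bpm import compare_models
from . import io as onlio

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

_STAGES = ("mie_series", "build_onl", "compare_models")

_SCHEMA: dict[str, dict] = {
    "stages": None,
    "output_dir": None,
    "seed": None,
    "log_level": None,
    "mie_series": {
        "d_fused_um", "d_sweep_um", "counts", "m_particle", "m_medium",
        "wavelength_nm", "n_medium_abs", "volume_fraction", "apply_packing_correction",
    },
    "build_onl": {
        "n_nuclei", "domain_shape", "voxel_size_um", "radius_mean_um", "radius_sd_um",
    },
    "chromatin": {
        "n1", "n2", "n0", "n_cc_min", "n_cc_max", "smoothing_sigma",
    },
    "compare_models": {"theta_min_deg", "n_cc_override", "wavelength_nm"},
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    stages: list[str]
    output_dir: str
    seed: int = 0
    log_level: str = "INFO"
    mie_series: dict = field(default_factory=dict)
    build_onl: dict = field(default_factory=dict)
    chromatin: dict = field(default_factory=dict)
    compare_models: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - set(_SCHEMA)
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        if "stages" not in raw or not raw["stages"]:
            raise ConfigError("missing required field: stages")
        if "output_dir" not in raw:
            raise ConfigError("missing required field: output_dir")
        for stage in raw["stages"]:
            if stage not in _STAGES:
                raise ConfigError(f"unknown stage '{stage}'; valid stages: {_STAGES}")
        for section, allowed in _SCHEMA.items():
            if allowed is None or section not in raw:
                continue
            bad = set(raw[section]) - allowed
            if bad:
                raise ConfigError(f"unknown key(s) in '{section}': {sorted(bad)}")
        if "compare_models" in raw.get("stages", []) and "build_onl" not in raw["stages"]:
            raise ConfigError("stage 'compare_models' requires stage 'build_onl'")
        return cls(
            stages=list(raw["stages"]),
            output_dir=str(raw["output_dir"]),
            seed=int(raw.get("seed", 0)),
            log_level=str(raw.get("log_level", "INFO")),
            mie_series=dict(raw.get("mie_series", {})),
            build_onl=dict(raw.get("build_onl", {})),
            chromatin=dict(raw.get("chromatin", {})),
            compare_models=dict(raw.get("compare_models", {})),
        )

    def to_dict(self) -> dict:
        return {
            "stages": self.stages,
            "output_dir": self.output_dir,
            "seed": self.seed,
            "log_level": self.log_level,
            "mie_series": self.mie_series,
            "build_onl": self.build_onl,
            "chromatin": self.chromatin,
            "compare_models": self.compare_models,
        }


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} did not parse to a mapping")
    return PipelineConfig.from_dict(raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _chromatin_params(cfg: PipelineConfig) -> ChromatinParams:
    c = cfg.chromatin
    return ChromatinParams(
        n1=float(c.get("n1", 1.357)),
        n2=float(c.get("n2", 1.382)),
        n0=float(c.get("n0", 1.33)),
        n_cc_range=(int(c.get("n_cc_min", 8)), int(c.get("n_cc_max", 12))),
        smoothing_sigma=float(c.get("smoothing_sigma", 2.0)),
    )


def run_pipeline(config: PipelineConfig, resume: bool = False) -> dict:
    """Execute the configured stages and return the artifact manifest.

    Inputs are never mutated; all randomness flows from ``config.seed``.
    With ``resume=True``, stages whose artifacts already exist with
    matching checksums in a previous manifest are skipped.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    previous = {}
    if resume and manifest_path.exists():
        previous = json.loads(manifest_path.read_text()).get("stages", {})

    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "stages": {},
    }
    labels = None

    for stage in config.stages:
        artifacts: dict[str, str] = {}
        if resume and stage in previous and _artifacts_intact(previous[stage], outdir):
            manifest["stages"][stage] = {**previous[stage], "status": "skipped (resume)"}
            if stage == "build_onl":
                labels = onlio.read_labeled_volume(outdir / "labels.tif")
            continue

        if stage == "mie_series":
            p = config.mie_series
            counts = list(p.get("counts", [1, 2, 4, 8, 12]))
            sweep = p.get("d_sweep_um")
            diameters = (
                list(np.linspace(*sweep)) if sweep else [float(p.get("d_fused_um", 2.0))]
            )
            frames = []
            for d in diameters:
                frames.append(
                    fusion_series(
                        d,
                        counts,
                        m_particle=float(p.get("m_particle", 1.04)),
                        m_medium=float(p.get("m_medium", 1.02)),
                        wavelength_nm=float(p.get("wavelength_nm", 500.0)),
                        n_medium_abs=p.get("n_medium_abs", 1.357),
                        volume_fraction=float(p.get("volume_fraction", 0.3351)),
                        apply_packing_correction=bool(p.get("apply_packing_correction", False)),
                    ).to_dataframe()
                )
            import pandas as pd

            path = outdir / "mie_series.csv"
            pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")
            artifacts["mie_series.csv"] = _sha256(path)

        elif stage == "build_onl":
            p = config.build_onl
            labels = generate_packed_nuclei(
                n_nuclei=int(p.get("n_nuclei", 40)),
                domain_shape=tuple(p.get("domain_shape", (128, 256, 256))),
                voxel_size_um=float(p.get("voxel_size_um", 0.166)),
                radius_um=(float(p.get("radius_mean_um", 2.8)), float(p.get("radius_sd_um", 0.3))),
                seed=config.seed,
            )
            path = outdir / "labels.tif"
            onlio.write_labeled_volume(labels, path)
            artifacts["labels.tif"] = _sha256(path)

        elif stage == "compare_models":
            p = config.compare_models
            report = compare_models(
                labels,
                _chromatin_params(config),
                seed=config.seed,
                wavelength_nm=float(p.get("wavelength_nm", 500.0)),
                theta_min_deg=float(p.get("theta_min_deg", 30.0)),
                n_cc_override=p.get("n_cc_override"),
            )
            path = outdir / "compare_models.json"
            onlio.write_metrics_json(report.to_dict(), path)
            artifacts["compare_models.json"] = _sha256(path)

        manifest["stages"][stage] = {"status": "completed", "artifacts": artifacts, "seed": config.seed}

    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def _artifacts_intact(stage_entry: dict, outdir: Path) -> bool:
    arts = stage_entry.get("artifacts", {})
    if not arts:
        return False
    for name, digest in arts.items():
        p = outdir / name
        if not p.exists() or _sha256(p) != digest:
            return False
    return True
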