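"""Config-driven pipeline runner.

A pipeline configuration (YAML/JSON) names an output directory, a seed,
optional physical-constant overrides, and an ordered list of stages.
Each stage writes its artifacts plus a JSON provenance record into the
run directory, so every output is reproducible from its record alone.

Supported stages:

``gen-cellular``    synthetic cellular iron map (CSV + sidecar)
``gen-ribbon``      synthetic cortical ribbon phantom (CSV maps + boundary)
``gen-surface``     synthetic per-vertex surface table (CSV)
``simulate-field``  iron map -> Larmor field -> fitted line shape
``fit-profiles``    cortical profiles + linear contrast model fit
``map-swm``         orientation GLM fit and corrected surface table
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .constants import PhysicalConstants
from .fieldsim import micro_relaxivity, simulate_line_width, soma_mask, masked_map
from .io import (
    read_quantitative_map,
    read_surface_table,
    write_field_nifti,
    write_line_shape,
    write_provenance,
    write_quantitative_map,
    write_surface_table,
)
from .profiles import (
    BoundaryPolyline,
    band_average,
    extract_profiles,
    fit_linear_contrast_model,
)
from .surface import correct_orientation, fit_orientation_glm

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("swmrelax")

_TOP_KEYS = {"out_dir", "seed", "constants", "stages", "log_level"}
_STAGES = {
    "gen-cellular", "gen-ribbon", "gen-surface",
    "simulate-field", "fit-profiles", "map-swm",
}


@dataclasses.dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    out_dir: Path
    stages: list
    seed: int = 0
    constants: PhysicalConstants = dataclasses.field(default_factory=PhysicalConstants)
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        unknown = set(data) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown pipeline config key(s): {sorted(unknown)}")
        if "out_dir" not in data or "stages" not in data:
            raise ValueError("pipeline config needs 'out_dir' and 'stages'")
        stages = data["stages"]
        for stage in stages:
            if set(stage) - {"name", "params"}:
                raise ValueError(
                    f"stage entries allow only 'name' and 'params': {stage}"
                )
            if stage.get("name") not in _STAGES:
                raise ValueError(
                    f"unknown stage {stage.get('name')!r}; known: {sorted(_STAGES)}"
                )
        constants = PhysicalConstants.from_dict(data.get("constants", {}))
        return cls(
            out_dir=Path(data["out_dir"]),
            stages=stages,
            seed=int(data.get("seed", 0)),
            constants=constants,
            log_level=str(data.get("log_level", "INFO")),
        )

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        data = yaml.safe_load(path.read_text())
        return cls.from_dict(data or {})


def _require_inputs(params: dict, keys) -> None:
    for key in keys:
        if key in params:
            p = Path(params[key])
            if not p.exists():
                raise FileNotFoundError(f"input file not found: {p}")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages in order; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    logger.info("pipeline start: %d stage(s), seed=%d", len(config.stages), config.seed)
    (out / "effective_config.json").write_text(json.dumps({
        "out_dir": str(out),
        "seed": config.seed,
        "constants": config.constants.to_dict(),
        "stages": config.stages,
    }, indent=2))

    # validate all declared file inputs before any computation
    for stage in config.stages:
        _require_inputs(stage.get("params", {}), (
            "iron_map", "r2s_map", "iron", "myelin", "boundary", "table",
        ))

    artifacts: dict = {}
    for stage in config.stages:
        name = stage["name"]
        params = dict(stage.get("params", {}))
        try:
            _run_stage(name, params, config, out, artifacts)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        logger.info("stage %s done", name)
    return out


def _load_boundary(spec, artifacts) -> BoundaryPolyline:
    if isinstance(spec, BoundaryPolyline):
        return spec
    if isinstance(spec, str) and spec in artifacts:
        return artifacts[spec]
    points = np.loadtxt(spec, delimiter=",", ndmin=2)
    return BoundaryPolyline(points)


def _run_stage(name, params, config, out, artifacts) -> None:
    constants = config.constants
    seed = int(params.pop("seed", config.seed))

    if name == "gen-cellular":
        cfg = synthetic.CellularSceneConfig(**params, seed=seed)
        iron, truth = synthetic.gen_cellular_iron_map(cfg)
        path = write_quantitative_map(
            out / "cellular_iron.csv", iron.values, iron.pixel_size,
            "ug/g", iron.section_thickness,
        )
        artifacts["cellular_iron"] = iron
        artifacts["cellular_truth"] = truth
        write_provenance(out / "cellular_iron.provenance.json",
                         stage=name, parameters=dataclasses.asdict(cfg), seed=seed)

    elif name == "gen-ribbon":
        cfg = synthetic.RibbonPhantomConfig(**params, seed=seed)
        phantom = synthetic.gen_ribbon_phantom(cfg)
        for key, units in (("iron", "ug/g"), ("myelin", "fraction"), ("r2s", "s^-1")):
            write_quantitative_map(out / f"ribbon_{key}.csv", phantom[key],
                                   (1.0, 1.0), units)
        np.savetxt(out / "ribbon_boundary.csv", phantom["boundary"].points,
                   delimiter=",")
        artifacts["ribbon"] = phantom
        write_provenance(out / "ribbon.provenance.json",
                         stage=name, parameters=dataclasses.asdict(cfg), seed=seed)

    elif name == "gen-surface":
        cfg = synthetic.SurfaceTableConfig(**params, seed=seed)
        table, truth = synthetic.gen_surface_table(cfg)
        write_surface_table(out / "surface_table.csv", table)
        artifacts["surface_table"] = table
        artifacts["surface_truth"] = truth
        write_provenance(out / "surface_table.provenance.json",
                         stage=name, parameters=dataclasses.asdict(cfg), seed=seed)

    elif name == "simulate-field":
        threshold = params.pop("threshold", None)
        b0 = params.pop("b0_direction", "z")
        if "iron_map" in params:
            iron = read_quantitative_map(params.pop("iron_map"), "ug/g").as_iron_map()
        elif "cellular_iron" in artifacts:
            iron = artifacts["cellular_iron"]
        else:
            raise ValueError("simulate-field needs an iron_map input or a "
                             "preceding gen-cellular stage")
        if threshold is not None:
            iron = masked_map(iron, soma_mask(iron, threshold))
        shape = simulate_line_width(iron, b0, constants, **params)
        write_line_shape(out / "line_shape", shape)
        mean_c = float(iron.values.mean())
        summary = {
            "fwhm_rad_s": shape.fwhm,
            "model": shape.model,
            "mean_c_fe": mean_c,
            "micro_relaxivity": micro_relaxivity(shape.fwhm, mean_c)
            if mean_c > 0 else None,
        }
        (out / "field_summary.json").write_text(json.dumps(summary, indent=2))
        artifacts["line_shape"] = shape
        write_provenance(out / "line_shape.provenance.json", stage=name,
                         parameters={"threshold": threshold, "b0": str(b0)},
                         constants=constants.to_dict(), seed=seed)

    elif name == "fit-profiles":
        if "ribbon" in artifacts:
            phantom = artifacts["ribbon"]
            maps = {k: phantom[k] for k in ("r2s", "iron", "myelin")}
            boundary = phantom["boundary"]
            depth = params.pop("cortical_depth", phantom["cortical_depth"])
        else:
            maps = {
                "r2s": read_quantitative_map(params.pop("r2s_map"), "s^-1").values,
                "iron": read_quantitative_map(params.pop("iron"), "ug/g").values,
                "myelin": read_quantitative_map(params.pop("myelin"), "fraction").values,
            }
            boundary = _load_boundary(params.pop("boundary"), artifacts)
            depth = params.pop("cortical_depth")
        prof = {k: extract_profiles(v, boundary, depth, **params)
                for k, v in maps.items()}
        fit = fit_linear_contrast_model(
            prof["r2s"].mean, prof["iron"].mean, prof["myelin"].mean
        )
        bands = {b: dict(zip(("mean", "sd"), band_average(prof["iron"], b)))
                 for b in ("cortex-upper", "cortex-middle", "swm", "dwm")}
        result = {
            "coefficients": {
                "iron_relaxivity": fit.iron_relaxivity,
                "myelin_coefficient": fit.myelin_coefficient,
                "offset": fit.offset,
            },
            "stderr": fit.stderr,
            "variance_explained": fit.variance_explained,
            "variance_explained_reduced": fit.variance_explained_reduced,
            "iron_band_averages": bands,
        }
        (out / "contrast_fit.json").write_text(json.dumps(result, indent=2))
        depth_df = pd.DataFrame({
            "depth": prof["r2s"].depth,
            **{f"{k}_mean": p.mean for k, p in prof.items()},
            **{f"{k}_se": p.se for k, p in prof.items()},
        })
        depth_df.to_csv(out / "profiles.csv", index=False)
        artifacts["contrast_fit"] = fit
        write_provenance(out / "contrast_fit.provenance.json", stage=name,
                         parameters={"cortical_depth": depth}, seed=seed)

    elif name == "map-swm":
        if "table" in params:
            table = read_surface_table(params.pop("table"))
        elif "surface_table" in artifacts:
            table = artifacts["surface_table"]
        else:
            raise ValueError("map-swm needs a table input or a preceding "
                             "gen-surface stage")
        fit = fit_orientation_glm(table, **params)
        corrected = correct_orientation(table, fit)
        write_surface_table(out / "corrected_surface.csv", corrected)
        result = {
            "beta0": fit.beta0, "beta1": fit.beta1, "beta2": fit.beta2,
            "stderr": fit.stderr,
            "orientation_variance_fraction": fit.orientation_variance_fraction,
            "condition_number": fit.condition_number,
        }
        (out / "glm_fit.json").write_text(json.dumps(result, indent=2))
        artifacts["glm_fit"] = fit
        write_provenance(out / "glm_fit.provenance.json", stage=name, seed=seed)
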