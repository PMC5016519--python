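"""End-to-end orchestration: config, stages, and a reproducibility manifest.

The pipeline chains the analysis stages -- obtain localizations (load or
simulate), sliding-window density, blink calibration on a diluted
reference, molecular density, Ripley's h versus CSR and Neyman-Scott
nulls -- writing CSV/JSON artifacts plus a manifest (seeds, versions,
config hash) sufficient to re-run the bundle.

Configuration is a nested YAML document.  Every stochastic stage has an
explicit seed; defaults are the standard protocol values (1 um / 100 nm
window, 1-160 nm radius sweep, 50 nm plateau, m = 500 test points,
offspring mean 5, sigma 8 nm, 5x5 um^2 region).  Unknown keys are
rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import LocalizationTable, Region, read_localizations, write_localizations
from .simulate import (NeymanScottParams, simulate_csr, simulate_neyman_scott,
                       simulate_blinking_scene, simulate_double_membrane,
                       simulate_vesicle_field, DEFAULT_N_FRAMES)
from .density import sliding_window_density, summarize_density, DensitySummary
from .calibration import BlinkCalibrationModel, BlinkCalibrationResults
from .ripley import (RipleyModel, RipleyResults, null_envelopes, RipleyEnvelope,
                     ComparisonReport)

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "validate_config", "load_config", "save_config",
           "run_pipeline", "PipelineError", "ReportBundle", "DEFAULT_CONFIG"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


#: fully-defaulted configuration (the standard protocol parameters)
DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 1,
    "output_dir": "locquant_out",
    "region": {"x_min": 0.0, "x_max": 5000.0, "y_min": 0.0, "y_max": 5000.0},
    "input": {
        # either a list of localization files ...
        "paths": [],
        "dialect": "generic_csv",
        # ... or a simulation spec used when 'paths' is empty
        "simulation": {
            "kind": "csr",  # csr | neyman_scott | blinking | double_membrane | vesicles
            "intensity": 1000.0,  # loc/um^2 (csr, double_membrane background ...)
            "fluorophore_density": 2.0,  # per um^2 (blinking)
            "blink_mean": 5.0,
            "precision_sigma": 8.0,  # nm
            "n_frames": DEFAULT_N_FRAMES,
            "vesicle_count": 10,
            "vesicle_radius": 100.0,  # nm
            "vesicle_loc_count": 200,
            "n_replicates": 5,  # independent regions for the Ripley stage
        },
    },
    "reference": {
        # diluted reference sample for the blink calibration
        "paths": [],
        "dialect": "generic_csv",
        "simulation": {
            "fluorophore_density": 2.0,
            "blink_mean": 5.0,
            "precision_sigma": 8.0,
            "n_frames": DEFAULT_N_FRAMES,
            "n_scenes": 16,
        },
    },
    "density": {"diameter": 1000.0, "step": 100.0},
    "calibration": {
        "radius_min": 1.0, "radius_max": 160.0, "radius_step": 1.0,
        "plateau_radius": 50.0, "min_track_length": 3,
    },
    "ripley": {
        "d_min": 10.0, "d_max": 800.0, "d_step": 10.0,
        "m": 500, "guard_buffer": False,
        "null_replicates": 5,
        "offspring_mean": 5.0, "offspring_sigma": 8.0,
    },
}


def _merge_defaults(defaults: dict, given: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in given.items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ValueError(f"unknown configuration key: {where!r}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise ValueError(f"configuration key {where!r} must be a mapping")
            out[key] = _merge_defaults(defaults[key], value, where)
        else:
            out[key] = value
    return out


@dataclass
class AnalysisConfig:
    """Validated, fully-defaulted pipeline configuration."""

    settings: dict[str, Any]

    def __getitem__(self, key: str) -> Any:
        return self.settings[key]

    @property
    def seed(self) -> int:
        return int(self.settings["seed"])

    def region(self) -> Region:
        r = self.settings["region"]
        return Region(r["x_min"], r["x_max"], r["y_min"], r["y_max"])

    def config_hash(self) -> str:
        canonical = yaml.safe_dump(self.settings, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.settings, sort_keys=True)


def validate_config(source) -> AnalysisConfig:
    """Resolve a config file/dict against the defaults and sanity-check it.

    ``source`` may be a path to a YAML file, a YAML string already read,
    a dict, or None/empty (pure defaults).  Unknown keys raise with the
    offending key path; a negative seed is a schema error.
    """
    if source is None:
        given: dict = {}
    elif isinstance(source, dict):
        given = source
    else:
        p = Path(source)
        if p.exists():
            text = p.read_text()
        else:
            text = str(source)
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError("configuration root must be a mapping")
        given = loaded
    settings = _merge_defaults(DEFAULT_CONFIG, given)
    seed = settings["seed"]
    if not isinstance(seed, (int, np.integer)) or isinstance(seed, bool) or seed < 0:
        raise ValueError("key 'seed' must be a non-negative integer")
    for key in ("diameter", "step"):
        if settings["density"][key] <= 0:
            raise ValueError(f"key 'density.{key}' must be > 0")
    if settings["ripley"]["d_min"] <= 0 or settings["ripley"]["d_max"] <= settings["ripley"]["d_min"]:
        raise ValueError("keys 'ripley.d_min'/'ripley.d_max' must satisfy 0 < d_min < d_max")
    cfg = AnalysisConfig(settings)
    cfg.region()  # validates the region block
    return cfg


def load_config(path) -> AnalysisConfig:
    return validate_config(path)


def save_config(config: AnalysisConfig, path) -> None:
    Path(path).write_text(config.to_yaml())


# ---------------------------------------------------------------------------
# running


@dataclass
class ReportBundle:
    """In-memory results of a pipeline run plus where they were written."""

    output_dir: Path
    density_summary: DensitySummary
    calibration: BlinkCalibrationResults
    molecular_density_row: dict
    ripley: RipleyResults
    csr_null: RipleyEnvelope
    ns_null: RipleyEnvelope
    comparison: ComparisonReport
    manifest: dict


def _obtain_tables(cfg: AnalysisConfig, rng: np.random.Generator) -> list[LocalizationTable]:
    block = cfg["input"]
    region = cfg.region()
    if block["paths"]:
        return [read_localizations(p, block["dialect"]) for p in block["paths"]]
    sim = block["simulation"]
    kind = sim["kind"]
    tables = []
    for _ in range(int(sim["n_replicates"])):
        if kind == "csr":
            tables.append(simulate_csr(sim["intensity"], region, rng, sim["n_frames"]))
        elif kind == "neyman_scott":
            params = NeymanScottParams.from_localization_density(
                sim["intensity"], sim["blink_mean"], sim["precision_sigma"])
            tables.append(simulate_neyman_scott(params, region, rng)[0])
        elif kind == "blinking":
            tables.append(simulate_blinking_scene(
                sim["fluorophore_density"], sim["blink_mean"], sim["precision_sigma"],
                sim["n_frames"], region, rng)[0])
        elif kind == "double_membrane":
            tables.append(simulate_double_membrane(sim["intensity"], region, rng,
                                                   sim["n_frames"]))
        elif kind == "vesicles":
            tables.append(simulate_vesicle_field(
                sim["intensity"], sim["vesicle_count"], sim["vesicle_radius"],
                sim["vesicle_loc_count"], region, rng, sim["n_frames"]))
        else:
            raise ValueError(f"unknown simulation kind {kind!r}")
    return tables


def _obtain_reference(cfg: AnalysisConfig, rng: np.random.Generator) -> list[LocalizationTable]:
    block = cfg["reference"]
    if block["paths"]:
        return [read_localizations(p, block["dialect"]) for p in block["paths"]]
    sim = block["simulation"]
    region = cfg.region()
    return [simulate_blinking_scene(sim["fluorophore_density"], sim["blink_mean"],
                                    sim["precision_sigma"], sim["n_frames"],
                                    region, rng)[0]
            for _ in range(int(sim["n_scenes"]))]


def run_pipeline(config: AnalysisConfig) -> ReportBundle:
    """Run every stage, writing artifacts and a manifest to the output dir.

    Any stage failure raises :class:`PipelineError` naming the stage;
    artifacts already written are retained alongside a ``FAILED`` marker
    describing the stage and cause.
    """
    out = Path(config["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    region = config.region()
    stage = "setup"
    counts: dict[str, Any] = {}
    try:
        stage = "input"
        tables = _obtain_tables(config, rng)
        counts["localizations_per_region"] = [t.n for t in tables]
        for i, t in enumerate(tables):
            write_localizations(t, out / f"localizations_region{i}.csv")
        logger.info("input: %d region table(s), n = %s", len(tables),
                    counts["localizations_per_region"])

        stage = "density"
        dcfg = config["density"]
        dmap = sliding_window_density(tables[0], region, dcfg["diameter"], dcfg["step"])
        dsum = summarize_density(dmap)
        pd.DataFrame({
            "x_nm": np.repeat(dmap.x_centers, dmap.y_centers.size),
            "y_nm": np.tile(dmap.y_centers, dmap.x_centers.size),
            "density_per_um2": dmap.densities.T.ravel(),
        }).to_csv(out / "density_windows.csv", index=False)
        logger.info("density: %d windows, median %.1f loc/um^2",
                    dsum.n_windows, dsum.median)

        stage = "calibration"
        ccfg = config["calibration"]
        reference = _obtain_reference(config, rng)
        counts["reference_localizations"] = sum(t.n for t in reference)
        radii = np.arange(ccfg["radius_min"], ccfg["radius_max"] + ccfg["radius_step"] / 2,
                          ccfg["radius_step"])
        calib = BlinkCalibrationModel(reference, radii=radii,
                                      plateau_radius=ccfg["plateau_radius"],
                                      min_track_length=ccfg["min_track_length"]).fit()
        pd.DataFrame({
            "radius_nm": calib.curve.radii,
            "mean_track_length": calib.curve.mean_track_length,
            "se_track_length": calib.curve.se_track_length,
            "n_tracks": calib.curve.n_tracks,
        }).to_csv(out / "calibration_curve.csv", index=False)
        logger.info("calibration: conversion factor %.2f ± %.2f, sigma (%.2f, %.2f) nm",
                    calib.conversion_factor, calib.conversion_se,
                    calib.sigma_x, calib.sigma_y)

        stage = "molecular_density"
        md = calib.molecular_density(dsum.median, dsum.median_se)
        row = {
            "localization_density_per_um2": dsum.median,
            "localization_density_se": dsum.median_se,
            "conversion_factor": calib.conversion_factor,
            "conversion_se": calib.conversion_se,
            "molecular_density_per_um2": md.value,
            "molecular_density_rounded": md.rounded,
            "molecular_density_se": md.se,
            "sigma_x_nm": calib.sigma_x,
            "sigma_y_nm": calib.sigma_y,
        }
        (out / "molecular_density.json").write_text(json.dumps(row, indent=2))

        stage = "ripley"
        rcfg = config["ripley"]
        grid = np.arange(rcfg["d_min"], rcfg["d_max"] + rcfg["d_step"] / 2, rcfg["d_step"])
        rip = RipleyModel(tables, region, grid, rcfg["m"], rcfg["guard_buffer"]).fit(rng)
        env = rip.envelope
        pd.DataFrame({"d_nm": env.distances, "mean_h_nm": env.mean,
                      "lower95_nm": env.lower, "upper95_nm": env.upper,
                      }).to_csv(out / "ripley_observed.csv", index=False)

        stage = "nulls"
        csr_env, ns_env = null_envelopes(
            dsum.median, region, grid, rcfg["m"], rcfg["null_replicates"], rng,
            rcfg["offspring_mean"], rcfg["offspring_sigma"], rcfg["guard_buffer"])
        for name, e in (("csr", csr_env), ("neyman_scott", ns_env)):
            pd.DataFrame({"d_nm": e.distances, "mean_h_nm": e.mean,
                          "lower95_nm": e.lower, "upper95_nm": e.upper,
                          }).to_csv(out / f"ripley_null_{name}.csv", index=False)

        stage = "comparison"
        comparison = rip.compare_to(csr_env, ns_env)
        (out / "comparison.txt").write_text(comparison.summary() + "\n")

        stage = "manifest"
        manifest = {
            "locquant_version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "config": config.settings,
            "counts": counts,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        save_config(config, out / "config.resolved.yaml")
    except Exception as exc:  # noqa: BLE001 - stage attribution is the point
        (out / "FAILED").write_text(f"stage: {stage}\ncause: {exc}\n")
        raise PipelineError(stage, exc) from exc

    return ReportBundle(out, dsum, calib, row, rip, csr_env, ns_env, comparison, manifest)
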