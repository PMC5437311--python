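"""Reproducible multi-stage runs: config validation, execution, manifest.

A run is described by a YAML/dict config with one section per stage plus
top-level ``seed``, ``out_dir``, ``stages`` and ``log_level``.  Unknown
keys are rejected before any computation; every parameter is echoed into
the JSON manifest together with SHA-256 checksums of all tabular outputs,
so reruns with the same config and seed are bit-identical apart from the
timestamp.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import imaging, permde, synthetic_data, tracking

logger = logging.getLogger("sagakit")

KNOWN_STAGES = ("simulate_spheroid", "imaging", "simulate_tracks", "tracks",
                "simulate_expression", "permde", "demo")

_TOP_KEYS = {"seed", "out_dir", "stages", "log_level"} | set(KNOWN_STAGES)


class ConfigError(ValueError):
    pass


def _dataclass_from(cls, section: dict, *, inject: dict | None = None):
    """Build a dataclass from a config section, rejecting unknown keys."""
    section = dict(section or {})
    section.update(inject or {})
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - valid
    if unknown:
        raise ConfigError(f"{cls.__name__}: unknown keys {sorted(unknown)}")
    try:
        return cls(**section)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{cls.__name__}: {exc}") from exc


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    return cfg


def validate_config(config: dict) -> dict:
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")
    stages = config.get("stages", ["demo"])
    bad = [s for s in stages if s not in KNOWN_STAGES]
    if bad:
        raise ConfigError(f"unknown stages: {bad}")
    cfg = dict(config)
    cfg.setdefault("seed", 0)
    cfg.setdefault("out_dir", "sagakit_run")
    cfg.setdefault("stages", stages)
    for stage in stages:
        section = cfg.get(stage, {}) or {}
        if not isinstance(section, dict):
            raise ConfigError(f"stage section {stage!r} must be a mapping")
        # fail fast on malformed stage parameters before any computation
        if stage == "simulate_spheroid":
            section.setdefault("image_shape", (8, 6, 128, 128))
            section["image_shape"] = tuple(section["image_shape"])
            _dataclass_from(synthetic_data.SpheroidPhantomSpec, section,
                            inject={"seed": section.get("seed", cfg["seed"])})
        elif stage == "simulate_tracks":
            _dataclass_from(synthetic_data.TrackSimSpec, section,
                            inject={"seed": section.get("seed", cfg["seed"])})
        elif stage == "simulate_expression":
            _dataclass_from(synthetic_data.ExpressionSimSpec, section,
                            inject={"seed": section.get("seed", cfg["seed"])})
        elif stage == "imaging":
            params = {k: v for k, v in section.items() if k not in ("input", "pixel_size", "frame_interval")}
            _dataclass_from(imaging.SegmentationParams, params)
        elif stage == "permde":
            params = {k: v for k, v in section.items()
                      if k not in ("matrix", "design", "quantile", "log2_offset")}
            _dataclass_from(permde.PermParams, params,
                            inject={"seed": section.get("seed", cfg["seed"])})
        cfg[stage] = section
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict) -> dict:
    """Execute the configured stages and write a run manifest.

    Returns the manifest dict (also written to ``out_dir/manifest.json``).
    """
    cfg = validate_config(config)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, str(cfg.get("log_level", "INFO")).upper(),
                                      logging.INFO))
    seed = int(cfg["seed"])
    manifest: dict = {
        "version": _package_version(),
        "seed": seed,
        "stages": list(cfg["stages"]),
        "parameters": {s: _jsonable(cfg.get(s, {})) for s in cfg["stages"]},
        "outputs": {},
        "metrics": {},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    # fail fast: check declared input files before running anything
    for stage in cfg["stages"]:
        section = cfg.get(stage, {})
        for key in ("input", "matrix", "design"):
            path = section.get(key)
            if path is not None and not Path(path).exists():
                raise ConfigError(f"stage {stage!r}: input file {path} not found")

    state: dict = {}
    for stage in cfg["stages"]:
        logger.info("running stage %s with %s", stage, cfg.get(stage, {}))
        _run_stage(stage, cfg, out_dir, seed, state, manifest)

    for name, path in manifest["outputs"].items():
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(Path(path))}
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _run_stage(stage: str, cfg: dict, out_dir: Path, seed: int,
               state: dict, manifest: dict) -> None:
    section = cfg.get(stage, {}) or {}
    if stage == "demo":
        _demo(out_dir, seed, manifest)
        return
    if stage == "simulate_spheroid":
        spec = _dataclass_from(synthetic_data.SpheroidPhantomSpec, section,
                               inject={"seed": section.get("seed", seed)})
        stack, truth = synthetic_data.generate_spheroid_stack(spec)
        paths = synthetic_data.write_phantom(stack, truth, out_dir)
        state["stack"], state["truth"] = stack, truth
        manifest["outputs"].update({"phantom_stack": paths["stack"],
                                    "phantom_truth": paths["truth"]})
    elif stage == "imaging":
        if "input" in section:
            stack = synthetic_data.read_stack(section["input"])
        elif "stack" in state:
            stack = state["stack"]
        else:
            raise ConfigError("imaging stage needs an 'input' TIFF or a prior "
                              "simulate_spheroid stage")
        params = _dataclass_from(imaging.SegmentationParams,
                                 {k: v for k, v in section.items()
                                  if k not in ("input", "pixel_size", "frame_interval")})
        table = imaging.feature_timecourse(
            stack, params, pixel_size=section.get("pixel_size"),
            frame_interval=section.get("frame_interval"))
        path = out_dir / "features.csv"
        table.to_csv(path, index=False)
        state["features"] = table
        manifest["outputs"]["features"] = path
    elif stage == "simulate_tracks":
        spec = _dataclass_from(synthetic_data.TrackSimSpec, section,
                               inject={"seed": section.get("seed", seed)})
        ts = synthetic_data.generate_tracks(spec)
        paths = synthetic_data.write_tracks(ts, out_dir)
        state["trackset"] = ts
        manifest["outputs"].update({"tracks": paths["tracks"],
                                    "tracks_spec": paths["spec"]})
    elif stage == "tracks":
        if "input" in section:
            tracks = tracking.read_tracks_csv(section["input"],
                                              section.get("frame_interval", 10.0))
        elif "trackset" in state:
            ts = state["trackset"]
            tracks = tracking.tracks_from_frame(ts.tracks, ts.spec.frame_interval)
        else:
            raise ConfigError("tracks stage needs an 'input' CSV or a prior "
                              "simulate_tracks stage")
        events = None
        if "trackset" in state and state["trackset"].spec.detachment_frame is not None:
            events = {tr.track_id: state["trackset"].spec.detachment_frame
                      for tr in tracks}
        table = tracking.metrics_table(tracks, events)
        path = out_dir / "track_metrics.csv"
        table.to_csv(path, index=False)
        manifest["outputs"]["track_metrics"] = path
    elif stage == "simulate_expression":
        spec = _dataclass_from(synthetic_data.ExpressionSimSpec, section,
                               inject={"seed": section.get("seed", seed)})
        matrix, design, truth = synthetic_data.generate_expression(spec)
        paths = synthetic_data.write_expression(matrix, design, out_dir, truth=truth)
        state["matrix"], state["design"] = matrix, design
        manifest["outputs"].update({"expression": paths["matrix"],
                                    "design": paths["design"],
                                    "expression_truth": paths["truth"]})
    elif stage == "permde":
        if "matrix" in section:
            matrix = pd.read_csv(section["matrix"], sep="\t", index_col=0)
            design = pd.read_csv(section["design"])
        elif "matrix" in state:
            matrix, design = state["matrix"], state["design"]
        else:
            raise ConfigError("permde stage needs 'matrix'/'design' files or a "
                              "prior simulate_expression stage")
        if section.get("log2_offset") is not None:
            matrix = permde.log2_transform(matrix, section["log2_offset"])
        if section.get("quantile", False):
            matrix = permde.quantile_normalize(matrix)
        params = _dataclass_from(
            permde.PermParams,
            {k: v for k, v in section.items()
             if k not in ("matrix", "design", "quantile", "log2_offset")},
            inject={"seed": section.get("seed", seed)})
        result = permde.run_de(matrix, design, params)
        path = out_dir / "de_results.tsv"
        result.to_csv(path, sep="\t")
        (out_dir / "de_metadata.json").write_text(
            json.dumps(result.attrs, indent=2, sort_keys=True))
        manifest["outputs"]["de_results"] = path
        manifest["outputs"]["de_metadata"] = out_dir / "de_metadata.json"
        manifest["metrics"]["n_selected_leader"] = int(result.selected_leader.sum())
        manifest["metrics"]["n_selected_follower"] = int(result.selected_follower.sum())
    else:  # pragma: no cover - guarded by validate_config
        raise ConfigError(f"unknown stage {stage!r}")


def _demo(out_dir: Path, seed: int, manifest: dict) -> None:
    """Small end-to-end fixture run: phantom -> features vs truth deltas."""
    spec = synthetic_data.SpheroidPhantomSpec(
        image_shape=(6, 6, 128, 128), core_radius=14, n_branches=4,
        branch_growth_rate=6, branch_width=5, noise_sd=0.5, seed=seed)
    stack, truth = synthetic_data.generate_spheroid_stack(spec)
    table = imaging.feature_timecourse(stack)
    paths = synthetic_data.write_phantom(stack, truth, out_dir, stem="demo_phantom")
    feat_path = out_dir / "demo_features.csv"
    table.to_csv(feat_path, index=False)
    manifest["outputs"].update({"demo_phantom": paths["stack"],
                                "demo_truth": paths["truth"],
                                "demo_features": feat_path})
    manifest["metrics"]["demo_branch_count_max_abs_error"] = float(
        np.abs(table.branch_count.to_numpy() - truth.true_branch_count).max())
    manifest["metrics"]["demo_invasive_radius_max_abs_error"] = float(
        np.abs(table.invasive_radius.to_numpy() - truth.true_invasive_radius).max())


def _package_version() -> str:
    from . import __version__
    return __version__


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
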