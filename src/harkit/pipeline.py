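"""Config-driven pipeline chaining the processing stages.

Stages: generate -> preprocess -> calibrate -> angles -> features ->
resample -> select -> evaluate.  Each stage writes its artifact to the
output directory together with a manifest recording the configuration
echo, per-stage seeds and content hashes of the inputs, so a rerun
with the same config reproduces identical manifests.

Per-stage seeds are derived from the global seed and the stage name by
hashing, so stages consume independent, reproducible randomness.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from . import synthetic
from .calibration import calibrate_axes, correct_imu, estimate_attitudes, joint_angles
from .evaluation import sensor_combination_sweep
from .features import FeatureTable, extract_features, normalize_minmax
from .gfsfan import GAConfig, run_gfsfan
from .preprocess import PreprocessConfig, preprocess, segment
from .recording import read_recording, write_recording
from .resampling import build_ensemble

__all__ = ["run_pipeline", "stage_seed", "load_config"]

_KNOWN_STAGES = (
    "generate", "preprocess", "calibrate", "angles",
    "features", "resample", "select", "evaluate",
)
_GLOBAL_KEYS = {"seed", "output_dir", "stages", "input"}


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage substream seed below 2**31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    cfg = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    unknown = set(cfg) - _GLOBAL_KEYS - set(_KNOWN_STAGES)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict | str | Path, output_dir: str | Path | None = None) -> Path:
    """Execute the configured stages in order; returns the artifact dir."""
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    unknown = set(cfg) - _GLOBAL_KEYS - set(_KNOWN_STAGES)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    out = Path(output_dir or cfg.get("output_dir", "har_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    stages = cfg.get("stages") or [s for s in _KNOWN_STAGES if s in cfg]
    manifest: dict = {"seed": seed, "stages": [], "config": {
        k: v for k, v in cfg.items() if k not in ("stages",)
    }}

    rec = None
    table: FeatureTable | None = None
    if "input" in cfg:
        rec = read_recording(cfg["input"])

    for stage in stages:
        if stage not in _KNOWN_STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        params = dict(cfg.get(stage) or {})
        s_seed = stage_seed(seed, stage)
        entry = {"stage": stage, "seed": s_seed}
        try:
            if stage == "generate":
                kind = params.pop("kind", "rigid_body")
                if kind == "rigid_body":
                    amp = float(params.pop("amplitude_deg", 60.0))
                    period = float(params.pop("period_s", 2.0))
                    spec = synthetic.RigidBodySpec(
                        angle_trajectory=lambda t: amp * 0.5 * (1 - np.cos(2 * np.pi * t / period)),
                        seed=s_seed,
                        **params,
                    )
                    rec, truth, _ = synthetic.generate_rigid_body(spec)
                    np.savetxt(out / "truth_angle.csv", truth, header="angle_deg")
                else:
                    raise ValueError(f"unknown generate kind {kind!r}")
                entry["artifact"] = str(write_recording(rec, out / "recording.csv"))
            elif stage == "preprocess":
                rec = preprocess(rec, PreprocessConfig(**params))
                entry["artifact"] = str(write_recording(rec, out / "preprocessed.csv"))
            elif stage == "calibrate":
                calib = calibrate_axes(rec)
                rec = correct_imu(rec, calib)
                path = out / "calibration.json"
                path.write_text(json.dumps({k: v.to_dict() for k, v in calib.items()}, indent=1))
                entry["artifact"] = str(path)
            elif stage == "angles":
                calib = calibrate_axes(rec)
                traces = estimate_attitudes(rec, **params)
                angles = joint_angles(rec, calib, traces)
                for name, tr in angles.items():
                    np.savetxt(out / f"angle_{name}.csv", tr.angle_deg, header="angle_deg")
                entry["artifact"] = str(out / "angle_*.csv")
            elif stage == "features":
                window_ms = float(params.pop("window_ms", 1040.0))
                overlap = float(params.pop("overlap", 0.8))
                ws = segment(rec, window_ms, overlap)
                table = extract_features(ws)
                if params.pop("normalize", True):
                    table = normalize_minmax(table)
                table.X.assign(label=table.labels).to_csv(out / "features.csv", index=False)
                entry["artifact"] = str(out / "features.csv")
            elif stage == "resample":
                ensemble = build_ensemble(table, seed=s_seed, **params)
                entry["target"] = ensemble.target
                entry["k"] = ensemble.k
            elif stage == "select":
                ga = GAConfig(seed=s_seed, **params)
                result = run_gfsfan(table, ga)
                path = out / "subset.json"
                path.write_text(json.dumps({
                    "selected": result.selected,
                    "fitness": result.fitness,
                    "history_best": result.history_best,
                }, indent=1))
                entry["artifact"] = str(path)
            elif stage == "evaluate":
                classifiers = params.pop("classifiers", ["knn", "lda", "nb"])
                grid = sensor_combination_sweep(table, classifiers, seed=s_seed, **params)
                grid.to_csv(out / "results.csv", index=False)
                entry["artifact"] = str(out / "results.csv")
        except Exception as exc:
            manifest["stages"].append({**entry, "error": str(exc)})
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        if "artifact" in entry:
            primary = Path(entry["artifact"])
            if primary.exists():
                entry["sha256"] = _hash_file(primary)
        manifest["stages"].append(entry)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
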