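"""Run configuration and the end-to-end simulate/prepare/train/evaluate driver.

A run is described by a YAML/dict config with four sections -- ``bladder``,
``profiles``, ``pipeline``, ``training`` -- plus a global seed.  Every
stochastic stage receives a child seed derived deterministically from the
global one, so a rerun with the same config reproduces the metrics exactly.
``run_pipeline`` writes all artifacts (trace CSV, dataset archive, model
directory, metrics JSON) together with a manifest recording the resolved
configuration, its hash, the derived seeds and package version.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .io import write_trace_csv
from .network import (ArchitectureSpec, TrainingConfig, build_model, evaluate,
                      train)
from .pipeline import prepare_dataset
from .synth import ActivityProfile, default_profiles, generate_session

__all__ = ["DEFAULT_CONFIG", "load_config", "resolve_config", "run_pipeline"]

logger = logging.getLogger("pneumyo")

DEFAULT_CONFIG: dict = {
    "seed": 42,
    "bladder": {
        "D_mm": 20.0, "loop_length_mm": 300.0, "baseline_kpa": 20.0,
        "k": 1.0, "x_mm": 100.0, "Am_mm2": 2000.0,
        "Ab_mm2": 400.0, "Au_mm2": 1200.0,
    },
    "profiles": {"baseline_kpa": 20.0, "overrides": {}},
    "pipeline": {
        "duration_s_per_mode": 60.0,
        "window_ms": 500, "stride_ms": 50,
        "target_per_class": None, "split_ratio": 0.8,
        "squat_threshold": "auto",
    },
    "training": {"learning_rate": 1e-3, "epochs": 300, "batch_size": 128},
    "architecture": {},
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path=None) -> dict:
    """Defaults merged with an optional YAML file."""
    if path is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    user = yaml.safe_load(Path(path).read_text()) or {}
    return _deep_merge(DEFAULT_CONFIG, user)


def resolve_config(config: dict) -> dict:
    """Validate required sections; log every resolved parameter value."""
    for section in ("bladder", "profiles", "pipeline", "training"):
        if section not in config:
            raise ValueError(f"config missing required section {section!r}")
    for section, values in config.items():
        if isinstance(values, dict):
            for key, val in values.items():
                logger.info("config %s.%s = %r", section, key, val)
        else:
            logger.info("config %s = %r", section, values)
    return config


def _profiles_from_config(config: dict) -> dict[str, ActivityProfile]:
    section = config["profiles"]
    profiles = default_profiles(section.get("baseline_kpa", 20.0))
    for mode, override in (section.get("overrides") or {}).items():
        if mode not in profiles:
            raise ValueError(f"profile override for unknown mode {mode!r}")
        fields = {**profiles[mode].__dict__, **override}
        profiles[mode] = ActivityProfile(**fields)
    return profiles


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute simulate -> prepare -> train -> evaluate; write all artifacts.

    Returns the manifest dict (also written to ``manifest.json``).
    """
    config = resolve_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config["seed"]).generate_state(3) % (2**31)
    sim_seed, prep_seed, train_seed = (int(s) for s in seeds)

    stage = "simulate"
    try:
        profiles = _profiles_from_config(config)
        dur = float(config["pipeline"]["duration_s_per_mode"])
        modes = sorted(profiles)
        session = generate_session([profiles[m] for m in modes],
                                   [dur] * len(modes), seed=sim_seed)
        write_trace_csv(session, out / "traces.csv")

        stage = "prepare"
        pl = config["pipeline"]
        thr = pl.get("squat_threshold")
        if thr == "auto":
            thr = config["profiles"].get("baseline_kpa", 20.0)
        rate = session.sampling_rate_hz
        split = prepare_dataset(
            session,
            window_len_samples=int(round(pl["window_ms"] * rate / 1000.0)),
            stride_samples=int(round(pl["stride_ms"] * rate / 1000.0)),
            target_per_class=pl.get("target_per_class"),
            split_ratio=pl["split_ratio"],
            seed=prep_seed,
            squat_threshold_kpa=thr,
        )
        split.save(out / "dataset.npz")

        stage = "train"
        tr = config["training"]
        spec = ArchitectureSpec(**config.get("architecture", {}))
        model = build_model(spec, seed=train_seed, labels=modes)
        cfg = TrainingConfig(learning_rate=tr["learning_rate"],
                             epochs=tr["epochs"], batch_size=tr["batch_size"],
                             seed=train_seed)
        model, history = train(model, split, cfg)
        model.save(out / "model")

        stage = "evaluate"
        metrics = evaluate(model, split.test_X, split.test_y)
        (out / "metrics.json").write_text(json.dumps(metrics.to_dict(), indent=2))
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest = {
        "version": __version__,
        "config": config,
        "config_hash": _config_hash(config),
        "seeds": {"simulate": sim_seed, "prepare": prep_seed, "train": train_seed},
        "metrics": {"accuracy": metrics.accuracy,
                    "per_class": metrics.per_class},
        "final_training_loss": history["loss"][-1],
        "artifacts": ["traces.csv", "dataset.npz", "model", "metrics.json"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
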