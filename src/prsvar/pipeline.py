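"""End-to-end pipeline driven by a nested configuration mapping.

Stages: ``simulate`` (screen simulation) -> ``decompose`` -> ``screen``
(threshold derivation + hit-calling) -> ``cluster``; independently
``trajectories`` (simulation + shape statistics), ``compare`` (ABC
resampling test between two strains) and ``events`` (event-timing
statistics from a scored event table).  Stages are individually
toggleable; every randomized stage gets its own seed derived
deterministically from the global one.  Each output table carries the
SHA-256 hash of the canonical configuration in ``DataFrame.attrs`` so
results can be traced back to the configuration that produced them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, curves, decomposition, events, io, screen, simulate, trajectories
from .exceptions import ConfigError, DependencyError
from .params import SimulationParams

__all__ = ["run_pipeline", "load_config", "validate_config", "config_hash"]

logger = logging.getLogger("prsvar")

_SCHEMA = {
    "seed": int,
    "input": str,
    "output_dir": str,
    "params": {f: None for f in SimulationParams().to_dict()},
    "stages": {
        "simulate": {
            "enabled": bool,
            "n_strains": int,
            "n_replicates": int,
            "n_cells_per_rep": int,
            "doses": list,
            "mean_multipliers": list,
            "var_multipliers": list,
            "cluster_labels": list,
        },
        "decompose": {"enabled": bool, "trim": list},
        "screen": {
            "enabled": bool,
            "tail_prob": float,
            "reference_strain": str,
            "thresholds": dict,
            "confirm_k": int,
        },
        "cluster": {
            "enabled": bool,
            "doses": list,
            "n_clusters": int,
            "cut_height": float,
            "per_replicate": bool,
        },
        "trajectories": {
            "enabled": bool,
            "n_cells": int,
            "times": list,
            "crooked_frac": float,
            "jump_magnitude": float,
            "dose_nM": float,
            "threshold": float,
            "n_boot": int,
        },
        "compare": {
            "enabled": bool,
            "strain_a": str,
            "strain_b": str,
            "n_resamples": int,
            "unit": str,
            "method": str,
        },
        "events": {"enabled": bool, "input": str, "reference": str, "n_boot": int, "n_perm": int},
    },
}


def validate_config(config: dict, schema: dict = _SCHEMA, prefix: str = "") -> None:
    """Reject unknown keys anywhere in the nested configuration."""
    if not isinstance(config, dict):
        raise ConfigError(f"expected a mapping at '{prefix or '<root>'}'")
    for key, value in config.items():
        if key not in schema:
            raise ConfigError(f"unknown config key '{prefix}{key}'")
        sub = schema[key]
        if isinstance(sub, dict) and isinstance(value, dict):
            validate_config(value, sub, prefix=f"{prefix}{key}.")


def load_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    validate_config(config)
    return config


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % 2**31


def _enabled(stages: dict, name: str) -> bool:
    stage = stages.get(name, {})
    return bool(stage.get("enabled", False))


def run_pipeline(config: dict | str | Path) -> dict:
    """Run the configured stages; returns a dict of result tables.

    Deterministic given the configuration (including its seed).  Raises
    :class:`ConfigError` for unknown keys and :class:`DependencyError`
    when a stage is enabled without the stage it consumes.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        validate_config(config)
    chash = config_hash(config)
    seed = int(config.get("seed", 0))
    stages = config.get("stages", {})
    params = SimulationParams(**{**config.get("params", {}), "seed": seed})
    bundle: dict = {"config_hash": chash}

    def _tag(obj):
        if isinstance(obj, pd.DataFrame):
            obj.attrs["config_hash"] = chash
        return obj

    cells = None
    if _enabled(stages, "simulate"):
        cfg = dict(stages["simulate"])
        cfg.pop("enabled")
        cells, truth = simulate.simulate_screen(
            params, seed=_stage_seed(seed, "simulate"), **cfg
        )
        bundle["cells"] = _tag(cells)
        bundle["truth"] = _tag(truth)
    elif config.get("input"):
        cells = io.read_cell_table(config["input"])
        bundle["cells"] = _tag(cells)

    decomp = None
    if _enabled(stages, "decompose"):
        if cells is None:
            raise DependencyError("decompose requires the simulate stage or an input table")
        cfg = dict(stages["decompose"])
        cfg.pop("enabled")
        trim = cfg.pop("trim", None)
        decomp = decomposition.decompose_table(cells, trim=tuple(trim) if trim else None)
        bundle["decomposition"] = _tag(decomp)

    if _enabled(stages, "screen"):
        if decomp is None:
            raise DependencyError("screen requires the decompose stage")
        cfg = dict(stages["screen"])
        cfg.pop("enabled")
        ref = cfg.pop("reference_strain", "reference")
        explicit = cfg.pop("thresholds", None)
        confirm_k = cfg.pop("confirm_k", None)
        if explicit is not None:
            thresholds = screen.SelectionThresholds(**explicit)
        else:
            ref_rows = decomp[decomp["strain"] == ref]
            thresholds = screen.derive_thresholds(ref_rows, **cfg)
        non_ref = decomp[decomp["strain"] != ref]
        if confirm_k is not None:
            per_rep = screen.call_hits_per_replicate(non_ref, thresholds)
            calls = screen.confirm_hits(per_rep, k=confirm_k)
        else:
            calls = screen.call_hits(non_ref, thresholds)
        bundle["thresholds"] = thresholds
        bundle["hits"] = _tag(screen.hit_table(calls))

    if _enabled(stages, "cluster"):
        if decomp is None:
            raise DependencyError("cluster requires the decompose stage")
        cfg = dict(stages["cluster"])
        cfg.pop("enabled")
        n_clusters = cfg.pop("n_clusters", None)
        cut_height = cfg.pop("cut_height", None)
        mat = clustering.strain_phenotype_matrix(decomp, **cfg)
        centered = clustering.preprocess_matrix(mat)
        result = clustering.cluster_strains(
            centered, n_clusters=n_clusters, cut_height=cut_height
        )
        bundle["phenotype_matrix"] = _tag(centered)
        bundle["clusters"] = result
        if result["labels"] is not None:
            sig = {
                c: clustering.cluster_signature(centered.loc[idx])
                for c, idx in result["labels"].groupby(result["labels"]).groups.items()
            }
            bundle["signatures"] = _tag(pd.DataFrame(sig).T)

    if _enabled(stages, "trajectories"):
        cfg = dict(stages["trajectories"])
        cfg.pop("enabled")
        times = np.asarray(cfg.pop("times", np.arange(0.0, 301.0, 30.0)), dtype=float)
        threshold = cfg.pop("threshold", 0.3)
        n_boot = cfg.pop("n_boot", 1000)
        rng = np.random.default_rng(_stage_seed(seed, "trajectories"))
        tset, truth = simulate.simulate_trajectories(params, times=times, rng=rng, **cfg)
        per_cell, summary = trajectories.classify_crooked(tset, threshold=threshold)
        result = trajectories.mps(tset, n_boot=n_boot, seed=_stage_seed(seed, "mps"))
        bundle["trajectory_cells"] = _tag(per_cell)
        bundle["trajectory_truth"] = _tag(truth)
        bundle["trajectory_summary"] = {
            **summary,
            "mps": result.mps,
            "mps_ci_low": result.ci_low,
            "mps_ci_high": result.ci_high,
        }

    if _enabled(stages, "compare"):
        if cells is None:
            raise DependencyError("compare requires the simulate stage or an input table")
        cfg = dict(stages["compare"])
        cfg.pop("enabled")
        strain_a = cfg.pop("strain_a")
        strain_b = cfg.pop("strain_b")
        result = curves.abc_resampling_test(
            cells[cells["strain"] == strain_a],
            cells[cells["strain"] == strain_b],
            seed=_stage_seed(seed, "compare"),
            **cfg,
        )
        bundle["abc_test"] = result

    if _enabled(stages, "events"):
        cfg = dict(stages["events"])
        cfg.pop("enabled")
        path = cfg.pop("input", None)
        if path is None:
            raise DependencyError("events requires an input event table")
        table = pd.read_csv(path)
        reference = cfg.pop("reference", "reference")
        bundle["event_summary"] = _tag(
            events.summarize_event_table(
                table, n_boot=cfg.get("n_boot", 10_000), seed=_stage_seed(seed, "events")
            )
        )
        bundle["event_tests"] = _tag(
            events.compare_to_reference(
                table,
                reference,
                n_perm=cfg.get("n_perm", 10_000),
                seed=_stage_seed(seed, "event_tests"),
            )
        )
        bundle["category_tests"] = _tag(events.category_tests(table, reference))

    ran = [k for k in bundle if k != "config_hash"]
    if not ran:
        logger.info("no stages enabled; empty bundle")
    out_dir = config.get("output_dir")
    if out_dir:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, obj in bundle.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(out_dir / f"{name}.csv", index=False)
    meta = {
        k: (v if isinstance(v, (str, int, float, dict)) else str(v))
        for k, v in bundle.items()
        if not isinstance(v, pd.DataFrame)
    }
    with open(out_dir / "bundle.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
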