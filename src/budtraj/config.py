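"""Pipeline configuration: defaults, validation, normalization.

A single YAML (or dict) configures every stage.  Unknown keys are rejected
so typos fail loudly; every threshold has a documented default.  The
``simulate`` block, when present, replaces the four input paths with a
synthetic dataset generated from the planted-truth model.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import yaml

from .prioritize import DEFAULT_WEIGHTS

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "inputs": {
        "expression": None,
        "samples": None,
        "hormones": None,
        "annotations": None,
        "classes": None,
    },
    "simulate": {
        "enabled": False,
        "n_genes": 2000,
        "noise_sd": 0.2,
        "baseline_sd": 1.5,
        "reps": 3,
    },
    "qc": {
        "min_tpm": 1.0,
        "min_libraries": 3,
        "n_top_genes": 2000,
    },
    "trajectory": {
        "k": 8,
        "n_restarts": 10,
        "scale": "tpm",
        "tau_discordant": 0.5,
    },
    "divergence": {
        "eps": 0.05,
        "concordance_k": 3,
        "abundance_min_mean": 0.5,
        "abundance_min_max": 1.0,
    },
    "enrichment": {
        "alpha": 0.05,
    },
    "network": {
        "min_abs_r": 0.8,
        "beta": 6,
        "cut_height": 0.8,
        "min_module_size": 20,
        "consensus_k": 3,
        "consensus_min_abs_r": 0.5,
    },
    "prioritize": {
        "weights": dict(DEFAULT_WEIGHTS),
        "top_n": 20,
    },
}


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


def _merge(defaults: Mapping[str, Any], raw: Mapping[str, Any],
           path: str = "") -> dict[str, Any]:
    out = copy.deepcopy(dict(defaults))
    for key, value in raw.items():
        here = f"{path}{key}"
        if key not in defaults:
            raise ConfigError(f"unknown config key: {here!r}")
        if isinstance(defaults[key], dict) and key != "weights":
            if not isinstance(value, Mapping):
                raise ConfigError(f"{here!r} must be a mapping")
            out[key] = _merge(defaults[key], value, path=f"{here}.")
        else:
            out[key] = copy.deepcopy(value)
    return out


def validate_config(raw: Mapping[str, Any] | None) -> dict[str, Any]:
    """Fill defaults, reject unknown keys, check ranges; returns the
    normalized config."""
    cfg = _merge(DEFAULTS, raw or {})

    def check(cond: bool, msg: str) -> None:
        if not cond:
            raise ConfigError(msg)

    check(isinstance(cfg["seed"], int) and cfg["seed"] >= 0,
          "seed must be a non-negative integer")
    check(cfg["qc"]["min_tpm"] >= 0, "qc.min_tpm must be >= 0")
    check(cfg["qc"]["min_libraries"] >= 1, "qc.min_libraries must be >= 1")
    check(cfg["qc"]["n_top_genes"] >= 2, "qc.n_top_genes must be >= 2")
    check(cfg["trajectory"]["k"] >= 2, "trajectory.k must be >= 2")
    check(cfg["trajectory"]["n_restarts"] >= 1,
          "trajectory.n_restarts must be >= 1")
    check(cfg["trajectory"]["scale"] in ("tpm", "log"),
          "trajectory.scale must be 'tpm' or 'log'")
    check(0 <= cfg["trajectory"]["tau_discordant"] <= 1,
          "trajectory.tau_discordant must be in [0, 1]")
    check(cfg["divergence"]["eps"] >= 0, "divergence.eps must be >= 0")
    check(cfg["divergence"]["concordance_k"] >= 1,
          "divergence.concordance_k must be >= 1")
    check(0 < cfg["enrichment"]["alpha"] < 1,
          "enrichment.alpha must be in (0, 1)")
    check(0 < cfg["network"]["min_abs_r"] <= 1,
          "network.min_abs_r must be in (0, 1]")
    check(cfg["network"]["beta"] >= 1, "network.beta must be >= 1")
    check(0 < cfg["network"]["cut_height"] <= 1,
          "network.cut_height must be in (0, 1]")
    check(cfg["network"]["min_module_size"] >= 2,
          "network.min_module_size must be >= 2")
    check(cfg["network"]["consensus_k"] >= 1,
          "network.consensus_k must be >= 1")
    check(0 < cfg["network"]["consensus_min_abs_r"] <= 1,
          "network.consensus_min_abs_r must be in (0, 1]")
    weights = cfg["prioritize"]["weights"]
    check(all(v >= 0 for v in weights.values()),
          "prioritize.weights must be non-negative")
    check(abs(sum(weights.values()) - 1.0) <= 1e-9,
          f"prioritize.weights must sum to 1, got {sum(weights.values())}")
    check(cfg["prioritize"]["top_n"] >= 1, "prioritize.top_n must be >= 1")
    check(cfg["simulate"]["n_genes"] >= 1, "simulate.n_genes must be >= 1")
    check(cfg["simulate"]["noise_sd"] >= 0, "simulate.noise_sd must be >= 0")
    check(cfg["simulate"]["reps"] >= 1, "simulate.reps must be >= 1")

    if not cfg["simulate"]["enabled"]:
        needed = ("expression", "samples", "hormones", "annotations")
        missing = [k for k in needed if not cfg["inputs"][k]]
        if missing and raw:   # empty config is valid (defaults only)
            pass
    return cfg


def load_config(path: str | Path | None) -> dict[str, Any]:
    if path is None:
        return validate_config({})
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def config_hash(cfg: Mapping[str, Any]) -> str:
    """Stable short hash of the normalized config (provenance header)."""
    blob = json.dumps(cfg, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
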