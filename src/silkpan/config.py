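"""Run configuration and provenance records for the command-line layer.

A RunConfig is a plain YAML mapping with a versioned schema; every threshold
defaults to the pipeline's standard values (5 kb / 500 bp windows, top 1%
FST, top 5% XP-CLR, lowest 5% Tajima's D, FDR 1e-4 and fold change 2 for
divergence scans, FDR 0.001 for expression, +/-5 kb regulatory flanks,
2.5 kb error-region flank, 100 kb SV size cap, 500 bp merge distance).
"""

from __future__ import annotations

import hashlib
import json

import yaml

SCHEMA_VERSION = 1

DEFAULTS = {
    "schema_version": SCHEMA_VERSION,
    "window_size": 5000,
    "window_step": 500,
    "q_fst": 0.99,
    "q_xpclr": 0.95,
    "q_tajd": 0.05,
    "divergence_fdr": 1e-4,
    "divergence_fc": 2.0,
    "expression_fdr": 1e-3,
    "regulatory_flank": 5000,
    "error_flank": 2500,
    "sv_max_len": 100_000,
    "merge_max_dist": 500,
    "merge_size_ratio": 0.7,
    "rare_af": 0.05,
    "seed": 0,
}


def load_config(path=None, **overrides) -> dict:
    cfg = dict(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    cfg.update({k: v for k, v in overrides.items() if v is not None})
    _validate(cfg)
    return cfg


def _validate(cfg: dict) -> None:
    if cfg["schema_version"] != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema version {cfg['schema_version']}")
    for key in ("q_fst", "q_xpclr", "q_tajd"):
        if not (0.0 < cfg[key] < 1.0):
            raise ValueError(f"{key} must lie in (0, 1)")
    if cfg["window_step"] <= 0 or cfg["window_size"] < cfg["window_step"]:
        raise ValueError("window_size must be >= window_step > 0")
    for key in ("divergence_fdr", "expression_fdr"):
        if not (0.0 < cfg[key] < 1.0):
            raise ValueError(f"{key} must lie in (0, 1)")


def config_hash(cfg: dict) -> str:
    payload = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_provenance(path, cfg: dict, stage: str) -> None:
    from . import __version__

    record = {
        "tool": "silkpan",
        "version": __version__,
        "stage": stage,
        "config": cfg,
        "config_hash": config_hash(cfg),
        "seed": cfg.get("seed"),
    }
    with open(path, "w") as fh:
        json.dump(record, fh, indent=1, sort_keys=True)
        fh.write("\n")
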