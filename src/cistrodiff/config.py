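"""Hierarchical run configuration: every tunable the pipeline exposes.

A YAML config file may override any subset of the defaults; unknown keys
are rejected so typos fail loudly.  Every CLI run writes the fully resolved
configuration beside its outputs.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "io": {
        "pwm_pseudocount": 0.8,
    },
    "peaks": {
        "promoter_halfwidth": 1500,
        "normalization_target": 1.0e7,
    },
    "scan": {
        "rel_threshold": 0.8,
        "background": [0.25, 0.25, 0.25, 0.25],
    },
    "enrichment": {
        "p_floor": 1.0e-300,
    },
    "footprint": {
        "fp_sizes": [11, 13, 15, 17, 19, 21, 23, 25],
        "shoulder_size": 35,
        "score_cutoff": -10.0,
    },
    "cooccurrence": {
        "window_bp": 50,
        "n_boot": 1000,
    },
    "differential": {
        "pseudocount": 1.0,
        "fold_threshold_dhs": 2.0,
        "fold_threshold_expression": 1.5,
        "assignment_window": 50000,
        "heatmap_window_bp": 2000,
        "heatmap_bins": 200,
        "density_window_bp": 1000,
        "density_bins": 50,
        "row_smoothing": 50,
    },
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise KeyError(f"unknown config key: {here}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ValueError(f"config key {here} must be a mapping")
            out[key] = _merge(base[key], value, here)
        else:
            out[key] = value
    return out


def load_config(path=None) -> dict:
    """Defaults, optionally overridden by a YAML file; unknown keys rejected."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    with open(path) as fh:
        override = yaml.safe_load(fh) or {}
    if not isinstance(override, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return _merge(DEFAULTS, override)


def write_resolved(config: dict, out_dir) -> None:
    Path(out_dir).mkdir(parents=True, exist_ok=True)
    with open(Path(out_dir) / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
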