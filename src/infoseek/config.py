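"""Defaults and YAML configuration loading for the CLI.

The configuration mirrors the package defaults: task geometry and
economy, agent parameters, EEG synthesis, preprocessing, epoching and
analysis settings.  A YAML file overrides any subset of keys; unknown
keys are rejected to catch typos.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "task": {
        "n_blocks": 7,
        "trials_per_block": 16,
        "cards_total": 5,
        "majority": 3,
        "win_amount": 20.0,
        "cost_levels": [0, 1, 2],
        "catch_rate": 0.10,
        "catch_penalty": 100.0,
        "winnings_cap": 1500.0,
    },
    "agent": {
        "info_value": 0.5,
        "choice_noise": 1.5,
        "catch_compliance": 0.98,
        "info_value_sd": 0.75,
    },
    "eeg": {
        "sample_rate": 512.0,
        "montage": None,  # null -> full default montage
        "white_sd": 8.0,
        "pink_scale": 8.0,
        "participant_sd": 1.0,
        "trial_sd": 1.0,
        "frn_rpe_effect": -1.4,
        "frn_ipe_effect": -2.1,
        "n1_rpe_effect": -1.3,
        "n1_ipe_effect": -1.1,
        "lpp_ipe_effect": 0.0,
        "frn_outcome_effect": -0.8,
    },
    "preprocess": {
        "l_freq": 0.1,
        "h_freq": 70.0,
        "notch": [45.0, 55.0],
        "filter_order": 4,
    },
    "epochs": {
        "window": [-1.0, 1.0],
        "baseline": [-0.1, 0.0],
        "rejection_threshold": 200.0,
        "min_epochs": 20,
    },
    "analysis": {
        "component": "FRN",
        "scheme": "ipe_sign",
        "zero_tolerance": 1e-9,
        "gg_correction": "auto",
    },
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key not in base:
            raise KeyError(f"unknown configuration key {path + key!r}")
        if isinstance(base[key], dict) and isinstance(value, dict):
            out[key] = _merge(base[key], value, path + key + ".")
        else:
            out[key] = value
    return out


def load_config(path=None) -> dict:
    """Defaults, optionally overridden by a YAML file."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    with open(Path(path)) as fh:
        override = yaml.safe_load(fh) or {}
    return _merge(DEFAULTS, override)
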