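"""Pipeline configuration: every detector threshold in one nested mapping,
overridable from a YAML file."""
from __future__ import annotations

import copy

import yaml

DEFAULTS: dict = {
    "repeat": {
        "min_unit": 50,
        "seed_k": 12,
        "min_identity": 0.80,
        "max_mismatch_run": 5,
        "commit_run": 8,
    },
    "tsd": {"min_len": 4, "max_len": 25, "max_mismatch": 0},
    "palindrome": {
        "min_len": 10,
        "max_mismatch": 2,
        "max_spacer": 4,
        "terminal_window": 5,
    },
    "promoter": {
        "tata_motif": "TATATATA",
        "inr_motif": "TCACT",
        "rev_inr_motif": "ACATT",
        "spacing": 20,
        "max_spacing": 50,
    },
    "orf": {
        "min_aa": 300,
        "nrich_window": 50,
        "nrich_threshold": 0.25,
        "nrich_min_len": 100,
        "trunc_threshold_aa": 30,
        "intact_len_tolerance": 0.05,
    },
    "capture": {
        "element_free_k": 20,
        "min_anchor": 200,
        "flank_identity_threshold": 0.90,
        "junction_window": 50,
    },
    "classify": {
        "subfamily_cut": 0.10,
        "family_cut": 0.25,
        "group_cut": 0.45,
        "anchor_k": 12,
        "inclusion_fraction": 0.3333333333333333,
    },
    "smallrna": {"max_mismatch": 1, "window": 100, "min_run": 3},
    "forge": {
        "background": "uniform",  # flanks are i.i.d. ACGT unless at_rich set
        "at_fraction": 0.7,
        "boundary_slack_bp": 2,  # tolerated offset between called and expected boundaries before flagging
    },
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULTS)


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in (override or {}).items():
        if key not in out:
            raise KeyError(f"unknown config key: {path}{key}")
        if isinstance(out[key], dict):
            out[key] = _merge(out[key], val, f"{path}{key}.")
        else:
            out[key] = val
    return out


def load_config(path: str | None = None) -> dict:
    """Defaults, deep-merged with an optional YAML override file."""
    if path is None:
        return default_config()
    with open(path) as fh:
        override = yaml.safe_load(fh) or {}
    return _merge(DEFAULTS, override)


def dump_default_config() -> str:
    return yaml.safe_dump(DEFAULTS, sort_keys=True)
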