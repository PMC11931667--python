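"""Pipeline defaults and config-file loading.

The defaults encode the analysis parameters of the study workflow: the
10-residue active-site set, 50 MI histogram bins, 60 stability frames,
9 propensity snapshots, the 6 A contact and 0.25 correlation cutoffs, 500
suboptimal paths, and the 20.35 kcal/mol stability cap.  A TOML or YAML
file can override any subset.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

import yaml

from .dihedral_mi import DEFAULT_ACTIVE_SITE

__all__ = ["DEFAULTS", "load_config"]

DEFAULTS: dict = {
    "active_site": list(DEFAULT_ACTIVE_SITE),
    "mi_bins": 50,
    "ddg_frames": 60,
    "b2b_snapshots": 9,
    "contact_cutoff": 6.0,
    "corr_cutoff": 0.25,
    "n_paths": 500,
    "ddg_cap": 20.35,
}


def load_config(path=None) -> dict:
    """Defaults, optionally overlaid with a TOML/YAML file."""
    cfg = dict(DEFAULTS)
    if path is None:
        return cfg
    path = Path(path)
    if path.suffix == ".toml":
        with open(path, "rb") as fh:
            user = tomllib.load(fh)
    else:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
    unknown = set(user) - set(cfg)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg.update(user)
    return cfg
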