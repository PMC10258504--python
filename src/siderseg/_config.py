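"""Run configuration and provenance capture for the command-line layer.

Every parameter that affects an output appears in a JSON provenance sidecar
written next to that output, so any run can be reproduced from its sidecar
alone (``siderseg replay``). Flag precedence is CLI > config file >
built-in default, and the resolution is part of the provenance record.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path

import yaml

from . import __version__ as _version

#: Per-subcommand parameter schemas: name -> built-in default.
SCHEMAS: dict[str, dict] = {
    "vesselness": {
        "sigma": 1.0,
        "beta": 0.5,
        "c": None,
        "polarity": "dark",
        "threshold": None,  # resolves to vesselness.DEFAULT_THRESHOLD
        "slice_axis": None,  # None -> coarsest-spacing axis
    },
    "segment": {
        "sigma": 1.0,
        "beta": 0.5,
        "c": None,
        "polarity": "dark",
        "threshold": None,
        "slice_axis": None,
        "strict_seeds": False,
        "snap_radius": 0,
    },
    "phantom": {
        "rng_seed": 0,
    },
    "cohort": {
        "n": 20,
        "vol_min": 0.5,
        "vol_max": 15.0,
        "rng_seed": 0,
    },
    "agree": {},
    "change": {},
    "volume": {},
}


class UnknownConfigKeyError(ValueError):
    """A config file contains keys the subcommand does not define."""


def load_config(path, subcommand: str) -> dict:
    """Load a JSON or YAML config for one subcommand, rejecting unknown keys."""
    schema = SCHEMAS[subcommand]
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        values = yaml.safe_load(text) or {}
    else:
        values = json.loads(text)
    if not isinstance(values, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = sorted(set(values) - set(schema))
    if unknown:
        raise UnknownConfigKeyError(
            f"{path}: unknown config keys for '{subcommand}': {', '.join(unknown)}"
        )
    return values


def resolve(subcommand: str, cli_values: dict, config_path=None) -> dict:
    """Merge CLI flags over config-file values over built-in defaults.

    ``cli_values`` uses ``None`` for flags the user did not pass.
    Returns the fully materialised parameter set.
    """
    schema = SCHEMAS[subcommand]
    resolved = dict(schema)
    source = {k: "default" for k in schema}
    if config_path is not None:
        for k, v in load_config(config_path, subcommand).items():
            resolved[k] = v
            source[k] = "config"
    for k, v in cli_values.items():
        if k not in schema:
            raise KeyError(f"internal: flag {k} not in schema of {subcommand}")
        if v is not None:
            resolved[k] = v
            source[k] = "cli"
    resolved["_sources"] = source
    return resolved


def provenance_record(subcommand: str, params: dict, inputs: dict, outputs: dict) -> dict:
    return {
        "tool": "siderseg",
        "version": _version,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "subcommand": subcommand,
        "params": {k: v for k, v in params.items() if not k.startswith("_")},
        "param_sources": params.get("_sources", {}),
        "inputs": inputs,
        "outputs": outputs,
    }


def write_sidecar(output_path, record: dict) -> Path:
    sidecar = Path(str(output_path) + ".provenance.json")
    sidecar.write_text(json.dumps(record, indent=2) + "\n")
    return sidecar
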