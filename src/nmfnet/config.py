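"""Run configuration: schema, defaults, validation, round-trip serialization.

A run is described by a flat YAML mapping with a ``command`` key naming the
subcommand and command-specific parameters beside it.  Unknown keys are
rejected with field-level messages; every executed run writes its fully
resolved configuration next to its outputs so any artifact is
reconstructible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

#: defaults common to all commands
GLOBAL_DEFAULTS: dict = {"seed": 0, "out": "run_out", "verbosity": 1}

#: per-command parameter schemas with defaults (None = required)
SCHEMAS: dict[str, dict] = {
    "factorize": {"input": None, "rank": None, "iters": 200},
    "gradcheck": {"S": 12, "I": 7, "N": 25, "trials": 200},
    "train": {
        "variant": "cnmf_1x1",
        "width": 1,
        "groups": 1,
        "n_iters": 25,
        "data": None,  # path to an image archive; None -> synthetic parts task
        "n_classes": 3,
        "image_size": 12,
        "n_per_class": 300,
        "noise_sd": 0.1,
        "channels": [16, 8],
        "lr0": 1e-3,
        "lr_min": 1e-9,
        "lr_factor": 10.0,
        "plateau_patience": 10,
        "max_epochs": 30,
        "batch_size": 64,
        "alpha": 0.5,
        "flip": False,
        "jitter": False,
        "crop": False,
    },
    "sweep": {"widths": [1, 2, 4, 8], "groups": [1, 2, 4, 8, 16]},
    "synth": {
        "kind": "parts",  # parts | lowrank
        "n_classes": 3,
        "n_per_class": 200,
        "image_size": 12,
        "n_parts": 6,
        "noise_sd": 0.1,
        "M": 50,
        "S": 30,
        "rank": 4,
    },
}


@dataclass(frozen=True)
class RunConfig:
    """A validated, fully-defaulted run description."""

    command: str
    params: dict

    def to_dict(self) -> dict:
        return {"command": self.command, **self.params}


def parse_and_validate(source: str | Path | dict) -> RunConfig:
    """Build a RunConfig from a YAML file path or an in-memory mapping.

    Applies defaults, rejects unknown keys, and checks cross-field
    contradictions (e.g. ``lr_min >= lr0``).
    """
    if isinstance(source, (str, Path)):
        with open(source) as f:
            raw = yaml.safe_load(f) or {}
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    command = raw.pop("command", None)
    if command not in SCHEMAS:
        raise ValueError(
            f"config needs a 'command' key, one of {sorted(SCHEMAS)}; got {command!r}"
        )
    schema = {**GLOBAL_DEFAULTS, **SCHEMAS[command]}
    unknown = set(raw) - set(schema)
    if unknown:
        raise ValueError(f"unknown key(s) for {command}: {sorted(unknown)}")
    params = {**schema, **raw}
    missing = [k for k, v in params.items() if v is None and schema[k] is None and k != "data"]
    if missing:
        raise ValueError(f"missing required key(s) for {command}: {missing}")
    if command == "train" and params["lr_min"] >= params["lr0"]:
        raise ValueError(
            f"lr_min ({params['lr_min']}) must be below lr0 ({params['lr0']})"
        )
    if command == "factorize" and params["rank"] is not None and params["rank"] < 1:
        raise ValueError("rank must be >= 1")
    return RunConfig(command=command, params=params)


def serialize(cfg: RunConfig) -> str:
    """YAML form of a resolved config; parse(serialize(c)) == c."""
    return yaml.safe_dump(cfg.to_dict(), sort_keys=True)


def save_resolved(cfg: RunConfig, out_dir: str | Path) -> Path:
    """Write the resolved config beside the run's outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "config.yaml"
    path.write_text(serialize(cfg))
    return path
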