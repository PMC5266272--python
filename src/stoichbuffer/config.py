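"""Model configuration files (YAML key–value, keys = model field names)."""

from __future__ import annotations

from dataclasses import fields
from importlib import resources
from pathlib import Path

import yaml


def packaged_default_path() -> Path:
    """Path of the shipped default heterodimer calibration."""
    return Path(resources.files("stoichbuffer") / "data" / "default_model.yaml")


def load_model(path: str | Path):
    """Load a HeterodimerModel from a YAML mapping; unknown keys rejected."""
    from .kinetics import HeterodimerModel

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: model config must be a mapping")
    valid = {f.name for f in fields(HeterodimerModel)}
    unknown = sorted(set(raw) - valid)
    if unknown:
        raise ValueError(f"{path}: unknown model keys {unknown}")
    return HeterodimerModel(**{k: float(v) for k, v in raw.items()})


def dump_model(model, path: str | Path) -> None:
    from dataclasses import asdict

    with open(path, "w") as fh:
        yaml.safe_dump(asdict(model), fh, sort_keys=True)
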