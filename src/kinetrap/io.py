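"""Reading and writing flat configuration and tabular artifacts."""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from . import __version__
from .errors import InputError
from .kinetics import RATE_NAMES, RateSet

__all__ = ["read_rates", "write_rates", "write_manifest"]


def read_rates(path) -> RateSet:
    """Read a rate set from a flat key-value YAML config (keys k1..k3)."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise InputError(f"rate config {path} must be a mapping of rate names to values")
    unknown = set(data) - set(RATE_NAMES)
    if unknown:
        raise InputError(f"rate config {path} has unknown key(s): {sorted(unknown)}")
    missing = set(RATE_NAMES) - set(data)
    if missing:
        raise InputError(f"rate config {path} is missing key(s): {sorted(missing)}")
    return RateSet(**{k: float(v) for k, v in data.items()})


def write_rates(rates: RateSet, path) -> None:
    Path(path).write_text(
        "".join(f"{name}: {getattr(rates, name)!r}\n" for name in RATE_NAMES)
    )


def write_manifest(out_dir, command: str, params: dict, seed=None) -> Path:
    """Write a small run manifest (config echo, package version, seed)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "package": "kinetrap",
        "version": __version__,
        "seed": seed,
        "params": {k: _jsonable(v) for k, v in params.items()},
    }
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _jsonable(value):
    if isinstance(value, Path):
        return str(value)
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    return value
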