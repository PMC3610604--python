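"""Configuration, table I/O and run manifests.

Tables travel as headered CSV; lines starting with ``#`` before the
header carry JSON metadata (ground-truth parameters, seeds) and are
round-tripped into ``DataFrame.attrs``.  Every CLI run writes one JSON
manifest next to its outputs recording the command, the configuration
snapshot, the seeds, the paths and the package version.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .params import BehaviorParams

__all__ = [
    "load_config",
    "read_table",
    "write_table",
    "read_trace",
    "write_trace",
    "RunManifest",
    "write_manifest",
]

# configuration schema: section -> key -> (default, validator)
_POSITIVE = ("must be > 0", lambda v: v > 0)
_NONNEG = ("must be >= 0", lambda v: v >= 0)
_FRACTION = ("must be in [0, 1]", lambda v: 0.0 <= v <= 1.0)

_SCHEMA: dict[str, dict[str, tuple[Any, tuple[str, Any]]]] = {
    "simulation": {
        "gap_length": (15.0, _POSITIVE),
        "max_rate": (3.0, _NONNEG),
        "duration": (600, _POSITIVE),
        "reps": (1000, _POSITIVE),
        "seed": (0, _NONNEG),
    },
    "periodogram": {
        "fmin": (1.0 / 30.0, _POSITIVE),
        "fmax": (1.0, _POSITIVE),
        "oversample": (5, _POSITIVE),
        "fap_threshold": (0.05, _FRACTION),
    },
    "optical_flow": {
        "sobel_size": (45, _POSITIVE),
        "gaussian_sigma": (16.0, _POSITIVE),
        "gaussian_support": (100, _POSITIVE),
        "fps": (25.0, _POSITIVE),
    },
    "xcorr": {
        "block": (10, _POSITIVE),
        "max_lag": (100, _NONNEG),
        "lag_step": (10, _POSITIVE),
    },
}


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Load and validate the flat YAML configuration.

    Missing sections and keys fall back to the field-fitted defaults (an
    empty or absent file yields the full default configuration, including
    the default :class:`BehaviorParams`).  Unknown keys and out-of-range
    values raise a ``ValueError`` naming the offending key.
    """
    data: dict[str, Any] = {}
    if path is not None and Path(path).exists():
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        data = raw

    known_sections = set(_SCHEMA) | {"params"}
    unknown = set(data) - known_sections
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")

    config: dict[str, Any] = {}
    config["params"] = BehaviorParams.from_dict(data.get("params") or {})
    for section, keys in _SCHEMA.items():
        given = data.get(section) or {}
        if not isinstance(given, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        bad = set(given) - set(keys)
        if bad:
            raise ValueError(f"unknown key(s) in section {section!r}: {sorted(bad)}")
        out = {}
        for key, (default, (msg, check)) in keys.items():
            v = given.get(key, default)
            if not isinstance(v, (int, float)):
                raise ValueError(f"{section}.{key} must be numeric")
            if not check(v):
                raise ValueError(f"{section}.{key} {msg}, got {v}")
            out[key] = v
        config[section] = out
    return config


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a CSV with the frame's ``attrs`` as ``#``-prefixed JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if df.attrs:
            fh.write("# " + json.dumps(df.attrs, default=_jsonable) + "\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table`, restoring ``attrs``."""
    path = Path(path)
    attrs = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            attrs = json.loads(first.lstrip("# "))
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    df.attrs.update(attrs)
    return df


def write_trace(trace, path: str | Path) -> None:
    from .signal_analysis import TrafficTrace  # noqa: F401 (type only)
    write_table(pd.DataFrame({"time": trace.timestamps, "value": trace.values}),
                path)


def read_trace(path: str | Path):
    from .signal_analysis import TrafficTrace
    df = read_table(path)
    return TrafficTrace(df["time"].to_numpy(), df["value"].to_numpy())


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


@dataclass
class RunManifest:
    command: str
    config: dict[str, Any]
    seed: int
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    version: str = ""
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.version:
            from . import __version__
            self.version = __version__
        if not self.timestamp:
            self.timestamp = datetime.datetime.now(
                datetime.timezone.utc).isoformat()


def write_manifest(manifest: RunManifest, out_path: str | Path) -> Path:
    """Write the run manifest as ``<output stem>.manifest.json``."""
    out_path = Path(out_path)
    path = out_path.with_suffix(out_path.suffix + ".manifest.json") \
        if out_path.suffix != ".json" else out_path.with_name(
            out_path.stem + ".manifest.json")
    d = dataclasses.asdict(manifest)
    if isinstance(d["config"].get("params"), BehaviorParams):
        d["config"]["params"] = d["config"]["params"].to_dict()
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(d, indent=2, default=_jsonable) + "\n")
    return path
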