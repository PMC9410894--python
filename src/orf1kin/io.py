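"""Trace files, run configuration and manifests.

Traces are plain tab-separated text with a ``#``-prefixed key:value
header: diff-able, small (<= 1e5 rows) and lossless.  Units are fixed by
the column names: time_s, extension_nm, force_pN (plus optional derived
channels ext_nm_per_nt and ext_relative).  Configuration is YAML with
strict key checking; every run directory gets a manifest echoing the
effective configuration and seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .kinetics import KineticParams
from .polymer import PolymerParams
from .synthetic import NoiseModel
from .trace import Trace

__all__ = ["read_trace", "write_trace", "RunConfig", "write_manifest"]

_CORE_COLUMNS = ("time_s", "extension_nm", "force_pN")


def write_trace(trace: Trace, path) -> None:
    """Write a trace as TSV with a ``#`` metadata header (lossless)."""
    path = Path(path)
    frame = trace.to_frame()
    with open(path, "w") as fh:
        for key, value in trace.metadata.items():
            if isinstance(value, np.ndarray):
                continue  # bulk provenance arrays are not round-tripped
            fh.write(f"# {key}: {json.dumps(value)}\n")
        fh.write("\t".join(frame.columns) + "\n")
        for row in frame.itertuples(index=False):
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_trace(path) -> Trace:
    """Read a TSV trace written by :func:`write_trace`.

    Raises
    ------
    ValueError
        Naming the offending line number for malformed headers or rows
        with inconsistent column counts.
    """
    path = Path(path)
    metadata, columns, rows = {}, None, []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" not in body:
                    raise ValueError(
                        f"{path}:{lineno}: malformed header line {line!r}")
                key, _, raw = body.partition(":")
                try:
                    metadata[key.strip()] = json.loads(raw.strip())
                except json.JSONDecodeError:
                    metadata[key.strip()] = raw.strip()
            elif columns is None:
                columns = line.split("\t")
                missing = [c for c in _CORE_COLUMNS if c not in columns]
                if missing:
                    raise ValueError(
                        f"{path}:{lineno}: missing required columns {missing}")
            else:
                parts = line.split("\t")
                if len(parts) != len(columns):
                    raise ValueError(
                        f"{path}:{lineno}: expected {len(columns)} columns, "
                        f"found {len(parts)}")
                rows.append([float(v) for v in parts])
    if columns is None:
        raise ValueError(f"{path}: no column header found")
    data = (np.asarray(rows, dtype=float) if rows
            else np.empty((0, len(columns))))
    if data.shape[0] == 0:
        metadata["empty"] = True
    cols = {name: data[:, i] for i, name in enumerate(columns)}
    # segment boundary lists arrive as JSON lists of [label, t]
    if "segments" in metadata:
        metadata["segments"] = [(str(l), float(t))
                                for l, t in metadata["segments"]]
    channels = {name: cols[name] for name in columns
                if name not in _CORE_COLUMNS}
    return Trace(cols["time_s"], cols["extension_nm"], cols["force_pN"],
                 metadata, channels)


@dataclass
class RunConfig:
    """Effective configuration of one run; unknown keys are rejected."""

    polymer: PolymerParams = field(default_factory=PolymerParams)
    noise: NoiseModel = field(default_factory=NoiseModel)
    preset_overrides: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}; "
                             f"known keys: {sorted(known)}")
        kwargs = dict(raw)
        if "polymer" in kwargs:
            kwargs["polymer"] = PolymerParams(**kwargs["polymer"])
        if "noise" in kwargs:
            kwargs["noise"] = NoiseModel(**kwargs["noise"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def write_manifest(out_dir, config: RunConfig, extra: dict = None) -> Path:
    """Echo the effective configuration, seed and version into a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"package": "orf1kin", "version": __version__,
                "config": config.to_dict()}
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return path
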