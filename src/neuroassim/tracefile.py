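"""Delimited-text trace files and run manifests.

The interchange format is tab-separated text: '#'-prefixed comment lines
carry a JSON metadata block (units, noise SD, seed, generating parameters),
then a header line (``time_ms``, ``v_mV``, optional ``true_*`` hidden-truth
columns) and one row per observation time.  Round-trips are exact for
finite values (full float repr).
"""

from __future__ import annotations

import hashlib
import json
import platform
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import TraceParseError
from .simulate import TraceRecord, Trajectory

__all__ = ["write_trace", "read_trace", "RunManifest"]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_trace(rec: TraceRecord, path: str | Path,
                include_truth: bool = True) -> Path:
    path = Path(path)
    meta = {
        "format": "neuroassim-trace-v1",
        "units": {"time": "ms", "v": "mV"},
        "noise_sd_mV": rec.noise_sd,
        "seed": rec.seed,
        "observed": rec.observed,
        "interval_ms": rec.interval,
        "meta": _jsonable(rec.meta),
    }
    cols = {"time_ms": rec.time, "v_mV": rec.v}
    if include_truth and rec.truth is not None:
        for name in rec.truth.columns:
            cols[f"true_{name}"] = rec.truth[name]
    df = pd.DataFrame(cols)
    with path.open("w") as fh:
        for line in json.dumps(meta, indent=1).splitlines():
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")
    return path


def read_trace(path: str | Path) -> TraceRecord:
    """Parse a delimited trace; malformed input raises with line numbers."""
    path = Path(path)
    meta_lines: list[str] = []
    header_line = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                meta_lines.append(stripped.lstrip("#"))
                continue
            header_line = lineno
            break
    if header_line is None:
        raise TraceParseError(f"{path}: no data header found")
    meta = {}
    if meta_lines:
        try:
            meta = json.loads("\n".join(meta_lines))
        except json.JSONDecodeError:
            meta = {}
    try:
        df = pd.read_csv(path, sep="\t", comment="#",
                         float_precision="round_trip")
    except Exception as exc:
        raise TraceParseError(f"{path}: cannot parse table: {exc}") from exc
    if "time_ms" not in df.columns or "v_mV" not in df.columns:
        raise TraceParseError(
            f"{path}:{header_line}: header must contain time_ms and v_mV, "
            f"got {list(df.columns)}")
    t = df["time_ms"].to_numpy(float)
    v = df["v_mV"].to_numpy(float)
    bad = np.flatnonzero(~np.isfinite(t) | ~np.isfinite(v))
    if bad.size:
        raise TraceParseError(
            f"{path}:{header_line + 1 + bad[0]}: non-finite value in row")
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        row = int(np.flatnonzero(np.diff(t) <= 0)[0])
        raise TraceParseError(
            f"{path}:{header_line + 2 + row}: time is not strictly increasing")
    truth = None
    truth_cols = [c for c in df.columns if c.startswith("true_")]
    if truth_cols:
        names = tuple(c[len("true_"):] for c in truth_cols)
        states = df[truth_cols].to_numpy(float)
        truth = Trajectory(t, states, names, float(t[1] - t[0]) if len(t) > 1 else 0.0)
    return TraceRecord(
        time=t, v=v,
        noise_sd=float(meta.get("noise_sd_mV", 0.0)),
        seed=meta.get("seed"),
        truth=truth,
        observed=meta.get("observed", "pc"),
        meta=meta.get("meta", {}))


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to re-execute a run: config echo, seeds, digests."""
    command: str
    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)       # name -> sha256
    outputs: dict = field(default_factory=dict)
    version: str = ""
    started: str = ""
    finished: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.version:
            from . import __version__
            self.version = __version__
        if not self.started:
            self.started = _time.strftime("%Y-%m-%dT%H:%M:%S")
        self.platform = platform.platform()

    def add_input(self, path: str | Path) -> None:
        p = Path(path)
        self.inputs[p.name] = _digest(p)

    def add_output(self, path: str | Path) -> None:
        p = Path(path)
        self.outputs[p.name] = _digest(p)

    def save(self, path: str | Path) -> Path:
        self.finished = _time.strftime("%Y-%m-%dT%H:%M:%S")
        path = Path(path)
        payload = {
            "command": self.command, "config": _jsonable(self.config),
            "seeds": _jsonable(self.seeds), "inputs": self.inputs,
            "outputs": self.outputs, "version": self.version,
            "platform": self.platform, "started": self.started,
            "finished": self.finished, "extra": _jsonable(self.extra),
        }
        path.write_text(json.dumps(payload, indent=2, default=str))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        data = json.loads(Path(path).read_text())
        m = cls(command=data.get("command", ""))
        for key in ("config", "seeds", "inputs", "outputs", "version",
                    "started", "finished", "extra"):
            setattr(m, key, data.get(key, getattr(m, key)))
        return m
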