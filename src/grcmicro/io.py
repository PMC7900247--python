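"""Trace containers, run manifests and reproducibility plumbing.

Traces round-trip losslessly (float64) through two containers: columnar CSV
(``time_ms,value,signal_kind`` with a ``# key=value`` header block) and an
HDF5 layout ``/traces/<protocol>/<condition>/<repeat>``.  Every output
directory carries exactly one manifest recording code version, parameter-file
checksums, protocol parameters, seeds and integrator settings; re-running
from a manifest reproduces traces bit-identically.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from . import __version__
from .conditions import params_checksums
from .trace import Trace

SCHEMA_VERSION = 1


class ContainerError(IOError):
    """Corrupt or version-incompatible trace container."""


# ------------------------------------------------------------------ seeds

def fan_out_seed(seed: int, stream: str, index: int = 0) -> int:
    """Deterministic per-stream seed derived from one global seed.

    The splitting rule: SeedSequence spawned with the (stream, index) pair
    hashed into the entropy pool; documented so repeat seeds are auditable.
    """
    ss = np.random.SeedSequence([seed & 0x7FFFFFFF,
                                 zlib.crc32(stream.encode()) & 0x7FFFFFFF, index])
    return int(ss.generate_state(1)[0] % (2 ** 31))


# ------------------------------------------------------------------ CSV

def save_trace_csv(trace: Trace, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# schema_version={SCHEMA_VERSION}\n")
        fh.write(f"# dt_ms={float(trace.dt)!r}\n")
        fh.write(f"# t0_ms={float(trace.t0)!r}\n")
        fh.write(f"# kind={trace.kind}\n")
        fh.write(f"# n_samples={trace.n}\n")
        fh.write(f"# meta={json.dumps(trace.meta, default=str)}\n")
        fh.write("time_ms,value,signal_kind\n")
        t = trace.time()
        for ti, vi in zip(t, trace.data):
            fh.write(f"{float(ti)!r},{float(vi)!r},{trace.kind}\n")


def load_trace_csv(path) -> Trace:
    path = Path(path)
    header: dict = {}
    rows_t, rows_v = [], []
    kind = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                header[key.strip()] = val
            elif line.startswith("time_ms"):
                continue
            elif line:
                parts = line.split(",")
                if len(parts) != 3:
                    raise ContainerError(f"malformed row in {path}: {line!r}")
                rows_t.append(float(parts[0]))
                rows_v.append(float(parts[1]))
                kind = parts[2]
    if "schema_version" not in header:
        raise ContainerError(f"{path}: missing schema header")
    if int(header["schema_version"]) != SCHEMA_VERSION:
        raise ContainerError(
            f"{path}: schema version {header['schema_version']} needs migration")
    if not rows_v:
        raise ContainerError(f"{path}: no samples")
    dt = float(header["dt_ms"])
    if "n_samples" not in header:
        raise ContainerError(f"{path}: missing sample-count header")
    if int(header["n_samples"]) != len(rows_v):
        raise ContainerError(f"{path}: truncated trace "
                             f"({len(rows_v)} of {header['n_samples']} samples)")
    n_expected = int(round((rows_t[-1] - rows_t[0]) / dt)) + 1
    if n_expected != len(rows_v):
        raise ContainerError(f"{path}: non-uniform sampling")
    meta = json.loads(header.get("meta", "{}"))
    return Trace(dt=dt, data=np.array(rows_v), kind=kind,
                 t0=float(header.get("t0_ms", 0.0)), meta=meta)


# ------------------------------------------------------------------ HDF5

def save_traces_h5(traces: dict, path) -> None:
    """Save ``{(protocol, condition, repeat): Trace}`` to the HDF5 layout."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        for (protocol, condition, repeat), tr in traces.items():
            ds = f.create_dataset(f"/traces/{protocol}/{condition}/{repeat}",
                                  data=tr.data, dtype="float64")
            ds.attrs["dt_ms"] = tr.dt
            ds.attrs["t0_ms"] = tr.t0
            ds.attrs["kind"] = tr.kind
            ds.attrs["meta"] = json.dumps(tr.meta, default=str)


def load_traces_h5(path) -> dict:
    out = {}
    with h5py.File(path, "r") as f:
        if int(f.attrs.get("schema_version", -1)) != SCHEMA_VERSION:
            raise ContainerError(f"{path}: schema version mismatch")
        root = f["traces"]
        for protocol in root:
            for condition in root[protocol]:
                for repeat in root[protocol][condition]:
                    ds = root[protocol][condition][repeat]
                    out[(protocol, condition, int(repeat))] = Trace(
                        dt=float(ds.attrs["dt_ms"]), data=ds[()],
                        kind=str(ds.attrs["kind"]), t0=float(ds.attrs["t0_ms"]),
                        meta=json.loads(ds.attrs["meta"]))
    return out


# ------------------------------------------------------------------ manifest

@dataclass
class RunManifest:
    """Provenance record emitted alongside every run's outputs."""

    code_version: str = __version__
    schema_version: int = SCHEMA_VERSION
    condition_files: dict = field(default_factory=params_checksums)
    protocol: dict = field(default_factory=dict)
    seed: int | None = None
    derived_seeds: dict = field(default_factory=dict)
    integrator: dict = field(default_factory=lambda: {"dt_ms": 0.025, "theta": 0.5})
    timestamp: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    def save(self, directory) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        path = directory / "manifest.json"
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)
        return path

    @classmethod
    def load(cls, directory) -> "RunManifest":
        with open(Path(directory) / "manifest.json") as fh:
            raw = json.load(fh)
        m = cls()
        m.__dict__.update(raw)
        return m
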