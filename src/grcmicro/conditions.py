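"""Named, versioned condition bundles.

A condition bundle is a diff against the baseline ("control") parameter
files: an explicit list of overridden keys per cell model and per synapse
class, so every deviation the bundle introduces is auditable.  Bundles are
shipped as YAML files under ``params/conditions/`` and addressed by name.
"""

from __future__ import annotations

import copy
import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml


class ConfigurationError(ValueError):
    """Unknown condition/synapse/cell name or malformed override."""


def _params_dir() -> Path:
    return Path(str(resources.files("grcmicro").joinpath("params")))


def load_yaml(path: Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def file_checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class ConditionSet:
    """A named parameter bundle describing every deviation from baseline.

    ``intrinsic`` maps cell kind -> {dotted key: value} overrides applied to
    the cell parameter tree; ``synaptic`` maps synapse class -> overrides on
    the synapse parameter tree.  The control bundle is the identity (no
    overrides).
    """

    name: str
    intrinsic: dict = field(default_factory=dict)
    synaptic: dict = field(default_factory=dict)
    notes: str = ""
    source_file: str | None = None
    checksum: str | None = None

    def cell_overrides(self, kind: str) -> dict:
        return self.intrinsic.get(kind, {})

    def synapse_overrides(self, synapse: str) -> dict:
        return self.synaptic.get(synapse, {})


def _set_dotted(tree: dict, key: str, value, context: str) -> None:
    parts = key.split(".")
    node = tree
    for p in parts[:-1]:
        if not isinstance(node, dict) or p not in node:
            raise ConfigurationError(
                f"override {key!r} in {context}: path element {p!r} not in baseline"
            )
        node = node[p]
    leaf = parts[-1]
    if not isinstance(node, dict) or leaf not in node:
        raise ConfigurationError(
            f"override {key!r} in {context}: key {leaf!r} not in baseline"
        )
    node[leaf] = value


def apply_overrides(baseline: dict, overrides: dict, context: str = "condition") -> dict:
    """Return a deep copy of ``baseline`` with dotted-key overrides applied.

    Every override must name a key already present in the baseline tree, so a
    typo in a condition file fails loudly instead of silently adding a key.
    """
    tree = copy.deepcopy(baseline)
    for key, value in overrides.items():
        _set_dotted(tree, key, value, context)
    return tree


def available_conditions() -> list[str]:
    cdir = _params_dir() / "conditions"
    return sorted(p.stem for p in cdir.glob("*.yaml"))


def get_condition(name: str) -> ConditionSet:
    """Load a condition bundle by name from the packaged condition files."""
    path = _params_dir() / "conditions" / f"{name}.yaml"
    if not path.exists():
        raise ConfigurationError(
            f"unknown condition {name!r}; available: {', '.join(available_conditions())}"
        )
    raw = load_yaml(path)
    return ConditionSet(
        name=raw.get("name", name),
        intrinsic=raw.get("intrinsic", {}) or {},
        synaptic=raw.get("synaptic", {}) or {},
        notes=raw.get("notes", ""),
        source_file=str(path),
        checksum=file_checksum(path),
    )


def load_cell_params(kind: str) -> dict:
    """Baseline parameter tree for a cell model (``grc`` or ``goc``)."""
    path = _params_dir() / f"{kind}.yaml"
    if not path.exists():
        raise ConfigurationError(f"unknown cell kind {kind!r}")
    return load_yaml(path)


def load_synapse_params() -> dict:
    """Baseline parameter tree for all synapse classes."""
    return load_yaml(_params_dir() / "synapses.yaml")


def params_checksums() -> dict:
    """sha256 of every packaged parameter file (for run manifests)."""
    out = {}
    base = _params_dir()
    for p in sorted(base.rglob("*.yaml")):
        out[str(p.relative_to(base))] = file_checksum(p)
    return out
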