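"""Run configuration, named profiles, and deterministic seed derivation.

A run is described by a YAML file whose keys map one-to-one onto the
fields of :class:`~fibrelax.core.Domain`,
:class:`~fibrelax.assembly.AssemblyConfig`,
:class:`~fibrelax.core.SimParams` and
:class:`~fibrelax.rheometry.Protocol` — either nested under ``domain:``,
``assembly:``, ``params:``, ``protocol:`` sections or given flat (each
field name is unique across the four).  Unknown keys are rejected rather
than silently ignored.

Two named profiles are shipped:

* ``paper`` — the full 20 × 20 × 5 µm box (~227 fibrils at 3.65 mg/ml);
* ``desk``  — a 12 × 12 × 3 µm box (~49 fibrils) for fast exploratory
  runs and test suites, with proportionally relaxed anchoring tolerance
  and shorter loose-bundle chains so chains fit the smaller box.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import yaml

from .assembly import AssemblyConfig
from .core import Domain, SimParams
from .rheometry import Protocol

PROFILES = {
    "paper": {
        "domain": {"Lx": 20.0, "Ly": 20.0, "Lz": 5.0},
        "assembly": {"chain_length": 4, "anchor_tol": 0.25},
        "params": {"kBT_mech": 0.0},
        "protocol": {"hold": 60.0},
    },
    "desk": {
        "domain": {"Lx": 12.0, "Ly": 12.0, "Lz": 3.0},
        "assembly": {"chain_length": 3, "anchor_tol": 1.5},
        "params": {"kBT_mech": 0.0},
        "protocol": {"hold": 60.0},
    },
}


@dataclass
class RunConfig:
    """Fully resolved configuration of one simulation run."""

    domain: Domain = field(default_factory=Domain)
    assembly: AssemblyConfig = field(default_factory=AssemblyConfig)
    params: SimParams = field(default_factory=SimParams)
    protocol: Protocol = field(default_factory=Protocol)
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "domain": dataclasses.asdict(self.domain),
            "assembly": dataclasses.asdict(self.assembly),
            "params": dataclasses.asdict(self.params),
            "protocol": dataclasses.asdict(self.protocol),
            "seed": self.seed,
            "log_level": self.log_level,
        }


class ConfigError(ValueError):
    """Configuration parsing/validation failure, naming the offending key."""


_SECTIONS = {
    "domain": Domain,
    "assembly": AssemblyConfig,
    "params": SimParams,
    "protocol": Protocol,
}
_TOP_KEYS = {"seed", "log_level", "profile"}


def _field_names(cls) -> set:
    return {f.name for f in dataclasses.fields(cls)}


def load_config(path_or_dict, profile: Optional[str] = None) -> RunConfig:
    """Parse a YAML run configuration (empty file ⇒ all defaults).

    ``profile`` (or a ``profile:`` key in the file) applies a named
    preset before user keys; user keys always win.  Unknown keys raise
    :class:`ConfigError` with the key path.
    """
    if isinstance(path_or_dict, dict):
        raw = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            try:
                raw = yaml.safe_load(fh) or {}
            except yaml.YAMLError as exc:
                raise ConfigError(f"cannot parse config: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
    profile = raw.pop("profile", profile)
    kwargs = {name: {} for name in _SECTIONS}
    if profile is not None:
        if profile not in PROFILES:
            raise ConfigError(f"unknown profile {profile!r}")
        for section, over in PROFILES[profile].items():
            kwargs[section].update(over)
    flat_owner = {}
    for section, cls in _SECTIONS.items():
        for name in _field_names(cls):
            flat_owner[name] = section
    top = {}
    for key, value in raw.items():
        if key in _TOP_KEYS:
            top[key] = value
        elif key in _SECTIONS:
            if not isinstance(value, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            allowed = _field_names(_SECTIONS[key])
            for sub, sval in value.items():
                if sub not in allowed:
                    raise ConfigError(f"unknown key {key}.{sub}")
                kwargs[key][sub] = sval
        elif key in flat_owner:
            kwargs[flat_owner[key]][key] = value
        else:
            raise ConfigError(f"unknown key {key!r}")
    try:
        cfg = RunConfig(
            domain=Domain(**kwargs["domain"]),
            assembly=AssemblyConfig(**kwargs["assembly"]),
            params=SimParams(**kwargs["params"]),
            protocol=Protocol(**kwargs["protocol"]),
            seed=int(top.get("seed", 0)),
            log_level=str(top.get("log_level", "INFO")),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    return cfg


def derive_seeds(master_seed: int, labels: Sequence[str]) -> dict:
    """Deterministic, collision-resistant per-stage seeds.

    Each label gets ``sha256(master:label)`` folded to a 31-bit integer;
    the same master and label always produce the same seed.  Duplicate
    labels are rejected.
    """
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate seed labels")
    out = {}
    for label in labels:
        digest = hashlib.sha256(
            f"{int(master_seed)}:{label}".encode()).digest()
        out[label] = int.from_bytes(digest[:4], "big") % (2**31)
    return out
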