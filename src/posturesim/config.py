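"""Run configuration: loading, validation and lossless serialization.

A run configuration bundles everything one simulation or tuning run needs:
the fixture (or an inline plant description), the perturbation, objective
and CMA-ES settings, the integrator step and the master seed.  Files are
TOML or JSON; unknown keys are rejected with field-level messages.  JSON is
used for writing (round-trips losslessly).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .fixtures import FixtureSpec
from .perturbation import PerturbationSpec
from .tuning import CmaConfig, ObjectiveConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config",
           "config_hash"]


class ConfigError(ValueError):
    """Configuration file does not validate; message names the field."""


@dataclass(frozen=True)
class RunConfig:
    fixture: FixtureSpec
    perturbation: PerturbationSpec = field(default_factory=PerturbationSpec)
    objective: ObjectiveConfig = field(default_factory=ObjectiveConfig)
    cma: CmaConfig = field(default_factory=CmaConfig)
    dt: float = 1e-3  # s
    seed: int = 0
    output_dir: str = "runs"

    def __post_init__(self) -> None:
        if not (0 < self.dt <= 1e-3 + 1e-12):
            raise ConfigError("dt must be positive and at most 0.001 s")

    def to_dict(self) -> dict:
        d = {
            "fixture": dataclasses.asdict(self.fixture),
            "perturbation": dataclasses.asdict(self.perturbation),
            "objective": dataclasses.asdict(self.objective),
            "cma": dataclasses.asdict(self.cma),
            "dt": self.dt,
            "seed": self.seed,
            "output_dir": self.output_dir,
        }
        cma = d["cma"]
        if cma.get("gain_upper") is not None and hasattr(
                cma["gain_upper"], "tolist"):
            cma["gain_upper"] = cma["gain_upper"].tolist()
        return d


_SECTION_TYPES = {
    "fixture": FixtureSpec,
    "perturbation": PerturbationSpec,
    "objective": ObjectiveConfig,
    "cma": CmaConfig,
}


def _build_section(name: str, cls, payload: dict):
    if not isinstance(payload, dict):
        raise ConfigError(f"section {name!r} must be a table/object")
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - fields
    if unknown:
        raise ConfigError(
            f"section {name!r}: unknown keys {sorted(unknown)}")
    try:
        return cls(**payload)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"section {name!r}: {exc}") from exc


def load_config(path) -> RunConfig:
    """Parse and validate a TOML or JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    if path.suffix.lower() == ".toml":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    else:
        with open(path) as fh:
            raw = json.load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("top level must be a table/object")
    known_top = set(_SECTION_TYPES) | {"dt", "seed", "output_dir"}
    unknown = set(raw) - known_top
    if unknown:
        raise ConfigError(f"unknown top-level keys {sorted(unknown)}")
    if "fixture" not in raw:
        raise ConfigError("missing required section 'fixture'")
    kwargs = {}
    for name, cls in _SECTION_TYPES.items():
        if name in raw:
            kwargs[name] = _build_section(name, cls, raw[name])
    for key in ("dt", "seed", "output_dir"):
        if key in raw:
            kwargs[key] = raw[key]
    try:
        return RunConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def save_config(config: RunConfig, path) -> None:
    """Write the configuration as JSON (lossless round trip)."""
    with open(path, "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def config_hash(config: RunConfig) -> str:
    """Stable short hash identifying the configuration."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
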