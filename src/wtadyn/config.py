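"""Experiment configuration and reproducible output bundles.

A config file is a flat tables-per-section TOML (or JSON) document with
sections ``model``, ``task``, ``solver`` and ``output``.  Numbers carry
fixed documented units (currents pA, capacitance pF, voltage mV, time
s) rather than unit suffixes in keys.  Unknown keys are rejected.  The
materialized config (defaults merged with the file and any overrides)
is echoed into every output bundle so a run can be reproduced from its
own artifacts.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .model import ModelParams

__all__ = ["ExperimentConfig", "ConfigError", "load_config", "write_bundle"]


class ConfigError(ValueError):
    """Configuration parse/validation failure (names the offending key)."""


_SOLVER_DEFAULTS = {"dt": 1e-3, "method": "rk4"}
_OUTPUT_DEFAULTS = {"directory": "out", "formats": ["csv", "json"]}
_TASK_DEFAULTS = {"name": None}


@dataclass
class ExperimentConfig:
    model: dict = field(default_factory=dict)
    task: dict = field(default_factory=lambda: dict(_TASK_DEFAULTS))
    solver: dict = field(default_factory=lambda: dict(_SOLVER_DEFAULTS))
    output: dict = field(default_factory=lambda: dict(_OUTPUT_DEFAULTS))

    def model_params(self) -> ModelParams:
        try:
            return ModelParams.from_dict(self.model)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"model section: {exc}") from exc

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> ExperimentConfig:
    """Merged configuration: defaults <- file <- overrides, in that
    precedence order.  ``overrides`` is a {section: {key: value}} dict
    (e.g. from CLI flags)."""
    data: dict = {}
    if path is not None:
        path = Path(path)
        try:
            if path.suffix == ".json":
                data = json.loads(path.read_text())
            else:
                data = tomllib.loads(path.read_text())
        except (tomllib.TOMLDecodeError, json.JSONDecodeError) as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc

    known_sections = {"model", "task", "solver", "output"}
    unknown = set(data) - known_sections
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")

    cfg = ExperimentConfig()
    for section, defaults in (("task", _TASK_DEFAULTS), ("solver", _SOLVER_DEFAULTS),
                              ("output", _OUTPUT_DEFAULTS)):
        merged = dict(defaults)
        for src in (data.get(section, {}), (overrides or {}).get(section, {})):
            bad = set(src) - set(defaults) - ({"name"} if section == "task" else set())
            # task section carries task-specific settings; allow free keys there
            if section != "task" and bad:
                raise ConfigError(f"unknown {section} keys: {sorted(bad)}")
            merged.update(src)
        setattr(cfg, section, merged)
    cfg.model = {**data.get("model", {}), **(overrides or {}).get("model", {})}
    if cfg.solver["method"] not in ("euler", "rk4"):
        raise ConfigError(f"solver.method must be 'euler' or 'rk4', got {cfg.solver['method']!r}")
    if not (isinstance(cfg.solver["dt"], (int, float)) and cfg.solver["dt"] > 0):
        raise ConfigError(f"solver.dt must be a positive number, got {cfg.solver['dt']!r}")
    return cfg


def write_bundle(payloads: dict[str, str | bytes], directory: str | Path,
                 config: ExperimentConfig | None = None) -> dict:
    """Write a deterministic file set plus a manifest of content hashes.

    ``payloads`` maps relative file names to text/bytes content.  The
    config echo (config.json) is added automatically when given.  The
    manifest (manifest.json) lists every file with its sha256 and is
    itself part of the bundle.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = dict(payloads)
    if config is not None:
        files["config.json"] = json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n"
    manifest = {"files": {}}
    for name in sorted(files):
        content = files[name]
        raw = content.encode() if isinstance(content, str) else content
        (directory / name).write_bytes(raw)
        manifest["files"][name] = hashlib.sha256(raw).hexdigest()
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
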