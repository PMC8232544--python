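"""Run configuration: a strict, serialisable description of a simulation.

Configs are TOML or JSON files with sections ``geometry``, ``rule``,
``initial``, ``rates``, ``run``, ``analysis`` and ``environment``.  The
schema is strict — unknown keys are rejected by name — so a typo cannot
silently fall back to a default.  ``load_config(save_config(x)) == x``.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .errors import ConfigurationError

__all__ = ["RunSpec", "load_config", "save_config", "config_hash"]

_SCHEMA: dict[str, dict[str, type | tuple]] = {
    "geometry": {
        "dimension": int,
        "shape": list,
        "rest_channels": int,
        "phenotypes": int,
    },
    "rule": {
        "name": str,
        "beta": (int, float),
        "beta_agg": (int, float),
        "beta_align": (int, float),
        "beta_rest": (int, float),
        "n_crit": (int, float),
    },
    "initial": {"density": (int, float)},
    "rates": {"birth": (int, float), "death": (int, float)},
    "run": {"steps": int, "seed": int},
    "analysis": {
        "q_points": int,
        "rest_fraction_threshold": (int, float),
        "arg_tolerance": (int, float),
    },
    "environment": {"signal_csv": str, "field_csv": str},
}

_REQUIRED = {"geometry": ("dimension", "shape"), "rule": ("name",), "run": ("steps",)}


@dataclass
class RunSpec:
    """Fully explicit run description (all defaults filled on load)."""

    dimension: int
    shape: list[int]
    rule_name: str
    steps: int
    rest_channels: int = 0
    phenotypes: int = 1
    rule_params: dict = field(default_factory=dict)
    density: float = 0.2
    birth: float = 0.0
    death: float = 0.0
    seed: int = 0
    q_points: int = 256
    rest_fraction_threshold: float = 0.75
    arg_tolerance: float = 1e-6
    signal_csv: str | None = None
    field_csv: str | None = None

    def to_sections(self) -> dict:
        out = {
            "geometry": {
                "dimension": self.dimension,
                "shape": list(self.shape),
                "rest_channels": self.rest_channels,
                "phenotypes": self.phenotypes,
            },
            "rule": {"name": self.rule_name, **self.rule_params},
            "initial": {"density": self.density},
            "rates": {"birth": self.birth, "death": self.death},
            "run": {"steps": self.steps, "seed": self.seed},
            "analysis": {
                "q_points": self.q_points,
                "rest_fraction_threshold": self.rest_fraction_threshold,
                "arg_tolerance": self.arg_tolerance,
            },
        }
        env = {}
        if self.signal_csv is not None:
            env["signal_csv"] = self.signal_csv
        if self.field_csv is not None:
            env["field_csv"] = self.field_csv
        if env:
            out["environment"] = env
        return out


def _validate_sections(data: dict, source: str) -> list[str]:
    problems = []
    for section, content in data.items():
        if section not in _SCHEMA:
            problems.append(f"unknown section '{section}'")
            continue
        if not isinstance(content, dict):
            problems.append(f"section '{section}' must be a table")
            continue
        for key, value in content.items():
            if key not in _SCHEMA[section]:
                problems.append(f"unknown key '{key}' in section '{section}'")
            else:
                expected = _SCHEMA[section][key]
                if not isinstance(value, expected) or isinstance(value, bool):
                    problems.append(
                        f"key '{section}.{key}' has wrong type "
                        f"{type(value).__name__}"
                    )
    for section, keys in _REQUIRED.items():
        if section not in data:
            problems.append(f"missing required section '{section}'")
            continue
        for key in keys:
            if key not in data[section]:
                problems.append(f"missing required key '{section}.{key}'")
    return problems


def load_config(path: str | Path) -> RunSpec:
    """Load and validate a TOML or JSON run configuration."""
    path = Path(path)
    text = path.read_bytes()
    if path.suffix == ".json":
        data = json.loads(text)
    else:
        data = tomllib.loads(text.decode())
    problems = _validate_sections(data, str(path))
    if problems:
        raise ConfigurationError(
            f"invalid configuration {path}: " + "; ".join(problems)
        )
    geometry = data["geometry"]
    rule = dict(data["rule"])
    name = rule.pop("name")
    spec = RunSpec(
        dimension=geometry["dimension"],
        shape=[int(s) for s in geometry["shape"]],
        rest_channels=geometry.get("rest_channels", 0),
        phenotypes=geometry.get("phenotypes", 1),
        rule_name=name,
        rule_params={k: float(v) for k, v in rule.items()},
        steps=data["run"]["steps"],
        seed=data["run"].get("seed", 0),
        density=float(data.get("initial", {}).get("density", 0.2)),
        birth=float(data.get("rates", {}).get("birth", 0.0)),
        death=float(data.get("rates", {}).get("death", 0.0)),
        q_points=data.get("analysis", {}).get("q_points", 256),
        rest_fraction_threshold=float(
            data.get("analysis", {}).get("rest_fraction_threshold", 0.75)
        ),
        arg_tolerance=float(data.get("analysis", {}).get("arg_tolerance", 1e-6)),
        signal_csv=data.get("environment", {}).get("signal_csv"),
        field_csv=data.get("environment", {}).get("field_csv"),
    )
    return spec


def _toml_scalar(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    if isinstance(value, str):
        return json.dumps(value)
    if isinstance(value, list):
        return "[" + ", ".join(_toml_scalar(v) for v in value) + "]"
    raise ConfigurationError(f"cannot serialise {value!r} to TOML")


def save_config(spec: RunSpec, path: str | Path) -> None:
    """Write a RunSpec to TOML (default) or JSON, losslessly."""
    path = Path(path)
    sections = spec.to_sections()
    if path.suffix == ".json":
        path.write_text(json.dumps(sections, indent=2) + "\n")
        return
    lines = []
    for section, content in sections.items():
        lines.append(f"[{section}]")
        for key, value in content.items():
            lines.append(f"{key} = {_toml_scalar(value)}")
        lines.append("")
    path.write_text("\n".join(lines))


def config_hash(spec: RunSpec) -> str:
    """Stable hash of the full configuration, for output provenance."""
    payload = json.dumps(spec.to_sections(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
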