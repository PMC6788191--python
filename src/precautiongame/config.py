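"""Run configuration: schema-validated structured-text input, stable output.

A configuration file (YAML or JSON; JSON is a YAML subset and both parse
with the same loader) has up to five blocks::

    game:         {cc, cs, p, a, b, rule}          # required: cc, cs, p, a, b
    integration:  {t_max, rtol, atol, corner_tol, flow_tol}
    sweep:        {a_range, b_range, resolution}
    output:       {directory, formats}
    seed:         integer                           # only for sampled-start basin runs

Unknown keys are rejected, every numeric field is validated against its
domain, and the fully resolved configuration (defaults filled in) is
echoed into every output so results are self-describing.  All floats are
serialized with 12 significant digits — below integrator tolerance, above
representation noise — so repeated runs are byte-stable.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError, ParameterError
from .model import GameParams

__all__ = [
    "IntegrationSettings",
    "SweepSettings",
    "OutputSettings",
    "RunConfig",
    "load_config",
    "parse_config",
    "format_float",
    "round12",
    "dump_json",
    "write_trajectory_csv",
]


def format_float(x: float) -> str:
    """Fixed 12-significant-digit rendering used in all text outputs."""
    return format(float(x), ".12g")


def round12(obj):
    """Recursively round floats to 12 significant digits for stable output."""
    if isinstance(obj, float):
        return float(format_float(obj))
    if isinstance(obj, dict):
        return {k: round12(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [round12(v) for v in obj]
    return obj


def dump_json(obj, path: "Path | str") -> None:
    """Write a JSON report deterministically (sorted keys, rounded floats)."""
    Path(path).write_text(json.dumps(round12(obj), indent=2, sort_keys=True) + "\n")


def write_trajectory_csv(trajectory, path: "Path | str") -> None:
    """Write a trajectory as CSV with header ``t,alpha,beta``."""
    lines = ["t,alpha,beta"]
    for t, alpha, beta in zip(trajectory.t, trajectory.alpha, trajectory.beta):
        lines.append(f"{format_float(t)},{format_float(alpha)},{format_float(beta)}")
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class IntegrationSettings:
    t_max: float = 500.0
    rtol: float = 1e-10
    atol: float = 1e-12
    corner_tol: float = 1e-3
    flow_tol: float = 1e-8

    def __post_init__(self) -> None:
        for name in ("t_max", "rtol", "atol", "corner_tol", "flow_tol"):
            value = getattr(self, name)
            if not isinstance(value, (int, float)) or not math.isfinite(value) or value <= 0:
                raise ConfigError(f"integration.{name} must be a finite positive number, got {value!r}")
            object.__setattr__(self, name, float(value))


@dataclass(frozen=True)
class SweepSettings:
    a_range: tuple[float, float] = (0.0, 1.0)
    b_range: tuple[float, float] = (0.0, 1.0)
    resolution: int = 21

    def __post_init__(self) -> None:
        for name in ("a_range", "b_range"):
            value = getattr(self, name)
            try:
                lo, hi = (float(value[0]), float(value[1]))
            except (TypeError, ValueError, IndexError):
                raise ConfigError(f"sweep.{name} must be a pair [low, high], got {value!r}") from None
            if not (0.0 <= lo <= hi <= 1.0):
                raise ConfigError(f"sweep.{name} must satisfy 0 <= low <= high <= 1, got {value!r}")
            object.__setattr__(self, name, (lo, hi))
        if not isinstance(self.resolution, int) or self.resolution < 2:
            raise ConfigError(f"sweep.resolution must be an integer >= 2, got {self.resolution!r}")


@dataclass(frozen=True)
class OutputSettings:
    directory: str = "results"
    formats: tuple[str, ...] = ("csv", "json")

    def __post_init__(self) -> None:
        if not isinstance(self.directory, str) or not self.directory:
            raise ConfigError(f"output.directory must be a non-empty string, got {self.directory!r}")
        formats = tuple(self.formats)
        for fmt in formats:
            if fmt not in ("csv", "json", "png", "svg"):
                raise ConfigError(f"output.formats entry {fmt!r} not in {{csv, json, png, svg}}")
        object.__setattr__(self, "formats", formats)


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved run configuration."""

    game: GameParams
    integration: IntegrationSettings = field(default_factory=IntegrationSettings)
    sweep: SweepSettings = field(default_factory=SweepSettings)
    output: OutputSettings = field(default_factory=OutputSettings)
    seed: "int | None" = None

    def resolved(self) -> dict:
        """Plain-dict form with every default filled in (echoed into outputs)."""
        return round12({
            "game": {
                "cc": self.game.cc, "cs": self.game.cs, "p": self.game.p,
                "a": self.game.a, "b": self.game.b, "rule": self.game.rule.value,
            },
            "integration": asdict(self.integration),
            "sweep": {
                "a_range": list(self.sweep.a_range),
                "b_range": list(self.sweep.b_range),
                "resolution": self.sweep.resolution,
            },
            "output": {"directory": self.output.directory, "formats": list(self.output.formats)},
            "seed": self.seed,
        })


_BLOCK_KEYS = {
    "game": ("cc", "cs", "p", "a", "b", "rule"),
    "integration": ("t_max", "rtol", "atol", "corner_tol", "flow_tol"),
    "sweep": ("a_range", "b_range", "resolution"),
    "output": ("directory", "formats"),
}


def _check_keys(block: str, mapping: dict) -> None:
    if not isinstance(mapping, dict):
        raise ConfigError(f"block {block!r} must be a mapping, got {type(mapping).__name__}")
    unknown = set(mapping) - set(_BLOCK_KEYS[block])
    if unknown:
        allowed = ", ".join(_BLOCK_KEYS[block])
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in block {block!r}; allowed keys: {allowed}"
        )


def parse_config(data: dict) -> RunConfig:
    """Validate a parsed configuration mapping into a :class:`RunConfig`."""
    if not isinstance(data, dict):
        raise ConfigError(f"configuration root must be a mapping, got {type(data).__name__}")
    unknown = set(data) - {"game", "integration", "sweep", "output", "seed"}
    if unknown:
        raise ConfigError(
            f"unknown top-level key(s) {sorted(unknown)}; "
            "allowed: game, integration, sweep, output, seed"
        )
    if "game" not in data:
        raise ConfigError("configuration must contain a 'game' block with cc, cs, p, a, b")
    _check_keys("game", data["game"])
    missing = [k for k in ("cc", "cs", "p", "a", "b") if k not in data["game"]]
    if missing:
        raise ConfigError(f"game block is missing required key(s): {missing}")
    try:
        game = GameParams(**data["game"])
    except ParameterError as exc:
        raise ConfigError(f"game block invalid: {exc}") from exc

    def build(block: str, cls):
        raw = data.get(block, {})
        _check_keys(block, raw)
        raw = dict(raw)
        for key in ("a_range", "b_range", "formats"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    integration = build("integration", IntegrationSettings)
    sweep = build("sweep", SweepSettings)
    output = build("output", OutputSettings)
    seed = data.get("seed")
    if seed is not None and (not isinstance(seed, int) or isinstance(seed, bool)):
        raise ConfigError(f"seed must be an integer, got {seed!r}")
    return RunConfig(game=game, integration=integration, sweep=sweep, output=output, seed=seed)


def load_config(path: "Path | str") -> RunConfig:
    """Load and validate a YAML or JSON configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    return parse_config(data if data is not None else {})
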