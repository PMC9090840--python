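"""Run configuration: schema, validation, defaults, and lossless echo.

A run is described by a YAML mapping with the sections

    simulate:    FullSimConfig fields (synthetic mode), or
    inputs:      paths {sperm, blood, genome, genes, counts, sheet,
                 embryo_counts, embryo_sheet} (real-data mode)
    scan:        ScanParams fields
    classifier:  ClassifierParams fields
    stats:       n_perm, alpha
    seed:        mandatory integer — the only entropy source of a run
    outdir:      optional output directory

Unknown keys anywhere are rejected by name; every value (explicit or
default) is echoed into the run report so a run can be reproduced from its
own report byte-identically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .expression import ClassifierParams
from .scan import ScanParams
from .simulate import (
    DepthSimConfig,
    ExpressionSimConfig,
    FullSimConfig,
    GenomeConfig,
)

__all__ = ["ConfigError", "InputPaths", "StatsParams", "RunConfig",
           "load_validate_config", "config_from_dict", "config_to_dict"]


class ConfigError(ValueError):
    """Raised for unknown keys or type/range violations, naming the key."""


@dataclass
class InputPaths:
    sperm: str
    blood: str
    genome: str
    genes: str
    counts: str
    sheet: str
    embryo_counts: str | None = None
    embryo_sheet: str | None = None


@dataclass
class StatsParams:
    n_perm: int = 1000
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ConfigError("stats.n_perm: must be >= 1")
        if not (0 < self.alpha < 1):
            raise ConfigError("stats.alpha: must be in (0,1)")


@dataclass
class RunConfig:
    seed: int
    simulate: FullSimConfig | None = None
    inputs: InputPaths | None = None
    scan: ScanParams = field(default_factory=ScanParams)
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    stats: StatsParams = field(default_factory=StatsParams)
    outdir: str | None = None

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ConfigError("exactly one of 'simulate' and 'inputs' must be given")


def _build(cls, section: str, data: dict):
    """Instantiate a dataclass from a mapping, rejecting unknown keys and
    converting list values for tuple-typed fields."""
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{section}: expected a mapping")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(f"{section}: unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        default = known[key].default
        if isinstance(value, list) and (
            isinstance(default, tuple) or "tuple" in str(known[key].type)
        ):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{section}: {exc}") from exc


def config_from_dict(data: dict) -> RunConfig:
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    known = {"seed", "simulate", "inputs", "scan", "classifier", "stats", "outdir"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")
    if "seed" not in data:
        raise ConfigError("seed: required (every stochastic stage is seeded)")
    seed = data["seed"]
    if not isinstance(seed, int) or isinstance(seed, bool):
        raise ConfigError("seed: must be an integer")

    simulate = None
    if "simulate" in data and data["simulate"] is not None:
        sim = dict(data["simulate"]) if isinstance(data["simulate"], dict) else {}
        if not isinstance(data["simulate"], (dict, bool)):
            raise ConfigError("simulate: expected mapping or true")
        sub_unknown = set(sim) - {"genome", "depth", "expression", "embryo"}
        if sub_unknown:
            raise ConfigError(f"simulate: unknown key(s) {sorted(sub_unknown)}")
        simulate = FullSimConfig(
            genome=_build(GenomeConfig, "simulate.genome", sim.get("genome")),
            depth=_build(DepthSimConfig, "simulate.depth", sim.get("depth")),
            expression=_build(
                ExpressionSimConfig, "simulate.expression", sim.get("expression")
            ),
            embryo=bool(sim.get("embryo", False)),
        )

    inputs = None
    if "inputs" in data and data["inputs"] is not None:
        inputs = _build(InputPaths, "inputs", data["inputs"])

    return RunConfig(
        seed=seed,
        simulate=simulate,
        inputs=inputs,
        scan=_build(ScanParams, "scan", data.get("scan")),
        classifier=_build(ClassifierParams, "classifier", data.get("classifier")),
        stats=_build(StatsParams, "stats", data.get("stats")),
        outdir=data.get("outdir"),
    )


def load_validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run config, filling defaults."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data if data is not None else {})


def _plain(obj):
    """Tuples -> lists recursively, so the echo survives YAML/JSON."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def config_to_dict(config: RunConfig) -> dict:
    """Full echo of a RunConfig, defaults included — the report's
    'config' field.  config_from_dict(config_to_dict(c)) == c."""
    out: dict = {"seed": config.seed, "outdir": config.outdir}
    if config.simulate is not None:
        out["simulate"] = dataclasses.asdict(config.simulate)
    if config.inputs is not None:
        out["inputs"] = dataclasses.asdict(config.inputs)
    out["scan"] = dataclasses.asdict(config.scan)
    out["classifier"] = dataclasses.asdict(config.classifier)
    out["stats"] = dataclasses.asdict(config.stats)
    return _plain(out)
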