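"""Strict, YAML-backed run configuration.

Every analysis parameter inherited from the protocol this package mirrors is
under-specified somewhere upstream, so the whole surface is audit-friendly
configuration: each module's knobs live in one nested section with defaults
equal to the module's documented defaults, unknown keys are rejected rather
than ignored, and every run echoes its fully-resolved config (plus seed) next
to its outputs so any result is reproducible from that file alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import get_type_hints

import yaml

from .simulate import GeneratorConfig

__all__ = ["RunConfig", "load_config", "config_to_dict", "dump_config"]


@dataclass
class QCSection:
    min_genes: int = 200
    max_genes: int = 2000
    max_pct_mito: float = 1.0


@dataclass
class HVGSection:
    n_top: int = 3000
    span: float = 0.3


@dataclass
class IntegrationSection:
    k_cca: int = 30
    k_anchor: int = 5
    k_filter: int = 200   # reserved; anchor filtering is inactive by design
    k_score: int = 30
    k_weight: int = 100
    n_features: int = 3000


@dataclass
class ClusterSection:
    n_pcs: int = 30
    k: int = 20
    resolution: float = 0.8


@dataclass
class ScoringSection:
    scale: float = 10000.0


@dataclass
class MarkersSection:
    min_pct: float = 0.1
    logfc_min: float = 0.25
    correction: str = "bonferroni"
    top_n: int = 10


@dataclass
class DirectSection:
    isg_quantile: float = 0.95     # "high ISG" = median above this quantile
    blocked_fraction: float = 0.8  # cluster must be mostly blocked-condition
    k_panel: int = 4
    against: str = "condition2"    # or "isgneg"


@dataclass
class RunConfig:
    simulate: GeneratorConfig = field(default_factory=GeneratorConfig)
    qc: QCSection = field(default_factory=QCSection)
    hvg: HVGSection = field(default_factory=HVGSection)
    integration: IntegrationSection = field(default_factory=IntegrationSection)
    cluster: ClusterSection = field(default_factory=ClusterSection)
    scoring: ScoringSection = field(default_factory=ScoringSection)
    markers: MarkersSection = field(default_factory=MarkersSection)
    direct: DirectSection = field(default_factory=DirectSection)
    seed: int = 0
    out_dir: str = "ifndirect_out"


class ConfigError(ValueError):
    pass


def _coerce(value, typ, path: str):
    """Validate a YAML scalar against the dataclass field type."""
    if typ is float:
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ConfigError(f"{path}: expected a number, got {value!r}")
        return float(value)
    if typ is int:
        if isinstance(value, bool) or not isinstance(value, int):
            raise ConfigError(f"{path}: expected an integer, got {value!r}")
        return int(value)
    if typ is bool:
        if not isinstance(value, bool):
            raise ConfigError(f"{path}: expected a boolean, got {value!r}")
        return value
    if typ is str:
        if not isinstance(value, str):
            raise ConfigError(f"{path}: expected a string, got {value!r}")
        return value
    if typ is dict:
        if not isinstance(value, dict):
            raise ConfigError(f"{path}: expected a mapping, got {value!r}")
        return dict(value)
    return value


def _build(dc_type, data: dict, path: str = ""):
    if not isinstance(data, dict):
        raise ConfigError(f"{path or 'config'}: expected a mapping, "
                          f"got {data!r}")
    hints = get_type_hints(dc_type)
    fields = {f.name: f for f in dataclasses.fields(dc_type)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(
            f"unknown config key(s) {sorted(unknown)} under "
            f"'{path or '<root>'}'")
    kwargs = {}
    for name, value in data.items():
        sub = f"{path}.{name}" if path else name
        typ = hints[name]
        if dataclasses.is_dataclass(typ):
            kwargs[name] = _build(typ, value, sub)
        else:
            kwargs[name] = _coerce(value, typ, sub)
    return dc_type(**kwargs)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run config; missing keys take defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    return _build(RunConfig, data)


def config_to_dict(cfg: RunConfig) -> dict:
    return dataclasses.asdict(cfg)


def dump_config(cfg: RunConfig, path) -> Path:
    """Echo the fully-resolved config; re-loading it reproduces ``cfg``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)
    return path
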