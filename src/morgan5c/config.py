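"""Run configuration: namespaced sections with the pipeline defaults,
loadable from YAML or JSON, with unknown keys rejected so typos cannot
silently fall back to defaults."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .types import MorganError


@dataclass
class AggregationConfig:
    method: str = "pooled"  # or "mean"


@dataclass
class DEConfig:
    enabled: bool = False
    p_max: float = 0.01
    min_fold: float = 2.0
    pseudocount: float = 1.0
    use_adjusted: bool = False


@dataclass
class CorrelateConfig:
    threshold: float = 0.6
    sign: str = "positive"
    n_min: int = 5
    group: str | None = None


@dataclass
class GMMConfig:
    tol: float = 1e-8
    max_iter: int = 500
    var_floor: float = 1e-6
    G_max: int = 3


@dataclass
class DMConfig:
    o_mode: str = "occupancy_entropy"
    eps: float = 1e-6
    missing_group_policy: str = "group_global_mean"
    top_n: int = 10


@dataclass
class StatsConfig:
    universe: str = "annotation"  # or "expression"
    exact_max_n: int = 8
    deduplicate_sites: bool = False


@dataclass
class AnnotateConfig:
    priority: tuple[str, ...] = ("cds", "three_prime_utr", "five_prime_utr", "intron")


@dataclass
class MotifConfig:
    down: int = 4
    top_k: int = 10


@dataclass
class FilterConfig:
    max_zero_fraction: float = 0.25


@dataclass
class RunConfig:
    aggregation: AggregationConfig = field(default_factory=AggregationConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    de: DEConfig = field(default_factory=DEConfig)
    correlate: CorrelateConfig = field(default_factory=CorrelateConfig)
    gmm: GMMConfig = field(default_factory=GMMConfig)
    dm: DMConfig = field(default_factory=DMConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    annotate: AnnotateConfig = field(default_factory=AnnotateConfig)
    motif: MotifConfig = field(default_factory=MotifConfig)

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        cfg = cls()
        sections = {f.name: f for f in dataclasses.fields(cls)}
        for section, values in (data or {}).items():
            if section not in sections:
                raise MorganError(
                    f"unknown config section {section!r}; known: {sorted(sections)}"
                )
            target = getattr(cfg, section)
            known = {f.name for f in dataclasses.fields(target)}
            for key, value in (values or {}).items():
                if key not in known:
                    raise MorganError(
                        f"unknown config key {section}.{key}; known: {sorted(known)}"
                    )
                if isinstance(value, list):
                    value = tuple(value)
                setattr(target, key, value)
        return cfg

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            if path.suffix == ".json":
                data = json.load(fh)
            else:
                data = yaml.safe_load(fh)
        return cls.from_mapping(data or {})

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
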