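"""Pipeline configuration: nested, defaulted, and strict about unknown keys."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, is_dataclass
from typing import Any

import yaml

from .postprocess import DEFAULT_RULES, Clause, RegionRule


@dataclass
class PreprocessConfig:
    equalize: bool = True
    sigma: float = 1.0
    n_levels: int = 256


@dataclass
class SlicConfig:
    # k=None scales the superpixel count with image area, matching the
    # ~9500-superpixels-per-512x512-section operating regime
    k: int | None = None
    compactness: float = 0.1
    n_iters: int = 10
    distance_form: str = "linear"
    min_size: int | None = None

    def resolve_k(self, n_pixels: int) -> int:
        if self.k is not None:
            return self.k
        return max(1, round(9500 * n_pixels / (512 * 512)))


@dataclass
class HlfConfig:
    entropy_bins: int = 32
    samples_per_superpixel: int = 1


@dataclass
class ForestConfig:
    n_trees: int = 100


@dataclass
class PostprocessConfig:
    method: str = "otsu"
    max_iters: int = 10
    rules: tuple[Clause, ...] = DEFAULT_RULES


@dataclass
class MetricsConfig:
    tolerance_px: float = 2.0
    n_thresholds: int = 256


@dataclass
class PipelineConfig:
    seed: int = 0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    slic: SlicConfig = field(default_factory=SlicConfig)
    hlf: HlfConfig = field(default_factory=HlfConfig)
    forest: ForestConfig = field(default_factory=ForestConfig)
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["postprocess"]["rules"] = _rules_to_plain(self.postprocess.rules)
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        return _build(cls, data, path="")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def _rules_to_plain(rules) -> list:
    out = []
    for clause in rules:
        parts = clause if isinstance(clause, tuple) else (clause,)
        out.append(
            [
                {"property": r.property, "op": r.comparator, "value": r.threshold}
                for r in parts
            ]
        )
    return out


def _rules_from_plain(data) -> tuple[Clause, ...]:
    rules = []
    for clause in data:
        parts = clause if isinstance(clause, list) else [clause]
        built = tuple(
            RegionRule(p["property"], p["op"], float(p["value"])) for p in parts
        )
        rules.append(built if len(built) > 1 else built[0])
    return tuple(rules)


def _build(cls, data: dict[str, Any], path: str):
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        where = path or "config"
        raise ValueError(f"unknown {where} keys: {sorted(unknown)}")
    defaults = cls()
    kwargs = {}
    for name, value in data.items():
        if name == "rules":
            kwargs[name] = _rules_from_plain(value)
        elif isinstance(value, dict):
            current = getattr(defaults, name)
            if not is_dataclass(current):
                raise ValueError(f"key {path}{name} does not take a mapping")
            kwargs[name] = _build(type(current), value, path=f"{path}{name}.")
        else:
            kwargs[name] = value
    return cls(**kwargs)
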