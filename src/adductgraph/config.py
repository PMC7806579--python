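"""Run configuration: annotation sets, filters and I/O options from YAML.

Unknown keys are rejected with the list of accepted ones, so typos fail loudly
instead of silently running with defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Mapping

import yaml

from .chem import DEFAULT_DELTA_NAMES, DEFAULT_MAX_DEPTH, DELTA_REGISTRY, expand_species_closure
from .filters import FilterConfig

__all__ = ["AnnotationConfig", "IOConfig", "RunConfig", "load_run_config", "default_run_config"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class AnnotationConfig:
    """The annotation set and matching parameters.

    ``deltas`` are registry names; ``max_mult`` overrides per-delta stacking
    caps; ``tolerance_mmu`` is the absolute matching tolerance in mmu.
    """

    deltas: tuple[str, ...] = DEFAULT_DELTA_NAMES
    max_depth: int = DEFAULT_MAX_DEPTH
    multimers: tuple[int, ...] = (1, 2, 3)
    tolerance_mmu: float = 10.0
    max_mult: Mapping[str, int] = field(default_factory=dict)
    polarity: str = "positive"

    def __post_init__(self) -> None:
        if self.polarity != "positive":
            raise ConfigError(
                "only positive-mode annotation sets are shipped; the tool is "
                "currently focused on singly charged positive ions"
            )
        if self.tolerance_mmu <= 0:
            raise ConfigError("tolerance_mmu must be positive")
        for name in self.deltas:
            if name not in DELTA_REGISTRY:
                raise ConfigError(
                    f"unknown delta {name!r}; known: {sorted(DELTA_REGISTRY)}"
                )
        object.__setattr__(self, "deltas", tuple(self.deltas))
        object.__setattr__(self, "multimers", tuple(int(n) for n in self.multimers))

    @property
    def tolerance(self) -> float:
        """Tolerance in Da."""
        return self.tolerance_mmu / 1000.0

    def closure(self):
        return expand_species_closure(
            self.deltas, self.max_depth, self.multimers, dict(self.max_mult)
        )


@dataclass(frozen=True)
class IOConfig:
    output_dir: str = "."
    graph_format: str = "graphml"

    def __post_init__(self) -> None:
        if self.graph_format not in ("graphml", "dot", "none"):
            raise ConfigError("graph_format must be one of graphml, dot, none")


@dataclass(frozen=True)
class RunConfig:
    filter: FilterConfig = field(default_factory=FilterConfig)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    io: IOConfig = field(default_factory=IOConfig)
    seed: int = 0


def _build(cls, data: Mapping[str, Any], context: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in {context} section; "
            f"accepted: {sorted(fields)}"
        )
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list):
            v = tuple(v)
        coerced[f.name] = v
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {context} section: {exc}") from exc


def load_run_config(source: str | Mapping[str, Any]) -> RunConfig:
    """Load a run configuration from a YAML path or a mapping."""
    if isinstance(source, str):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(source)
    if not isinstance(data, Mapping):
        raise ConfigError("run config must be a mapping")
    known = {"filter", "annotation", "io", "seed"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(
            f"unknown top-level key(s) {sorted(unknown)}; accepted: {sorted(known)}"
        )
    return RunConfig(
        filter=_build(FilterConfig, data.get("filter", {}) or {}, "filter"),
        annotation=_build(AnnotationConfig, data.get("annotation", {}) or {}, "annotation"),
        io=_build(IOConfig, data.get("io", {}) or {}, "io"),
        seed=int(data.get("seed", 0)),
    )


def default_run_config() -> RunConfig:
    """The shipped defaults (data/default_positive.yaml)."""
    ref = resources.files("adductgraph").joinpath("data/default_positive.yaml")
    with resources.as_file(ref) as path:
        return load_run_config(str(path))
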