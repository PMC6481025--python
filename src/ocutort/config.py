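"""Pipeline configuration: one YAML file drives the whole run.

Unknown keys are rejected so typos fail loudly rather than silently
falling back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
import yaml

from .metrics import MetricConfig
from .stats import StatsConfig
from .synth import CohortParams
from .trace import TraceConfig

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    """Everything a full run needs, serializable to a single YAML file."""

    metrics: MetricConfig = field(default_factory=MetricConfig)
    tracing: TraceConfig = field(default_factory=TraceConfig)
    cohort: CohortParams = field(default_factory=CohortParams)
    stats: StatsConfig = field(default_factory=StatsConfig)
    #: "centerline" computes metrics on generated centerlines; "raster"
    #: additionally rasterizes each segment and re-traces it.
    trace_mode: str = "centerline"
    rng_seed: int = 0
    output_dir: str = "ocutort_out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.trace_mode not in ("centerline", "raster"):
            raise ValueError("trace_mode must be 'centerline' or 'raster'")


_SECTIONS = {
    "metrics": MetricConfig,
    "tracing": TraceConfig,
    "cohort": CohortParams,
    "stats": StatsConfig,
}
_SCALARS = ("trace_mode", "rng_seed", "output_dir", "log_level")


def _build_section(cls, data: dict):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {cls.__name__}: {sorted(unknown)}")
    kwargs = dict(data)
    for f in dataclasses.fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            # YAML has no tuples; restore them where the dataclass expects one
            default = getattr(cls(), f.name, None) if cls is not CohortParams else None
            kwargs[f.name] = tuple(kwargs[f.name])
    return cls(**kwargs)


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline config, rejecting unknown keys."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    unknown = set(data) - set(_SECTIONS) - set(_SCALARS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in data:
            kwargs[name] = _build_section(cls, data[name] or {})
    for name in _SCALARS:
        if name in data:
            kwargs[name] = data[name]
    return PipelineConfig(**kwargs)


def save_config(cfg: PipelineConfig, path) -> None:
    """Write the config back as YAML (lossless round trip)."""
    data = {
        name: dataclasses.asdict(getattr(cfg, name)) for name in _SECTIONS
    }
    for name in _SCALARS:
        data[name] = getattr(cfg, name)

    def _clean(obj):
        if isinstance(obj, tuple):
            return [_clean(v) for v in obj]
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, list):
            return [_clean(v) for v in obj]
        return obj

    Path(path).write_text(yaml.safe_dump(_clean(data), sort_keys=False))
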