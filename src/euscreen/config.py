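"""YAML configuration for the simulator and analysis thresholds."""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any

import yaml

from .screen_model import LayoutConfig
from .synthetic import SimulationConfig


@dataclasses.dataclass
class AnalysisConfig:
    """Thresholds for clean-up and normalization, overridable from YAML."""

    mode: str = "primary"
    max_cytoplasmic_fraction: float = 0.20
    dapi_outlier_k: float = 4.0
    well_range_threshold: float = 1.5
    mad_factor: float = 3.0
    iqr_k: float = 1.5
    background: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"DAPI": 0.0, "EU": 0.0, "PCNA": 0.0, "SE": 0.0})
    hit_cutoff: float = 0.85
    min_viable_cells: int = 500


def _from_mapping(cls, data: dict[str, Any]):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML file with optional ``simulation``, ``layout`` and
    ``analysis`` sections into the corresponding config objects."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out: dict[str, Any] = {}
    layout = None
    if "layout" in raw:
        layout = _from_mapping(LayoutConfig, raw["layout"])
        out["layout"] = layout
    if "simulation" in raw:
        sim = dict(raw["simulation"])
        for key in ("cycle_fractions", "size_phase_factors", "eu_phase_factors"):
            if key in sim:
                sim[key] = tuple(sim[key])
        if layout is not None:
            sim.setdefault("layout", layout)
        out["simulation"] = _from_mapping(SimulationConfig, sim)
    if "analysis" in raw:
        out["analysis"] = _from_mapping(AnalysisConfig, raw["analysis"])
    return out
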