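"""Pipeline configuration: YAML loading, validation, provenance hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import List, Optional

import yaml

from .errors import ConfigError
from .io import PISUM, SOLANUM, StandardDef

__all__ = ["PipelineConfig", "load_config", "config_hash"]


def _strict(cls, data: dict, where: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {where}: {exc}") from exc


@dataclass
class BinningConfig:
    n_channels: int = 1024
    gain: float = 1.0

    def __post_init__(self):
        if self.n_channels < 64:
            raise ConfigError("binning.n_channels must be >= 64")
        if self.gain <= 0:
            raise ConfigError("binning.gain must be > 0")


@dataclass
class DetectionConfig:
    smooth_window: int = 9
    min_peak_events: int = 100
    cv_max: float = 0.10
    min_amplitude: float = 2.0

    def __post_init__(self):
        if self.smooth_window < 3 or self.smooth_window % 2 == 0:
            raise ConfigError("detection.smooth_window must be odd and >= 3")
        if self.min_peak_events < 1:
            raise ConfigError("detection.min_peak_events must be >= 1")
        if not 0 < self.cv_max < 1:
            raise ConfigError("detection.cv_max must lie in (0, 1)")


@dataclass
class PEConfig:
    p_mode: str = "regression"
    progression_tol: float = 0.02
    standard: str = PISUM.name

    def __post_init__(self):
        if self.p_mode not in ("regression", "first_two"):
            raise ConfigError("pe.p_mode must be 'regression' or 'first_two'")
        if not 0 < self.progression_tol < 0.5:
            raise ConfigError("pe.progression_tol must lie in (0, 0.5)")


@dataclass
class DelineationConfig:
    p_tol: float = 0.10
    gs_hybrid_dev: float = 0.15
    diploid_p_bound: float = 4.0
    p_diploid_ref: Optional[float] = None
    base_ploidy: int = 2

    def __post_init__(self):
        if not 0 < self.p_tol < 0.5:
            raise ConfigError("delineation.p_tol must lie in (0, 0.5)")
        if not 0 < self.gs_hybrid_dev < 1:
            raise ConfigError("delineation.gs_hybrid_dev must lie in (0, 1)")
        if self.diploid_p_bound <= 0:
            raise ConfigError("delineation.diploid_p_bound must be > 0")


@dataclass
class SummaryConfig:
    alpha: float = 0.05
    hsd_unit: str = "individual"

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ConfigError("summary.alpha must lie in (0, 1)")
        if self.hsd_unit not in ("individual", "population"):
            raise ConfigError("summary.hsd_unit must be individual|population")


@dataclass
class PipelineConfig:
    standards: List[StandardDef] = field(
        default_factory=lambda: [PISUM, SOLANUM]
    )
    binning: BinningConfig = field(default_factory=BinningConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    pe: PEConfig = field(default_factory=PEConfig)
    delineation: DelineationConfig = field(default_factory=DelineationConfig)
    summary: SummaryConfig = field(default_factory=SummaryConfig)
    seed: int = 0

    def standard_by_name(self, name: str) -> StandardDef:
        for s in self.standards:
            if s.name == name:
                return s
        raise ConfigError(f"standard {name!r} not defined in config")


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    known = {
        "standards",
        "binning",
        "detection",
        "pe",
        "delineation",
        "summary",
        "seed",
    }
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown top-level config key(s) {sorted(unknown)}")
    standards = [PISUM, SOLANUM]
    if "standards" in raw:
        standards = []
        for item in raw["standards"]:
            standards.append(
                _strict(StandardDef, dict(item), "standards entry")
            )
    return PipelineConfig(
        standards=standards,
        binning=_strict(BinningConfig, raw.get("binning", {}), "binning"),
        detection=_strict(DetectionConfig, raw.get("detection", {}), "detection"),
        pe=_strict(PEConfig, raw.get("pe", {}), "pe"),
        delineation=_strict(
            DelineationConfig, raw.get("delineation", {}), "delineation"
        ),
        summary=_strict(SummaryConfig, raw.get("summary", {}), "summary"),
        seed=int(raw.get("seed", 0)),
    )


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash of the full configuration, for provenance headers."""
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]
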