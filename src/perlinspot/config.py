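"""Pipeline configuration: YAML loading with strict schema validation.

Every section validates against its dataclass fields; unknown keys are
rejected by name (misspelled keys never silently fall back to defaults).
An empty file yields the full default configuration: 8.7 cm images at
40 px/cm, 30 pairs at strengths 40/50/60, the published observer
calibration targets, and the published chance-model geometry.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import stimuli
from .observer import ObserverParams
from .scoring import AREA_CONVENTIONS
from .stimuli import FORMAT_NAMES


class ConfigError(ValueError):
    """Configuration schema violation; message names the offending field."""


@dataclass
class StimulusConfig:
    side_cm: float = stimuli.DEFAULT_SIDE_CM
    scale_px_per_cm: float = stimuli.DEFAULT_SCALE_PX_PER_CM
    grid_cells: int = stimuli.DEFAULT_GRID_CELLS
    strengths: list[int] = field(default_factory=lambda: list(stimuli.DEFAULT_STRENGTHS))
    n_pairs: int = 30
    sigma_cm: float = stimuli.DEFAULT_SIGMA_CM
    margin_cm: float = stimuli.DEFAULT_MARGIN_CM
    screening_threshold: float = stimuli.DEFAULT_ANISOTROPY_THRESHOLD
    seed: int = 0


@dataclass
class ObserverConfig:
    p_cb: dict[str, float] = field(default_factory=lambda: ObserverParams().p_cb)
    m_total: dict[str, float] = field(default_factory=lambda: ObserverParams().m_total)
    median_s: dict[str, float] = field(default_factory=lambda: ObserverParams().median_s)
    sd_log: float = 0.5
    sigma_mark_cm: float = 0.3
    loading: dict[str, float] = field(default_factory=lambda: ObserverParams().loading)
    eta: float = 0.9
    strength_multiplier: dict[int, float] = field(
        default_factory=lambda: ObserverParams().strength_multiplier)
    p_chance_hit: float | None = None  # None: derive from the scoring section
    n_participants: int = 30
    seed: int = 0

    def to_params(self, p_chance_hit: float) -> ObserverParams:
        p = self.p_chance_hit if self.p_chance_hit is not None else p_chance_hit
        return ObserverParams(
            p_cb=dict(self.p_cb), m_total=dict(self.m_total),
            median_s=dict(self.median_s), sd_log=self.sd_log,
            sigma_mark_cm=self.sigma_mark_cm, loading=dict(self.loading),
            eta=self.eta,
            strength_multiplier={int(k): float(v) for k, v in self.strength_multiplier.items()},
            p_chance_hit=p, seed=self.seed,
        )


@dataclass
class ScoringConfig:
    aoi_radius_cm: float = 1.0
    image_side_cm: float = 8.7
    area_convention: str = "paper"
    n_trials: int = 30
    alpha: float = 0.05

    def __post_init__(self):
        if self.area_convention not in AREA_CONVENTIONS:
            raise ConfigError(f"scoring.area_convention: unknown value {self.area_convention!r}")


@dataclass
class InferenceConfig:
    cauchy_scale: float = 0.7071067811865476
    kappa: float = 1.0
    alpha: float = 0.05
    sphericity: str = "none"
    adjustment: str = "none"

    def __post_init__(self):
        if self.sphericity not in ("none", "gg"):
            raise ConfigError(f"inference.sphericity: unknown value {self.sphericity!r}")
        if self.adjustment not in ("none", "holm"):
            raise ConfigError(f"inference.adjustment: unknown value {self.adjustment!r}")


@dataclass
class OutputConfig:
    directory: str = "perlinspot_out"


@dataclass
class PipelineConfig:
    stimulus: StimulusConfig = field(default_factory=StimulusConfig)
    observer: ObserverConfig = field(default_factory=ObserverConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    output: OutputConfig = field(default_factory=OutputConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


_SECTIONS = {
    "stimulus": StimulusConfig,
    "observer": ObserverConfig,
    "scoring": ScoringConfig,
    "inference": InferenceConfig,
    "output": OutputConfig,
}


def _build_section(name: str, cls, data: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in section {name!r}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        fld = next(f for f in dataclasses.fields(cls) if f.name == key)
        if key in ("p_cb", "m_total", "median_s", "loading") and isinstance(value, (list, tuple)):
            value = dict(zip(FORMAT_NAMES, value))
        kwargs[fld.name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"section {name!r}: {exc}") from exc


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration.

    ``None`` or an empty file produce the all-defaults configuration.
    Unknown section names or keys raise :class:`ConfigError` naming them.
    """
    if path is None:
        return PipelineConfig()
    raw = Path(path).read_text()
    data = yaml.safe_load(raw)
    if data is None:
        return PipelineConfig()
    if not isinstance(data, dict):
        raise ConfigError("top level of the config must be a mapping of sections")
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown section(s): {sorted(unknown)}")
    sections = {}
    for name, cls in _SECTIONS.items():
        payload = data.get(name, {})
        if payload is None:
            payload = {}
        if not isinstance(payload, dict):
            raise ConfigError(f"section {name!r} must be a mapping")
        sections[name] = _build_section(name, cls, payload)
    return PipelineConfig(**sections)
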