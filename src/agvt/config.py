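"""Pipeline configuration: defaults, YAML/JSON parsing, validation."""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .enhancement import DEFAULT_SCALES
from .refinement import RefinementParams
from .seeds import SeedParams
from .tracking import TrackingParams

__all__ = ["PipelineConfig", "EnhancementConfig", "ConfigError",
           "parse_config"]


class ConfigError(ValueError):
    """Invalid or unknown configuration key/value."""


@dataclass
class EnhancementConfig:
    scales: tuple[float, ...] = DEFAULT_SCALES
    alpha: float = 0.5
    beta: float | None = None     # None -> per-scale automatic beta
    gamma: float = 1.0
    polarity: str = "dark"


@dataclass
class PipelineConfig:
    enhancement: EnhancementConfig = field(default_factory=EnhancementConfig)
    seeds: SeedParams = field(default_factory=SeedParams)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    refinement: RefinementParams = field(default_factory=RefinementParams)
    seed: int | None = None       # master RNG seed (simulation, shuffling)
    verbosity: int = 1

    def validate(self) -> "PipelineConfig":
        enh, sd, tr, rf = (self.enhancement, self.seeds, self.tracking,
                           self.refinement)
        checks = [
            (len(enh.scales) > 0 and all(s > 0 for s in enh.scales),
             "enhancement.scales"),
            (enh.alpha > 0, "enhancement.alpha"),
            (enh.beta is None or enh.beta > 0, "enhancement.beta"),
            (enh.polarity in ("dark", "bright"), "enhancement.polarity"),
            (0 <= sd.tau < 1, "seeds.tau"),
            (0 <= sd.tau_rect < 1, "seeds.tau_rect"),
            (sd.circle_radius > 0, "seeds.circle_radius"),
            (0 < sd.delta_theta <= math.pi, "seeds.delta_theta"),
            (sd.rect_lx >= 1 and sd.rect_ly >= 1, "seeds.rect_lx/rect_ly"),
            (sd.order in ("intensity", "shuffle"), "seeds.order"),
            (tr.step_min > 0 and tr.step_max >= tr.step_min,
             "tracking.step_min/step_max"),
            (0 < tr.delta_theta <= math.pi, "tracking.delta_theta"),
            (0 < tr.bif_fraction <= 1, "tracking.bif_fraction"),
            (tr.bif_sep_deg > 0, "tracking.bif_sep_deg"),
            (tr.profile_step > 0, "tracking.profile_step"),
            (rf.merge_tol >= 0, "refinement.merge_tol"),
            (rf.min_length >= 0, "refinement.min_length"),
            (rf.keep_top >= 1, "refinement.keep_top"),
        ]
        for ok, key in checks:
            if not ok:
                raise ConfigError(f"invalid value for config key {key}")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["enhancement"]["scales"] = list(self.enhancement.scales)
        return d

    def dump(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _merge_section(obj, data: dict, section: str) -> None:
    known = {f.name for f in fields(obj)}
    for key, value in data.items():
        if key not in known:
            raise ConfigError(f"unknown config key {section}.{key}")
        if key == "scales":
            value = tuple(float(v) for v in value)
        setattr(obj, key, value)


def config_from_dict(data: dict | None) -> PipelineConfig:
    cfg = PipelineConfig()
    if not data:
        return cfg.validate()
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    sections = {"enhancement": cfg.enhancement, "seeds": cfg.seeds,
                "tracking": cfg.tracking, "refinement": cfg.refinement}
    for key, value in data.items():
        if key in sections:
            if not isinstance(value, dict):
                raise ConfigError(f"config section {key} must be a mapping")
            _merge_section(sections[key], value, key)
        elif key == "seed":
            cfg.seed = value
        elif key == "verbosity":
            cfg.verbosity = int(value)
        else:
            raise ConfigError(f"unknown config key {key}")
    return cfg.validate()


def parse_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML or JSON config file; defaults merged, keys validated."""
    if path is None:
        return PipelineConfig().validate()
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        data = json.loads(text) if text.strip() else {}
    else:
        data = yaml.safe_load(text) or {}
    return config_from_dict(data)
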