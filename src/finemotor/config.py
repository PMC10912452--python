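"""Run configuration: schema, defaults, YAML loading and validation."""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["RunConfig", "ConfigError", "validate_config"]


class ConfigError(ValueError):
    """Raised with a list of all validation problems found."""


@dataclass
class RunConfig:
    n_subjects: int = 20
    rng_seed: int = 0
    out_dir: str = "finemotor_out"
    movement_types: list = field(
        default_factory=lambda: ["finger_tapping", "pronation_supination"]
    )
    # detection overrides (None = use the movement-type preset)
    rms_percentile: float | None = None
    jerk_percentile: float | None = None
    prominence_sd: float = 2.5
    min_peak_distance_ms: float = 100.0
    merge_gap_ms: float = 25.0
    min_event_duration_ms: float = 5.0
    # simulation overrides keyed by movement type
    simulation: dict = field(default_factory=dict)
    # factor-model thresholds
    loading_threshold: float = 0.70
    rmsea_max: float = 0.06
    cfi_min: float = 0.95
    srmr_max: float = 0.08
    fit_gated_pruning: bool = False
    # artifact screening
    clip_bound: float = 200.0

    def validate(self) -> None:
        problems = []
        if self.n_subjects < 2:
            problems.append(
                "n_subjects must be >= 2 (mixed models need multiple subjects)"
            )
        for name in ("rms_percentile", "jerk_percentile"):
            value = getattr(self, name)
            if value is not None and not 0 < value < 100:
                problems.append(f"{name}={value} out of range (0, 100)")
        for name in ("loading_threshold", "rmsea_max", "cfi_min", "srmr_max"):
            value = getattr(self, name)
            if not 0 < value < 1:
                problems.append(f"{name}={value} out of range (0, 1)")
        for name in ("prominence_sd", "min_peak_distance_ms", "merge_gap_ms"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        unknown_types = set(self.movement_types) - {
            "finger_tapping",
            "pronation_supination",
        }
        if unknown_types:
            problems.append(f"unknown movement type(s): {sorted(unknown_types)}")
        if problems:
            raise ConfigError("; ".join(problems))

    def as_dict(self) -> dict:
        return asdict(self)


def validate_config(path: str | os.PathLike | None = None, **overrides) -> RunConfig:
    """Load a YAML config file, fill defaults and reject unknown keys."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ConfigError(f"{path}: config must be a mapping")
            raw.update(loaded)
    raw.update({k: v for k, v in overrides.items() if v is not None})
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    config = RunConfig(**raw)
    config.validate()
    return config
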