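"""Run configuration: window endpoints, BSA formula, imputation and model
settings. Loadable from YAML; every field has the pipeline default."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class WindowConfig:
    """Time windows (hours from ICU admission) for the derived features.

    Boundary semantics are fixed so that a t = 36 h event is counted in
    exactly one of the two balance windows: the initial-hematocrit window is
    closed on both ends, every later window is left-open/right-closed.
    """

    initial_hct: tuple[float, float] = (-12.0, 18.0)   # closed [lo, hi]
    final_hct: tuple[float, float] = (18.0, 36.0)      # half-open (lo, hi]
    net_balance: tuple[float, float] = (-6.0, 36.0)    # closed [lo, hi]
    outcome_balance: tuple[float, float] = (36.0, 84.0)  # half-open (lo, hi]


@dataclass
class ModelConfig:
    """Settings for the additive and quartile association models."""

    spline_df: int = 10          # basis dimension of the VLI smooth
    spline_degree: int = 3
    alpha: float | None = None   # smoothing penalty; None = select by GCV
    ci_level: float = 0.95
    grid_size: int = 100         # partial-effect evaluation grid

    def __post_init__(self) -> None:
        if not (0.5 < self.ci_level < 1):
            raise ValueError("ci_level must lie in (0.5, 1)")
        if self.spline_df < self.spline_degree + 2:
            raise ValueError("spline_df too small for the requested degree")


@dataclass
class RunConfig:
    """End-to-end analysis configuration."""

    windows: WindowConfig = field(default_factory=WindowConfig)
    bsa_formula: str = "dubois"          # or "mosteller"
    tail_fraction: float = 0.05          # VLI tail imputation fraction
    impute_per_cohort: bool = True       # impute within each analysis cohort
    min_age: float = 16.0                # demographic plausibility screen
    height_range: tuple[float, float] = (100.0, 250.0)
    weight_range: tuple[float, float] = (20.0, 350.0)
    model: ModelConfig = field(default_factory=ModelConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.tail_fraction <= 0.25):
            raise ValueError("tail_fraction must lie in [0, 0.25]")
        if self.bsa_formula not in ("dubois", "mosteller"):
            raise ValueError("bsa_formula must be 'dubois' or 'mosteller'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "windows" in d and isinstance(d["windows"], dict):
            d["windows"] = WindowConfig(
                **{k: tuple(v) for k, v in d["windows"].items()}
            )
        if "model" in d and isinstance(d["model"], dict):
            d["model"] = ModelConfig(**d["model"])
        for key in ("height_range", "weight_range"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)
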