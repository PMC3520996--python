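"""Pipeline configuration: one YAML-serializable object holding the
domain geometry, scenario definitions, model and threshold settings, and
per-stage seeds."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "default_config"]


@dataclass
class PipelineConfig:
    # domain geometry (fine grid)
    n_lon: int = 120
    n_lat: int = 60
    resolution: float = 0.01
    lon_origin: float = 130.0
    lat_origin: float = -37.0

    # scenarios: °C warming per decade; Reference (WRE750) reaches
    # ~1.1 °C by 2100, Policy (LEV1) ~0.5 °C under the linear trajectory
    scenarios: dict = field(default_factory=lambda: {"WRE750": 0.11, "LEV1": 0.05})
    policy_shape: str = "linear"           # or "peak_decline"
    decades: list = field(default_factory=lambda: [2010, 2050, 2100])

    # climate-model ensemble
    n_models: int = 6
    ensemble_k: int = 5
    gcm_spread_sd: float = 0.15
    outlier_bias: float = 3.0
    mid_resolution: float = 0.5
    coarse_resolution: float = 2.5

    # baseline climatology
    baseline_noise_sd: float = 0.3
    tps_knots: int = 300

    # SDM settings
    n_surveys: int = 800
    glm_family: str = "negbin"             # or "poisson"
    response_shapes: dict = field(default_factory=lambda: {"A": "linear",
                                                           "B": "quadratic"})
    brt: dict = field(default_factory=lambda: {"tree_depth": 3,
                                               "learning_rate": 0.01,
                                               "n_trees": 2000,
                                               "bag_fraction": 0.5})
    weight_scheme: str = "deviance"        # or "equal"
    validation_fraction: float = 0.2

    # thresholds
    ground_threshold: float = 20.0         # individuals per 100 m²
    march_bins: list = field(default_factory=lambda: [17.0, 20.0])
    distribution_cutoff: float = 0.5       # per 100 m², "current distribution"

    # mortality experiment conditions: group means/SDs (%) at the lower
    # and upper March temperature categories, tanks per group
    mortality_means: list = field(default_factory=lambda: [3.1, 58.12])
    mortality_sds: list = field(default_factory=lambda: [6.2, 17.2])
    mortality_labels: list = field(default_factory=lambda: ["17C", "20C"])
    n_tanks: int = 4

    # bookkeeping
    seed: int = 1
    outdir: str = "abaclim_out"
    raster_format: str = "netcdf"          # or "ascii-grid"

    def __post_init__(self) -> None:
        if self.ensemble_k > self.n_models:
            raise ValueError("ensemble_k cannot exceed n_models")
        if self.raster_format not in ("netcdf", "ascii-grid"):
            raise ValueError("raster_format must be 'netcdf' or 'ascii-grid'")
        if sorted(self.scenarios, key=self.scenarios.get, reverse=True)[0] != "WRE750" \
                and "WRE750" in self.scenarios and "LEV1" in self.scenarios:
            raise ValueError("Reference scenario must warm faster than Policy")

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the base seed."""
        offsets = {"synth": 0, "gcm": 101, "downscale": 202, "sdm": 303,
                   "range": 404, "overlay": 505, "mortality": 606}
        return (int(self.seed) * 1000 + offsets[stage]) % (2**31 - 1)

    # -- serialization --------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def default_config(**overrides) -> PipelineConfig:
    return PipelineConfig(**overrides)
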