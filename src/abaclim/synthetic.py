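"""Synthetic study system: coastal SST climatologies, GCM anomaly fields,
abundance surveys, and juvenile-mortality replicates.

Every generator is a pure function of its parameters and a seed, so the
whole pipeline is testable without any satellite, climate-model or survey
download.  The generators encode a known ground truth
(:class:`SyntheticTruth`): species A ("blacklip") abundance responds
log-linearly to August SST, species B ("greenlip") has a hump-shaped
(quadratic-on-the-log-scale) response with a thermal optimum; warming per
decade differs between a high-emissions Reference scenario and a
mitigation Policy scenario; March SST is the August field plus a smooth,
spatially varying summer offset so the thermal-overlay stage sees
coherent August/March pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import GridGeometry, GridStack, RasterGrid

__all__ = [
    "SyntheticTruth",
    "SurveySet",
    "study_domain",
    "baseline_surface",
    "generate_baseline",
    "generate_gcm_anomalies",
    "generate_gcm_historical",
    "generate_surveys",
    "generate_mortality",
]

#: documented emulation ranges for covariates the source surveys do not
#: constrain: harvest intensity is a dimensionless index in [0, 1],
#: distance to the nearest boat launch in km
HARVEST_RANGE = (0.0, 1.0)
DIST_LAUNCH_RANGE = (0.0, 50.0)
DEPTH_RANGE = (5.0, 30.0)  # m, survey depth band


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameters of the synthetic study system.

    Abundance follows a log-link count model: for species A,
    ``log mu = a0 + a1*sst + covariates``; for species B,
    ``log mu = b0 + b1*sst + b2*sst^2 + covariates`` with ``b2 < 0`` so
    the response is hump-shaped with optimum ``-b1/(2*b2)``.
    """

    #: (intercept, linear SST coefficient) for species A, log scale
    sdm_coeffs_A: tuple[float, float] = (-3.5, 0.45)
    #: (intercept, linear, quadratic SST coefficients) for species B;
    #: defaults put the thermal optimum at 17 °C
    sdm_coeffs_B: tuple[float, float, float] = (-39.5, 5.1, -0.15)
    #: effects of depth (per m), harvest intensity (per unit index),
    #: distance to launch (per km), log scale
    covariate_coeffs: tuple[float, float, float] = (-0.03, -0.4, 0.015)
    #: negative-binomial size parameter k (var = mu + mu^2/k); larger is
    #: closer to Poisson
    dispersion: float = 2.0
    #: °C warming per decade by scenario; Reference reaches ~1.1 °C by
    #: 2100, Policy ~0.5 °C under the default linear trajectory
    warming_per_decade: dict = field(
        default_factory=lambda: {"WRE750": 0.11, "LEV1": 0.05}
    )
    #: base August→March offset, °C; the full offset surface adds smooth
    #: west–east and coastward gradients on top of this
    march_offset: float = 1.2
    #: Policy trajectory shape: "linear" or "peak_decline" (warming peaks
    #: around 2080 and eases slightly by 2100)
    policy_shape: str = "linear"
    #: count family: "negbin" or "poisson"
    count_family: str = "negbin"

    def __post_init__(self) -> None:
        if self.sdm_coeffs_B[2] >= 0:
            raise ValueError("species B quadratic coefficient must be < 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        w = self.warming_per_decade
        if not w["WRE750"] > w["LEV1"] >= 0:
            raise ValueError("need warming(Reference) > warming(Policy) >= 0")

    def optimum_B(self) -> float:
        """Thermal optimum of the species-B response, °C."""
        _, b1, b2 = self.sdm_coeffs_B
        return -b1 / (2.0 * b2)

    def scenario_anomaly(self, scenario: str, decade: int) -> float:
        """Domain-mean anomaly (°C) at a decade under a scenario."""
        rate = self.warming_per_decade[scenario]
        t = (decade - 2000) / 10.0
        if scenario == "LEV1" and self.policy_shape == "peak_decline":
            # rises to rate*8 around 2080 then eases ~5% by 2100
            peak = 8.0
            if t <= peak:
                return rate * t
            return rate * peak * (1.0 - 0.05 * (t - peak) / 2.0)
        return rate * t


@dataclass
class SurveySet:
    """Georeferenced abundance survey records for one species.

    ``records`` columns: lon, lat, depth_m, harvest_intensity,
    dist_launch_km, sst_august, count_per_100m2.
    """

    records: pd.DataFrame
    species: str

    def __post_init__(self) -> None:
        counts = self.records["count_per_100m2"]
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not (self.records["depth_m"].between(*DEPTH_RANGE)).all():
            raise ValueError("depths must lie within the survey band")

    def __len__(self) -> int:
        return len(self.records)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, species: str) -> "SurveySet":
        return cls(records=pd.read_csv(path), species=species)


# ---------------------------------------------------------------------------
# domain and baseline climatology
# ---------------------------------------------------------------------------

def study_domain(
    n_lon: int = 120,
    n_lat: int = 60,
    resolution: float = 0.01,
    lon_origin: float = 130.0,
    lat_origin: float = -37.0,
) -> tuple[GridGeometry, np.ndarray]:
    """Rectangular coastal domain with a procedural coastline mask.

    Sea is a southern band whose northern limit (the coastline) wiggles
    smoothly with longitude, emulating a south-facing coast.  Returns
    ``(geometry, sea_mask)``.
    """
    geom = GridGeometry(n_lat=n_lat, n_lon=n_lon, lon_origin=lon_origin,
                        lat_origin=lat_origin, resolution=resolution)
    lon2d, lat2d = geom.meshgrid()
    lon_span = max(resolution * (n_lon - 1), resolution)
    u = (lon2d - lon_origin) / lon_span  # 0..1 west→east
    lat_extent = resolution * n_lat
    # coastline latitude: on average 70% up the domain, ±12% wiggle
    coast_lat = (
        lat_origin
        + lat_extent * (0.70 + 0.12 * np.sin(2 * np.pi * u) * np.cos(np.pi * u))
    )
    mask = lat2d < coast_lat
    return geom, mask


def baseline_surface(
    geometry: GridGeometry,
    month: str,
    truth: SyntheticTruth | None = None,
) -> np.ndarray:
    """Closed-form smooth climatology surface, no noise.

    August spans roughly 12.5–18 °C, warmest offshore (south-west) and
    coldest along the coast, so the greenlip-like 17 °C thermal optimum
    sits in the interior of the winter range.  March is the August
    surface plus a smooth offset that grows strongly toward the coast —
    shallow coastal water has the cold winters and hot summers of a
    gulf system — and spans roughly 15–22 °C.  The resulting structure
    matters downstream: winter warming expands suitable habitat toward
    the August-cold coastal band, which is exactly where March
    temperatures approach and exceed the 20 °C tolerance category.
    """
    truth = truth or SyntheticTruth()
    if month not in ("august", "march"):
        raise ValueError("month must be 'august' or 'march'")
    lon2d, lat2d = geometry.meshgrid()
    lon_span = max(geometry.resolution * max(geometry.n_lon - 1, 1), 1e-12)
    lat_span = max(geometry.resolution * max(geometry.n_lat - 1, 1), 1e-12)
    u = (lon2d - geometry.lon_origin) / lon_span
    v = (lat2d - geometry.lat_origin) / lat_span
    august = (
        17.2
        - 1.6 * u                      # mildly cooler to the east
        - 3.6 * v                      # coldest along the coast
        + 0.8 * np.sin(2 * np.pi * u) * np.cos(np.pi * v)
        + 0.4 * np.cos(3 * np.pi * u)
    )
    if month == "august":
        return august
    offset = truth.march_offset - 1.0 * u + 8.0 * v  # coastal summers run hot
    return august + offset


def generate_baseline(
    domain: GridGeometry | tuple[GridGeometry, np.ndarray],
    month: str,
    truth: SyntheticTruth | None = None,
    noise_sd: float = 0.3,
    seed: int = 0,
    mask: np.ndarray | None = None,
) -> RasterGrid:
    """Fine-resolution baseline SST climatology with observation noise.

    ``domain`` may be a bare :class:`GridGeometry` (then ``mask`` applies,
    defaulting to all-sea) or the ``(geometry, mask)`` pair returned by
    :func:`study_domain`.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if isinstance(domain, tuple):
        geometry, mask = domain
    else:
        geometry = domain
    if mask is None:
        mask = np.ones(geometry.shape, dtype=bool)
    truth = truth or SyntheticTruth()
    rng = np.random.default_rng(seed)
    surface = baseline_surface(geometry, month, truth)
    noise = rng.normal(0.0, noise_sd, size=geometry.shape) if noise_sd > 0 else 0.0
    values = np.where(mask, surface + noise, np.nan)
    return RasterGrid(values=values, geometry=geometry, mask=mask,
                      variable=f"sst_{month}")


# ---------------------------------------------------------------------------
# GCM fields
# ---------------------------------------------------------------------------

def coarse_geometry_for(geometry: GridGeometry, resolution: float = 2.5) -> GridGeometry:
    """Coarse grid covering (and padding by one cell) a fine domain."""
    fine_w = geometry.lon_origin - geometry.resolution / 2
    fine_s = geometry.lat_origin - geometry.resolution / 2
    fine_e = fine_w + geometry.resolution * geometry.n_lon
    fine_n = fine_s + geometry.resolution * geometry.n_lat
    w = np.floor(fine_w / resolution) * resolution - resolution
    s = np.floor(fine_s / resolution) * resolution - resolution
    n_lon = int(np.ceil((fine_e - w) / resolution)) + 1
    n_lat = int(np.ceil((fine_n - s) / resolution)) + 1
    return GridGeometry(n_lat=n_lat, n_lon=n_lon,
                        lon_origin=w + resolution / 2,
                        lat_origin=s + resolution / 2,
                        resolution=resolution)


def _smooth_perturbation(geometry: GridGeometry, rng: np.random.Generator,
                         amplitude: float) -> np.ndarray:
    lon2d, lat2d = geometry.meshgrid()
    u = (lon2d - geometry.lon_origin) / max(geometry.resolution * geometry.n_lon, 1e-12)
    v = (lat2d - geometry.lat_origin) / max(geometry.resolution * geometry.n_lat, 1e-12)
    a = rng.normal(size=2)
    pa = rng.uniform(0, 2 * np.pi, size=2)
    return amplitude * (
        a[0] * np.sin(2 * np.pi * u + pa[0]) + a[1] * np.cos(np.pi * v + pa[1])
    ) / np.sqrt(2)


def generate_gcm_anomalies(
    n_models: int,
    decades: list[int],
    scenario: str,
    truth: SyntheticTruth | None = None,
    spread_sd: float = 0.15,
    outlier_bias: float = 0.0,
    seed: int = 0,
    geometry: GridGeometry | None = None,
) -> tuple[dict[str, GridStack], str | None]:
    """Per-model coarse (2.5°) SST anomaly stacks for decadal slices.

    Model ``m``'s anomaly at decade ``d`` is the scenario trajectory
    plus a model-specific offset (iid Gaussian, sd ``spread_sd``) and a
    smooth spatial perturbation; when ``outlier_bias`` is non-zero
    exactly one model — chosen from the seed — is additionally shifted
    by it, emulating a deliberately poor ensemble member.

    Returns ``({model_name: GridStack labelled by decade}, outlier_name)``
    with ``outlier_name`` None when no outlier was planted.
    """
    if n_models < 2:
        raise ValueError("need at least 2 models")
    bad = [d for d in decades if d not in range(2010, 2101)]
    if bad or not decades:
        raise ValueError(f"decades must be a non-empty subset of 2010..2100, got {bad}")
    truth = truth or SyntheticTruth()
    if geometry is None:
        geometry = coarse_geometry_for(study_domain()[0])
    rng = np.random.default_rng(seed)
    offsets = rng.normal(0.0, spread_sd, size=n_models) if spread_sd > 0 else np.zeros(n_models)
    outlier_idx = int(rng.integers(n_models)) if outlier_bias != 0 else None
    out: dict[str, GridStack] = {}
    for m in range(n_models):
        pert = (_smooth_perturbation(geometry, rng, spread_sd / 2)
                if spread_sd > 0 else np.zeros(geometry.shape))
        grids, labels = [], []
        for d in decades:
            base = truth.scenario_anomaly(scenario, d)
            values = base + offsets[m] + pert
            if m == outlier_idx:
                values = values + outlier_bias
            grids.append(RasterGrid(values=values, geometry=geometry,
                                    variable="sst_anomaly"))
            labels.append(d)
        out[f"model_{m:02d}"] = GridStack(grids=grids, labels=labels)
    return out, (f"model_{outlier_idx:02d}" if outlier_idx is not None else None)


def generate_gcm_historical(
    observed: RasterGrid,
    n_models: int,
    error_scales: list[float] | None = None,
    seed: int = 0,
) -> dict[str, RasterGrid]:
    """Per-model simulated present-day fields with known skill ordering.

    Model ``m``'s field is the observed field plus a constant bias and a
    spatial error field, both scaled by ``error_scales[m]`` — so smaller
    scale means better skill on every validation statistic, giving a
    known ground-truth ranking for tests.
    """
    if error_scales is None:
        error_scales = [0.1 * (m + 1) for m in range(n_models)]
    if len(error_scales) != n_models:
        raise ValueError("one error scale per model required")
    rng = np.random.default_rng(seed)
    out = {}
    for m, s in enumerate(error_scales):
        bias = s  # deterministic constant bias, °C
        noise = rng.normal(0.0, s, size=observed.shape)
        out[f"model_{m:02d}"] = observed.with_values(
            observed.values + bias + noise, variable="sst_hist"
        )
    return out


# ---------------------------------------------------------------------------
# abundance surveys
# ---------------------------------------------------------------------------

def linear_predictor(
    sst: np.ndarray,
    depth: np.ndarray,
    harvest: np.ndarray,
    dist_launch: np.ndarray,
    species: str,
    truth: SyntheticTruth,
) -> np.ndarray:
    """Ground-truth log mean abundance for given covariates."""
    cd, ch, cl = truth.covariate_coeffs
    cov = cd * depth + ch * harvest + cl * dist_launch
    if species == "A":
        a0, a1 = truth.sdm_coeffs_A
        return a0 + a1 * sst + cov
    if species == "B":
        b0, b1, b2 = truth.sdm_coeffs_B
        return b0 + b1 * sst + b2 * sst**2 + cov
    raise ValueError("species must be 'A' or 'B'")


def generate_surveys(
    baseline_august: RasterGrid,
    truth: SyntheticTruth | None = None,
    n_records: int = 1000,
    species: str = "A",
    seed: int = 0,
) -> SurveySet:
    """Abundance survey records with overdispersed count noise.

    Sites are drawn without replacement from the sea cells of the August
    baseline; SST at a site is the baseline cell value; counts are
    negative binomial (Poisson if ``truth.count_family == 'poisson'``)
    around the ground-truth mean.
    """
    truth = truth or SyntheticTruth()
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    sea_idx = np.flatnonzero(baseline_august.mask.ravel())
    if n_records > sea_idx.size:
        raise ValueError(
            f"n_records={n_records} exceeds {sea_idx.size} available sea cells"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(sea_idx, size=n_records, replace=False)
    rows, cols = np.unravel_index(chosen, baseline_august.shape)
    g = baseline_august.geometry
    lon = g.lon_origin + g.resolution * cols
    lat = g.lat_origin + g.resolution * rows
    sst = baseline_august.values[rows, cols]
    depth = rng.uniform(*DEPTH_RANGE, size=n_records)
    harvest = rng.uniform(*HARVEST_RANGE, size=n_records)
    dist = rng.uniform(*DIST_LAUNCH_RANGE, size=n_records)
    mu = np.exp(linear_predictor(sst, depth, harvest, dist, species, truth))
    if truth.count_family == "poisson":
        counts = rng.poisson(mu)
    else:
        # gamma–Poisson mixture: var = mu + mu^2/k
        lam = rng.gamma(shape=truth.dispersion, scale=mu / truth.dispersion)
        counts = rng.poisson(lam)
    records = pd.DataFrame({
        "lon": lon, "lat": lat, "depth_m": depth,
        "harvest_intensity": harvest, "dist_launch_km": dist,
        "sst_august": sst, "count_per_100m2": counts.astype(int),
    })
    return SurveySet(records=records, species=species)


# ---------------------------------------------------------------------------
# mortality experiment
# ---------------------------------------------------------------------------

def generate_mortality(
    group_means: list[float],
    group_sds: list[float],
    n_tanks: int = 4,
    seed: int = 0,
    group_labels: list[str] | None = None,
) -> pd.DataFrame:
    """Replicate-tank juvenile mortality percentages per temperature group.

    Tank-level mortality is Gaussian around the group mean, truncated to
    [0, 100].  Columns: ``temperature``, ``tank``, ``mortality_pct``.
    """
    if n_tanks < 2:
        raise ValueError("need at least 2 tanks per group")
    if not all(0 <= m <= 100 for m in group_means):
        raise ValueError("group means must lie in [0, 100]")
    if group_labels is None:
        group_labels = [f"group_{i}" for i in range(len(group_means))]
    rng = np.random.default_rng(seed)
    rows = []
    for label, mean, sd in zip(group_labels, group_means, group_sds):
        vals = mean + (rng.normal(0.0, sd, size=n_tanks) if sd > 0 else np.zeros(n_tanks))
        vals = np.clip(vals, 0.0, 100.0)
        for t, v in enumerate(vals):
            rows.append({"temperature": label, "tank": t, "mortality_pct": float(v)})
    return pd.DataFrame(rows)
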