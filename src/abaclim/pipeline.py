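"""Stage orchestration: run the projection pipeline end to end on disk.

Each stage reads its inputs from the configured output directory,
computes, writes its artifacts, and records them (with content hashes
and the seeds used) in a cumulative ``manifest.json``.  Stages are pure
functions of the configuration, so a rerun with the same config
reproduces every artifact bit for bit.

Stage order: synth → gcm → downscale → sdm → range → overlay →
mortality (the mortality stage is independent of the spatial chain).
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import downscale as ds
from . import gcm as gcm_mod
from . import mortality as mort
from . import ranges as rng_mod
from . import sdm as sdm_mod
from . import synthetic as synth
from .config import PipelineConfig
from .grids import GridGeometry, GridStack, RasterGrid, read_raster, write_raster

__all__ = ["run_stage", "STAGES"]

STAGES = ["synth", "gcm", "downscale", "sdm", "range", "overlay", "mortality"]

_PRODUCERS = {
    "baseline_august": "synth", "baseline_march": "synth",
    "observed_coarse": "synth", "surveys_A": "synth", "surveys_B": "synth",
    "mortality_table": "synth",
    "skill_table": "gcm", "ensemble_anomaly": "gcm",
    "sst_projected": "downscale", "baseline_smoothed": "downscale",
    "abundance": "sdm",
}


class MissingArtifactError(FileNotFoundError):
    pass


def _require(path: Path, key: str) -> Path:
    if not path.exists():
        stage = _PRODUCERS.get(key, "an earlier")
        raise MissingArtifactError(
            f"missing required artifact {path} — run stage '{stage}' first"
        )
    return path


def _ext(cfg: PipelineConfig) -> str:
    return ".nc" if cfg.raster_format == "netcdf" else ".asc"


def _truth(cfg: PipelineConfig) -> synth.SyntheticTruth:
    return synth.SyntheticTruth(warming_per_decade=dict(cfg.scenarios),
                                policy_shape=cfg.policy_shape)


def _domain(cfg: PipelineConfig):
    return synth.study_domain(n_lon=cfg.n_lon, n_lat=cfg.n_lat,
                              resolution=cfg.resolution,
                              lon_origin=cfg.lon_origin,
                              lat_origin=cfg.lat_origin)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path):
        self.path = outdir / "manifest.json"
        self.data = {}
        if self.path.exists():
            self.data = json.loads(self.path.read_text())

    def record(self, stage: str, seed: int, files: list[Path], t0: float) -> None:
        self.data[stage] = {
            "seed": seed,
            "wall_time_s": round(time.time() - t0, 3),
            "artifacts": {str(p.name): _sha256(p) for p in sorted(files)},
        }
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _run_synth(cfg: PipelineConfig, out: Path) -> list[Path]:
    seed = cfg.stage_seed("synth")
    truth = _truth(cfg)
    geom, mask = _domain(cfg)
    ext = _ext(cfg)
    files = []
    for i, month in enumerate(("august", "march")):
        grid = synth.generate_baseline((geom, mask), month, truth,
                                       noise_sd=cfg.baseline_noise_sd,
                                       seed=seed + i)
        p = out / f"baseline_{month}{ext}"
        write_raster(grid, p, cfg.raster_format)
        files.append(p)
    # observed climatology on the coarse GCM geometry, the validation
    # target for skill ranking
    coarse_geom = synth.coarse_geometry_for(geom, cfg.coarse_resolution)
    obs_coarse = RasterGrid(values=synth.baseline_surface(coarse_geom, "august", truth),
                            geometry=coarse_geom, variable="sst_august")
    p = out / f"observed_coarse{ext}"
    write_raster(obs_coarse, p, cfg.raster_format)
    files.append(p)
    baseline_aug = read_raster(out / f"baseline_august{ext}", cfg.raster_format)
    for j, sp in enumerate(("A", "B")):
        surveys = synth.generate_surveys(baseline_aug, truth,
                                         n_records=cfg.n_surveys, species=sp,
                                         seed=seed + 10 + j)
        p = out / f"surveys_{sp}.csv"
        surveys.to_csv(p)
        files.append(p)
    table = synth.generate_mortality(cfg.mortality_means, cfg.mortality_sds,
                                     n_tanks=cfg.n_tanks, seed=seed + 20,
                                     group_labels=cfg.mortality_labels)
    p = out / "mortality_table.csv"
    table.to_csv(p, index=False)
    files.append(p)
    return files


def _anomaly_sets(cfg: PipelineConfig, coarse_geom: GridGeometry):
    """Per-scenario per-model anomaly stacks (regenerated from config)."""
    truth = _truth(cfg)
    seed = cfg.stage_seed("gcm")
    result = {}
    for s_idx, scenario in enumerate(sorted(cfg.scenarios)):
        anomalies, outlier = synth.generate_gcm_anomalies(
            n_models=cfg.n_models, decades=list(cfg.decades), scenario=scenario,
            truth=truth, spread_sd=cfg.gcm_spread_sd,
            outlier_bias=cfg.outlier_bias, seed=seed + s_idx,
            geometry=coarse_geom,
        )
        result[scenario] = (anomalies, outlier)
    return result


def _run_gcm(cfg: PipelineConfig, out: Path) -> list[Path]:
    seed = cfg.stage_seed("gcm")
    ext = _ext(cfg)
    obs = read_raster(_require(out / f"observed_coarse{ext}", "observed_coarse"),
                      cfg.raster_format)
    hist = synth.generate_gcm_historical(obs, cfg.n_models, seed=seed + 50)
    tables = {m: gcm_mod.skill_stats(f, obs) for m, f in hist.items()}
    ranking = gcm_mod.rank_models(tables)
    files = []
    anomaly_sets = _anomaly_sets(cfg, obs.geometry)
    for scenario, (anomalies, outlier) in anomaly_sets.items():
        outliers = gcm_mod.outlier_analysis(anomalies)
        table = ranking.join(outliers)
        table["planted_outlier"] = [m == outlier for m in table.index]
        p = out / f"skill_table_{scenario}.csv"
        table.to_csv(p)
        files.append(p)
        # drop flagged outliers before selection, then average the top k
        keep = {m: s for m, s in anomalies.items()
                if not outliers.loc[m, "flagged"]}
        k = min(cfg.ensemble_k, len(keep))
        ens = gcm_mod.select_and_average(keep, ranking.loc[list(keep)], k=k)
        for decade, grid in ens:
            p = out / f"ensemble_anomaly_{scenario}_{decade}{ext}"
            write_raster(grid, p, cfg.raster_format)
            files.append(p)
    return files


def _run_downscale(cfg: PipelineConfig, out: Path) -> list[Path]:
    seed = cfg.stage_seed("downscale")
    ext = _ext(cfg)
    rng = np.random.default_rng(seed)
    files = []
    smoothed = {}
    for month in ("august", "march"):
        noisy = read_raster(_require(out / f"baseline_{month}{ext}",
                                     "baseline_august"), cfg.raster_format)
        # TPS/GCV smoothing of the noisy climatology samples
        sea = np.flatnonzero(noisy.mask.ravel())
        idx = rng.choice(sea, size=min(cfg.tps_knots, sea.size), replace=False)
        r, c = np.unravel_index(idx, noisy.shape)
        g = noisy.geometry
        pts = np.column_stack([g.lon_origin + g.resolution * c,
                               g.lat_origin + g.resolution * r,
                               noisy.values[r, c]])
        fit = ds.tps_fit(pts)
        smooth = ds.tps_evaluate(fit, noisy)
        smooth.variable = f"sst_{month}"
        p = out / f"baseline_smoothed_{month}{ext}"
        write_raster(smooth, p, cfg.raster_format)
        files.append(p)
        smoothed[month] = smooth
        (out / f"tps_fit_{month}.json").write_text(json.dumps({
            "lambda": fit.smoothing_parameter, "gcv": fit.gcv_score,
            "n_knots": len(fit.knots),
            "gcv_curve": fit.gcv_curve.to_dict(orient="list"),
        }, indent=2))
        files.append(out / f"tps_fit_{month}.json")
    for scenario in sorted(cfg.scenarios):
        for decade in cfg.decades:
            coarse = read_raster(
                _require(out / f"ensemble_anomaly_{scenario}_{decade}{ext}",
                         "ensemble_anomaly"), cfg.raster_format)
            mid = ds.bilinear_refine(coarse, cfg.mid_resolution)
            for month in ("august", "march"):
                proj = ds.change_factor(smoothed[month], mid)
                proj.variable = f"sst_{month}"
                p = out / f"sst_projected_{month}_{scenario}_{decade}{ext}"
                write_raster(proj, p, cfg.raster_format)
                files.append(p)
    return files


def _load_ensembles(cfg: PipelineConfig, out: Path, seed: int):
    ensembles = {}
    for sp in ("A", "B"):
        surveys = synth.SurveySet.from_csv(
            _require(out / f"surveys_{sp}.csv", f"surveys_{sp}"), species=sp)
        rng = np.random.default_rng(seed)
        n = len(surveys)
        order = rng.permutation(n)
        n_val = max(1, int(cfg.validation_fraction * n))
        val_idx, train_idx = order[:n_val], order[n_val:]
        train = synth.SurveySet(surveys.records.iloc[train_idx].reset_index(drop=True), sp)
        val = synth.SurveySet(surveys.records.iloc[val_idx].reset_index(drop=True), sp)
        glm = sdm_mod.fit_glm(train, response_shape=cfg.response_shapes[sp],
                              family=cfg.glm_family, seed=seed)
        brt = sdm_mod.fit_brt(train, seed=seed, **cfg.brt)
        w = sdm_mod.ensemble_weights(glm, brt, val, scheme=cfg.weight_scheme)
        ensembles[sp] = sdm_mod.SDMEnsemble(glm_component=glm, brt_component=brt,
                                            weights=w)
    return ensembles


def _run_sdm(cfg: PipelineConfig, out: Path) -> list[Path]:
    seed = cfg.stage_seed("sdm")
    ext = _ext(cfg)
    baseline = read_raster(_require(out / f"baseline_smoothed_august{ext}",
                                    "baseline_smoothed"), cfg.raster_format)
    ensembles = _load_ensembles(cfg, out, seed)
    files = []
    meta = {}
    for sp, ens in ensembles.items():
        present = sdm_mod.predict_abundance(ens, {"sst_august": baseline})
        p = out / f"abundance_{sp}_present{ext}"
        write_raster(present, p, cfg.raster_format)
        files.append(p)
        anomalies = {}
        for scenario in sorted(cfg.scenarios):
            for decade in cfg.decades:
                proj = read_raster(
                    _require(out / f"sst_projected_august_{scenario}_{decade}{ext}",
                             "sst_projected"), cfg.raster_format)
                anomalies[(decade, scenario)] = baseline.with_values(
                    proj.values - baseline.values, variable="anomaly")
        stack = sdm_mod.project_decades(ens, baseline, anomalies)
        for (decade, scenario), grid in zip(stack.labels, stack.grids):
            p = out / f"abundance_{sp}_{scenario}_{decade}{ext}"
            write_raster(grid, p, cfg.raster_format)
            files.append(p)
        glm = ens.glm_component
        meta[sp] = {
            "glm": {"params": glm.params.to_dict(), "family": glm.family,
                    "alpha": glm.alpha, "sst_center": glm.sst_center,
                    "cv_deviance": glm.cv_deviance,
                    "response_shape": glm.response_shape},
            "brt": {"hyperparameters": ens.brt_component.hyperparameters,
                    "seed": ens.brt_component.seed,
                    "n_trees_used": int(ens.brt_component.model.n_estimators_)},
            "weights": list(ens.weights),
        }
    p = out / "sdm_models.json"
    p.write_text(json.dumps(meta, indent=2))
    files.append(p)
    return files


def _run_range(cfg: PipelineConfig, out: Path) -> list[Path]:
    ext = _ext(cfg)
    files = []
    rows = []
    last = max(cfg.decades)
    for sp in ("A", "B"):
        present = read_raster(_require(out / f"abundance_{sp}_present{ext}",
                                       "abundance"), cfg.raster_format)
        cur = rng_mod.delineate_grounds(present, cfg.ground_threshold)
        for scenario in sorted(cfg.scenarios):
            future = read_raster(
                _require(out / f"abundance_{sp}_{scenario}_{last}{ext}",
                         "abundance"), cfg.raster_format)
            fut = rng_mod.delineate_grounds(future, cfg.ground_threshold)
            change = rng_mod.classify_change(cur, fut, cfg.ground_threshold,
                                             decade=last, scenario=scenario,
                                             species=sp)
            p = out / f"grounds_{sp}_{scenario}_{last}.asc"
            write_raster(change.categories, p, "ascii-grid")
            files.append(p)
            counts = change.counts()
            try:
                pct = rng_mod.percent_change_above_threshold(
                    present, future, cfg.ground_threshold)
            except ValueError:
                pct = np.nan
            rows.append({"species": sp, "scenario": scenario, "decade": last,
                         "pct_change_above_threshold": pct, **counts.to_dict()})
    p = out / "ground_change_summary.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    files.append(p)
    return files


def _run_overlay(cfg: PipelineConfig, out: Path) -> list[Path]:
    ext = _ext(cfg)
    last = max(cfg.decades)
    files = []
    reports = {}
    for sp in ("A", "B"):
        present = read_raster(_require(out / f"abundance_{sp}_present{ext}",
                                       "abundance"), cfg.raster_format)
        for scenario in sorted(cfg.scenarios):
            march = read_raster(
                _require(out / f"sst_projected_march_{scenario}_{last}{ext}",
                         "sst_projected"), cfg.raster_format)
            future = read_raster(
                _require(out / f"abundance_{sp}_{scenario}_{last}{ext}",
                         "abundance"), cfg.raster_format)
            cur = rng_mod.delineate_grounds(present, cfg.ground_threshold)
            fut = rng_mod.delineate_grounds(future, cfg.ground_threshold)
            change = rng_mod.classify_change(cur, fut)
            gained = change.categories.values == rng_mod.CATEGORY_CODES["gained"]
            regions = {"study_area": march.mask,
                       "current_distribution":
                           present.mask & (present.values > cfg.distribution_cutoff)}
            if gained.any():
                regions["expansion"] = gained
            rep = rng_mod.march_overlay(march, regions,
                                        bin_edges=tuple(cfg.march_bins),
                                        decade=last, scenario=scenario)
            reports[f"{sp}_{scenario}"] = rep.fractions.to_dict(orient="index")
    p = out / "march_overlay.json"
    p.write_text(json.dumps(reports, indent=2))
    files.append(p)
    return files


def _run_mortality(cfg: PipelineConfig, out: Path) -> list[Path]:
    table = pd.read_csv(_require(out / "mortality_table.csv", "mortality_table"))
    exp = mort.MortalityExperiment(data=table)
    res = mort.one_way_anova(exp)
    summ = exp.summary()
    recon = mort.anova_from_summary(summ["mean"].tolist(), summ["se"].tolist(),
                                    summ["n"].tolist())
    means = summ["mean"].sort_values()
    fc = mort.fold_change(means.iloc[-1], means.iloc[0]) if means.iloc[0] > 0 else np.nan
    payload = {
        "anova": res.as_dict(),
        "anova_from_summary": recon.as_dict(),
        "group_summary": summ.reset_index().to_dict(orient="records"),
        "fold_change": None if np.isnan(fc) else fc,
    }
    p = out / "mortality_stats.json"
    p.write_text(json.dumps(payload, indent=2))
    return [p]


_RUNNERS = {
    "synth": _run_synth, "gcm": _run_gcm, "downscale": _run_downscale,
    "sdm": _run_sdm, "range": _run_range, "overlay": _run_overlay,
    "mortality": _run_mortality,
}


def run_stage(stage: str, config: PipelineConfig) -> dict:
    """Run one pipeline stage (or ``'all'`` for every stage in order).

    Returns the manifest entry (or the whole manifest for ``'all'``).
    Raises :class:`MissingArtifactError` naming the producing stage when
    an upstream artifact is absent.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out)
    stages = STAGES if stage == "all" else [stage]
    if any(s not in _RUNNERS for s in stages):
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES + ['all']}")
    for s in stages:
        t0 = time.time()
        files = _RUNNERS[s](config, out)
        seed = config.stage_seed(s)
        manifest.record(s, seed, files, t0)
    return manifest.data if stage == "all" else manifest.data[stage]
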