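"""Thin-plate-spline smoothing with GCV and the change-factor chain."""

import numpy as np
import pytest
from scipy.interpolate import RBFInterpolator

from abaclim import (bilinear_refine, change_factor, generate_baseline,
                     study_domain, tps_evaluate, tps_fit)
from abaclim.grids import GridGeometry, RasterGrid

from conftest import make_grid


def _scatter(rng, n, f):
    xy = rng.uniform(0, 10, size=(n, 2))
    return np.column_stack([xy, f(xy[:, 0], xy[:, 1])])


# ---------------------------------------------------------------------------
# thin-plate spline
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("lam", [1e-6, 1.0, 100.0])
def test_affine_surfaces_reproduced_for_any_lambda(lam):
    """Planes lie in the penalty null space, so any smoothing level
    reproduces them exactly."""
    rng = np.random.default_rng(0)
    pts = _scatter(rng, 40, lambda x, y: 2.0 + 0.3 * x - 0.7 * y)
    fit = tps_fit(pts, lambda_grid=[lam])
    query = rng.uniform(0, 10, size=(30, 2))
    pred = tps_evaluate(fit, query)
    np.testing.assert_allclose(pred, 2.0 + 0.3 * query[:, 0] - 0.7 * query[:, 1],
                               atol=1e-8)


def test_interpolation_limit_matches_rbf_oracle():
    """lambda → 0: residuals vanish at the knots and the surface agrees
    with scipy's independent thin-plate interpolator off the knots."""
    rng = np.random.default_rng(1)
    pts = _scatter(rng, 60, lambda x, y: np.sin(x / 3) + np.cos(y / 4))
    fit = tps_fit(pts, lambda_grid=[1e-12])
    at_knots = tps_evaluate(fit, pts[:, :2])
    np.testing.assert_allclose(at_knots, pts[:, 2], atol=1e-6)
    oracle = RBFInterpolator(pts[:, :2], pts[:, 2],
                             kernel="thin_plate_spline", smoothing=0.0)
    query = rng.uniform(1, 9, size=(25, 2))
    np.testing.assert_allclose(tps_evaluate(fit, query), oracle(query), atol=1e-4)


def test_gcv_selects_positive_smoothing_on_noisy_data():
    """With observation noise the GCV choice is interior (lambda > 0) in
    at least 90% of seeds."""
    hits = 0
    for seed in range(50):
        rng = np.random.default_rng(seed)
        pts = _scatter(rng, 120, lambda x, y: 0.5 * x - 0.2 * y)
        pts[:, 2] += rng.normal(0, 0.5, size=len(pts))
        fit = tps_fit(np.vstack([pts]), lambda_grid=np.geomspace(1e-8, 1e2, 20))
        if fit.smoothing_parameter > 1e-8:
            hits += 1
    assert hits >= 45


def test_gcv_beats_interpolation_on_noisy_plane():
    """GCV smoothing recovers a noisy plane with lower MSE than the
    interpolant in at least 90% of 20 seeds."""
    wins = 0
    for seed in range(20):
        rng = np.random.default_rng(100 + seed)
        truth_f = lambda x, y: 1.0 + 0.4 * x - 0.3 * y
        pts = _scatter(rng, 200, truth_f)
        pts[:, 2] += rng.normal(0, 0.5, size=len(pts))
        query = rng.uniform(0, 10, size=(200, 2))
        target = truth_f(query[:, 0], query[:, 1])
        gcv_fit = tps_fit(pts)
        interp_fit = tps_fit(pts, lambda_grid=[1e-12])
        mse_gcv = np.mean((tps_evaluate(gcv_fit, query) - target) ** 2)
        mse_interp = np.mean((tps_evaluate(interp_fit, query) - target) ** 2)
        if mse_gcv < mse_interp:
            wins += 1
    assert wins >= 18


def test_holdout_error_on_synthetic_baseline_below_half_degree():
    """Out-of-sample validation of the smoothed climatology: mean
    absolute holdout error below the 0.5 °C acceptance bound."""
    domain = study_domain(n_lon=80, n_lat=40)
    grid = generate_baseline(domain, "august", noise_sd=0.3, seed=5)
    rng = np.random.default_rng(5)
    sea = np.flatnonzero(grid.mask.ravel())
    idx = rng.permutation(sea)
    train, hold = idx[:400], idx[400:800]
    g = grid.geometry

    def pts(cells):
        r, c = np.unravel_index(cells, grid.shape)
        return np.column_stack([g.lon_origin + g.resolution * c,
                                g.lat_origin + g.resolution * r,
                                grid.values[r, c]])

    fit = tps_fit(pts(train))
    held = pts(hold)
    err = np.abs(tps_evaluate(fit, held[:, :2]) - held[:, 2])
    assert err.mean() < 0.5


def test_degenerate_point_sets_rejected():
    line = np.column_stack([np.arange(5.0), np.arange(5.0), np.ones(5)])
    with pytest.raises(ValueError, match="collinear"):
        tps_fit(line)
    with pytest.raises(ValueError, match="at least 4"):
        tps_fit(np.ones((3, 3)))


# ---------------------------------------------------------------------------
# bilinear refinement
# ---------------------------------------------------------------------------

def test_bilinear_constant_and_plane():
    const = make_grid(np.full((4, 4), 3.3), resolution=2.5, lon_origin=130,
                      lat_origin=-40)
    fine = bilinear_refine(const, 0.5)
    np.testing.assert_allclose(fine.values, 3.3)
    assert fine.resolution == 0.5

    g = const.geometry
    lon2d, lat2d = g.meshgrid()
    plane = const.with_values(1.0 + 0.2 * lon2d - 0.1 * lat2d)
    fine = bilinear_refine(plane, 0.5)
    flon, flat = fine.geometry.meshgrid()
    interior = (flon >= g.lons()[0]) & (flon <= g.lons()[-1]) \
        & (flat >= g.lats()[0]) & (flat <= g.lats()[-1])
    np.testing.assert_allclose(fine.values[interior],
                               (1.0 + 0.2 * flon - 0.1 * flat)[interior],
                               atol=1e-9)


def test_bilinear_matches_direct_formula_oracle():
    """Random coarse field: fine values equal the textbook two-axis
    interpolation formula at 25 random interior points."""
    rng = np.random.default_rng(3)
    coarse = make_grid(rng.normal(0, 1, (4, 4)), resolution=2.5,
                       lon_origin=130, lat_origin=-40)
    fine = bilinear_refine(coarse, 0.5)
    g, fg = coarse.geometry, fine.geometry
    lons, lats = g.lons(), g.lats()
    flon, flat = fg.meshgrid()
    picks = rng.integers(0, fine.shape[0], 25), rng.integers(0, fine.shape[1], 25)
    for r, c in zip(*picks):
        x = np.clip(flon[r, c], lons[0], lons[-1])
        y = np.clip(flat[r, c], lats[0], lats[-1])
        i = min(np.searchsorted(lons, x, "right") - 1, len(lons) - 2)
        j = min(np.searchsorted(lats, y, "right") - 1, len(lats) - 2)
        tx = (x - lons[i]) / (lons[i + 1] - lons[i])
        ty = (y - lats[j]) / (lats[j + 1] - lats[j])
        v = coarse.values
        expected = (v[j, i] * (1 - tx) * (1 - ty) + v[j, i + 1] * tx * (1 - ty)
                    + v[j + 1, i] * (1 - tx) * ty + v[j + 1, i + 1] * tx * ty)
        assert fine.values[r, c] == pytest.approx(expected, rel=1e-9)


def test_bilinear_bounded_by_coarse_extrema():
    rng = np.random.default_rng(4)
    coarse = make_grid(rng.normal(0, 2, (5, 6)), resolution=2.5,
                       lon_origin=128, lat_origin=-42)
    fine = bilinear_refine(coarse, 0.5)
    assert fine.values.max() <= coarse.values.max() + 1e-12
    assert fine.values.min() >= coarse.values.min() - 1e-12


def test_bilinear_rejects_coarser_target():
    coarse = make_grid(np.ones((3, 3)), resolution=0.5)
    with pytest.raises(ValueError, match="not finer"):
        bilinear_refine(coarse, 2.5)


# ---------------------------------------------------------------------------
# change factor
# ---------------------------------------------------------------------------

def _fine_and_mid():
    geom, mask = study_domain(n_lon=50, n_lat=50, resolution=0.01)
    baseline = generate_baseline((geom, mask), "august", noise_sd=0.2, seed=9)
    from abaclim.synthetic import coarse_geometry_for
    mid_geom = coarse_geometry_for(geom, 0.5)
    return baseline, mid_geom


def test_zero_anomaly_reproduces_baseline_bit_exactly():
    baseline, mid_geom = _fine_and_mid()
    zero = RasterGrid(values=np.zeros(mid_geom.shape), geometry=mid_geom)
    proj = change_factor(baseline, zero)
    assert np.array_equal(proj.values[proj.mask], baseline.values[baseline.mask])


def test_constant_anomaly_shifts_every_cell():
    baseline, mid_geom = _fine_and_mid()
    const = RasterGrid(values=np.full(mid_geom.shape, 1.1), geometry=mid_geom)
    proj = change_factor(baseline, const)
    np.testing.assert_allclose(proj.values[proj.mask],
                               baseline.values[baseline.mask] + 1.1, rtol=1e-12)
    assert proj.sea_mean() == pytest.approx(baseline.sea_mean() + 1.1)


def test_varying_anomaly_matches_per_cell_brute_force():
    """Each 0.01° cell gets the anomaly of its nearest 0.5° parent,
    verified cell by cell on a 50×50 grid."""
    baseline, mid_geom = _fine_and_mid()
    rng = np.random.default_rng(2)
    anom = RasterGrid(values=rng.normal(1.0, 0.5, mid_geom.shape),
                      geometry=mid_geom)
    proj = change_factor(baseline, anom)
    g = baseline.geometry
    for r in range(g.n_lat):
        for c in range(g.n_lon):
            if not baseline.mask[r, c]:
                assert np.isnan(proj.values[r, c])
                continue
            lon = g.lon_origin + g.resolution * c
            lat = g.lat_origin + g.resolution * r
            pi = round((lat - mid_geom.lat_origin) / mid_geom.resolution)
            pj = round((lon - mid_geom.lon_origin) / mid_geom.resolution)
            assert proj.values[r, c] == pytest.approx(
                baseline.values[r, c] + anom.values[pi, pj], rel=1e-12)


def test_projected_minus_baseline_is_blockwise_constant():
    baseline, mid_geom = _fine_and_mid()
    rng = np.random.default_rng(8)
    anom = RasterGrid(values=rng.normal(0, 1, mid_geom.shape), geometry=mid_geom)
    proj = change_factor(baseline, anom)
    diff = proj.values - baseline.values
    assert len(np.unique(diff[baseline.mask].round(12))) <= anom.values.size


def test_uncovered_baseline_raises():
    geom = GridGeometry(n_lat=10, n_lon=10, lon_origin=130.0,
                        lat_origin=-36.0, resolution=0.01)
    baseline = RasterGrid(values=np.full((10, 10), 15.0), geometry=geom)
    far = GridGeometry(n_lat=2, n_lon=2, lon_origin=100.0, lat_origin=-80.0,
                       resolution=0.5)
    anom = RasterGrid(values=np.zeros((2, 2)), geometry=far)
    with pytest.raises(ValueError, match="does not cover"):
        change_factor(baseline, anom)


def test_full_chain_determinism(truth):
    """Identical inputs produce bit-identical projected grids through
    bilinear refinement plus change factor."""
    baseline, _ = _fine_and_mid()
    from abaclim.synthetic import coarse_geometry_for, generate_gcm_anomalies
    coarse_geom = coarse_geometry_for(baseline.geometry, 2.5)
    runs = []
    for _ in range(2):
        stacks, _out = generate_gcm_anomalies(
            n_models=3, decades=[2100], scenario="WRE750", truth=truth,
            spread_sd=0.1, seed=77, geometry=coarse_geom)
        mid = bilinear_refine(stacks["model_00"][2100], 0.5)
        runs.append(change_factor(baseline, mid).values)
    assert np.array_equal(runs[0][baseline.mask], runs[1][baseline.mask])
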