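"""GLM + BRT ensemble: fitting, weighting, spatial prediction, projection."""

import numpy as np
import pandas as pd
import pytest

from abaclim import (SDMEnsemble, SyntheticTruth, ensemble_weights, fit_brt,
                     fit_glm, generate_baseline, generate_surveys,
                     predict_abundance, project_decades, study_domain)
from abaclim.grids import RasterGrid
from abaclim.sdm import poisson_deviance
from abaclim.synthetic import SurveySet

from conftest import make_grid


def _centered_truth_coeffs(truth, species, center):
    """Ground-truth coefficients on the centered-SST fitting basis."""
    cd, ch, cl = truth.covariate_coeffs
    if species == "A":
        a0, a1 = truth.sdm_coeffs_A
        return {"const": a0 + a1 * center, "sst_c": a1,
                "depth_m": cd, "harvest_intensity": ch, "dist_launch_km": cl}
    b0, b1, b2 = truth.sdm_coeffs_B
    return {"const": b0 + b1 * center + b2 * center**2,
            "sst_c": b1 + 2 * b2 * center, "sst_c2": b2,
            "depth_m": cd, "harvest_intensity": ch, "dist_launch_km": cl}


# ---------------------------------------------------------------------------
# GLM
# ---------------------------------------------------------------------------

def test_null_model_recovers_intercept(baseline_august):
    truth = SyntheticTruth(sdm_coeffs_A=(np.log(25.0), 0.0),
                           covariate_coeffs=(0.0, 0.0, 0.0))
    s = generate_surveys(baseline_august, truth, n_records=1500, species="A",
                         seed=31)
    glm = fit_glm(s, response_shape="linear")
    lo, hi = glm.conf_int.loc["const"]
    assert lo <= np.log(25.0) <= hi


def test_quadratic_optimum_recovery(baseline_august, truth):
    """Species-B fitted thermal optimum within ±0.5 °C of the 17 °C truth,
    averaged over seeds."""
    opts = []
    for seed in range(5):
        s = generate_surveys(baseline_august, truth, n_records=2000,
                             species="B", seed=200 + seed)
        glm = fit_glm(s, response_shape="quadratic")
        opts.append(glm.thermal_optimum())
    assert np.mean(opts) == pytest.approx(truth.optimum_B(), abs=0.5)


def test_coefficients_recovered_within_confidence_intervals(baseline_august, truth):
    s = generate_surveys(baseline_august, truth, n_records=2000, species="A",
                         seed=55)
    glm = fit_glm(s, response_shape="linear")
    expected = _centered_truth_coeffs(truth, "A", glm.sst_center)
    for name, value in expected.items():
        est, se = glm.params[name], glm.bse[name]
        assert abs(est - value) < 4 * se, name


def test_quadratic_beats_misspecified_linear(baseline_august, truth):
    """Cross-validated deviance favours the correctly specified quadratic
    shape on hump-shaped data."""
    wins = 0
    for seed in range(5):
        s = generate_surveys(baseline_august, truth, n_records=1200,
                             species="B", seed=300 + seed)
        lin = fit_glm(s, response_shape="linear", seed=seed)
        quad = fit_glm(s, response_shape="quadratic", seed=seed)
        wins += quad.cv_deviance < lin.cv_deviance
    assert wins >= 4


def test_glm_preconditions(baseline_august, truth):
    tiny = generate_surveys(baseline_august, truth, n_records=20, species="A",
                            seed=1)
    with pytest.raises(ValueError, match="at least"):
        fit_glm(tiny, response_shape="linear")
    rec = generate_surveys(baseline_august, truth, n_records=200, species="B",
                           seed=1).records.copy()
    rec["sst_august"] = 15.0
    with pytest.raises(ValueError, match="distinct SST"):
        fit_glm(SurveySet(rec, "B"), response_shape="quadratic")


# ---------------------------------------------------------------------------
# BRT
# ---------------------------------------------------------------------------

def test_brt_constant_response_predicts_constant(baseline_august, truth):
    s = generate_surveys(baseline_august, truth, n_records=300, species="A",
                         seed=41)
    rec = s.records.copy()
    rec["count_per_100m2"] = 12
    brt = fit_brt(SurveySet(rec, "A"), seed=0)
    np.testing.assert_allclose(brt.predict(rec), 12.0, rtol=1e-6)


def test_brt_recovers_monotone_signal(baseline_august):
    truth = SyntheticTruth(sdm_coeffs_A=(-3.5, 0.45),
                           covariate_coeffs=(0.0, 0.0, 0.0),
                           count_family="poisson")
    s = generate_surveys(baseline_august, truth, n_records=2000, species="A",
                         seed=43)
    brt = fit_brt(s, seed=0)
    df = s.records
    pred = brt.predict(df)
    true_mean = np.exp(truth.sdm_coeffs_A[0] + truth.sdm_coeffs_A[1]
                       * df["sst_august"])
    rho = pd.Series(pred).corr(pd.Series(true_mean), method="spearman")
    assert rho > 0.9


def test_brt_permuted_response_is_uninformative(baseline_august, truth):
    """Negative control: shuffling the response removes any skill edge
    over the null (constant-mean) model."""
    margins = []
    for seed in range(3):
        s = generate_surveys(baseline_august, truth, n_records=1000,
                             species="A", seed=500 + seed)
        rng = np.random.default_rng(seed)
        rec = s.records.copy()
        rec["count_per_100m2"] = rng.permutation(rec["count_per_100m2"].values)
        train, test = rec.iloc[:800], rec.iloc[800:]
        brt = fit_brt(SurveySet(train.reset_index(drop=True), "A"), seed=seed)
        y = test["count_per_100m2"].values
        d_brt = poisson_deviance(y, brt.predict(test))
        d_null = poisson_deviance(y, np.full(len(y), train["count_per_100m2"].mean()))
        margins.append((d_null - d_brt) / d_null)
    assert np.mean(margins) < 0.05  # no real skill beyond noise


def test_brt_determinism_and_errors(baseline_august, truth):
    s = generate_surveys(baseline_august, truth, n_records=400, species="A",
                         seed=47)
    p1 = fit_brt(s, seed=3).predict(s.records)
    p2 = fit_brt(s, seed=3).predict(s.records)
    np.testing.assert_array_equal(p1, p2)
    with pytest.raises(ValueError, match="n_trees"):
        fit_brt(s, n_trees=0)


# ---------------------------------------------------------------------------
# ensemble weights
# ---------------------------------------------------------------------------

class _Fixed:
    def __init__(self, mu):
        self.mu = mu

    def predict(self, df):
        return np.full(len(df), self.mu, dtype=float)


def _val_set(baseline_august, truth, n=200, seed=61):
    return generate_surveys(baseline_august, truth, n_records=n, species="A",
                            seed=seed)


def test_identical_components_get_equal_weights(baseline_august, truth):
    val = _val_set(baseline_august, truth)
    mu = float(val.records["count_per_100m2"].mean())
    w = ensemble_weights(_Fixed(mu), _Fixed(mu), val)
    assert w == (0.5, 0.5)


def test_dominant_component_takes_nearly_all_weight(baseline_august, truth):
    val = _val_set(baseline_august, truth)
    good = float(val.records["count_per_100m2"].mean())
    w = ensemble_weights(_Fixed(good), _Fixed(good * 20), val)
    assert w[0] > 0.99


def test_weights_match_closed_form(baseline_august, truth):
    val = _val_set(baseline_august, truth)
    y = val.records["count_per_100m2"].values
    a, b = _Fixed(y.mean()), _Fixed(y.mean() * 1.15)
    d = np.array([poisson_deviance(y, c.predict(val.records)) for c in (a, b)])
    expected = np.exp(-(d - d.min()) / 2)
    expected /= expected.sum()
    w = ensemble_weights(a, b, val)
    np.testing.assert_allclose(w, expected, rtol=1e-12)
    assert sum(w) == pytest.approx(1.0, abs=1e-12)


def test_empty_validation_rejected(baseline_august, truth):
    val = _val_set(baseline_august, truth)
    empty = SurveySet(val.records.iloc[:0], "A")
    with pytest.raises(ValueError, match="empty"):
        ensemble_weights(_Fixed(1.0), _Fixed(2.0), empty)


# ---------------------------------------------------------------------------
# spatial prediction and projection
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def fitted(baseline_august, truth):
    s = generate_surveys(baseline_august, truth, n_records=1200, species="B",
                         seed=71)
    train = SurveySet(s.records.iloc[:1000].reset_index(drop=True), "B")
    val = SurveySet(s.records.iloc[1000:].reset_index(drop=True), "B")
    glm = fit_glm(train, response_shape="quadratic")
    brt = fit_brt(train, seed=0)
    w = ensemble_weights(glm, brt, val)
    return SDMEnsemble(glm_component=glm, brt_component=brt, weights=w)


def test_glm_only_prediction_matches_hand_computed_exp_eta(fitted):
    ens = SDMEnsemble(glm_component=fitted.glm_component,
                      brt_component=fitted.brt_component, weights=(1.0, 0.0))
    sst = make_grid(np.full((3, 3), 16.0))
    pred = predict_abundance(ens, {"sst_august": sst})
    glm = fitted.glm_component
    sc = 16.0 - glm.sst_center
    eta = (glm.params["const"] + glm.params["sst_c"] * sc
           + glm.params["sst_c2"] * sc**2
           + sum(glm.params[c] * glm.fixed_values[c] for c in glm.covariates))
    np.testing.assert_allclose(pred.values, np.exp(eta), rtol=1e-12)


def test_prediction_between_components_and_nonnegative(fitted, baseline_august):
    pred = predict_abundance(fitted, {"sst_august": baseline_august})
    m = pred.mask
    df = pd.DataFrame({"sst_august": baseline_august.values[m]})
    for c in fitted.glm_component.covariates:
        df[c] = fitted.glm_component.fixed_values[c]
    glm_p = fitted.glm_component.predict(df)
    brt_p = fitted.brt_component.predict(df)
    lo, hi = np.minimum(glm_p, brt_p), np.maximum(glm_p, brt_p)
    assert np.all(pred.values[m] >= lo - 1e-9)
    assert np.all(pred.values[m] <= hi + 1e-9)
    assert np.all(pred.values[m] >= 0) and np.isfinite(pred.values[m]).all()


def test_missing_covariate_is_named(fitted, baseline_august):
    broken = SDMEnsemble(glm_component=fitted.glm_component,
                         brt_component=fitted.brt_component,
                         weights=fitted.weights)
    saved = broken.glm_component.fixed_values.pop("depth_m")
    try:
        with pytest.raises(ValueError, match="depth_m"):
            predict_abundance(broken, {"sst_august": baseline_august})
    finally:
        broken.glm_component.fixed_values["depth_m"] = saved


def test_species_B_prediction_unimodal_along_gradient(fitted):
    """On a pure SST gradient the greenlip-like ensemble peaks strictly
    inside the gradient, not at an edge."""
    sst = make_grid(np.tile(np.linspace(12.5, 19.5, 40), (3, 1)))
    ens = SDMEnsemble(glm_component=fitted.glm_component,
                      brt_component=fitted.brt_component, weights=(1.0, 0.0))
    profile = predict_abundance(ens, {"sst_august": sst}).values[0]
    peak = int(np.argmax(profile))
    assert 0 < peak < 39


def test_zero_anomaly_projection_equals_present(fitted, baseline_august):
    zero = baseline_august.with_values(np.zeros(baseline_august.shape))
    stack = project_decades(fitted, baseline_august, {(2010, "LEV1"): zero})
    present = predict_abundance(fitted, {"sst_august": baseline_august})
    np.testing.assert_array_equal(stack[(2010, "LEV1")].values[present.mask],
                                  present.values[present.mask])


def test_warming_ordering_for_linear_positive_response(baseline_august, truth):
    """Species A (positive linear SST effect): totals rise with warming,
    and the warmer Reference scenario beats Policy at 2100."""
    s = generate_surveys(baseline_august, truth, n_records=1200, species="A",
                         seed=81)
    train = SurveySet(s.records.iloc[:1000].reset_index(drop=True), "A")
    glm = fit_glm(train, response_shape="linear")
    brt = fit_brt(train, seed=0)
    ens = SDMEnsemble(glm_component=glm, brt_component=brt, weights=(1.0, 0.0))
    anomalies = {}
    for decade in (2010, 2050, 2100):
        for scen, rate in (("WRE750", 0.11), ("LEV1", 0.05)):
            anomalies[(decade, scen)] = baseline_august.with_values(
                np.full(baseline_august.shape, rate * (decade - 2000) / 10))
    stack = project_decades(ens, baseline_august, anomalies)
    totals = {lab: np.nansum(g.values) for lab, g in stack}
    assert totals[(2010, "WRE750")] <= totals[(2050, "WRE750")] \
        <= totals[(2100, "WRE750")]
    assert totals[(2100, "WRE750")] >= totals[(2100, "LEV1")]
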