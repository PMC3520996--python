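"""Ensemble species distribution models for abundance.

Two complementary learners are fitted to survey counts — a parametric
count GLM (negative-binomial by default, log link; linear August-SST
term for the blacklip-like species A, linear + centered-quadratic for
the greenlip-like species B) and a boosted-regression-tree (BRT) model —
and combined by validation-deviance exponential weighting, the deviance
analogue of information-criterion weights: ``w_i ∝ exp(-Δ_i/2)`` with
``Δ_i`` the excess held-out deviance of component i.  Predictions are
mapped onto covariate grids, with every non-SST covariate held at the
value used for model fitting, and projected forward by perturbing the
SST grid with downscaled decadal anomalies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import GradientBoostingRegressor

from .grids import GridStack, RasterGrid, regrid_check
from .synthetic import SurveySet

__all__ = [
    "GLMComponent",
    "BRTComponent",
    "SDMEnsemble",
    "fit_glm",
    "fit_brt",
    "ensemble_weights",
    "predict_abundance",
    "project_decades",
    "poisson_deviance",
]

COVARIATES = ["depth_m", "harvest_intensity", "dist_launch_km"]


def poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    """Total Poisson deviance, the common currency for comparing count
    models of different families on held-out data."""
    y = np.asarray(y, dtype=float)
    mu = np.clip(np.asarray(mu, dtype=float), 1e-10, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


@dataclass
class GLMComponent:
    """Fitted count GLM with log link.

    ``params`` are on the centered-SST basis: the SST column is
    ``sst - sst_center`` and, for the quadratic shape, its square.
    """

    params: pd.Series
    bse: pd.Series
    conf_int: pd.DataFrame
    llf: float
    family: str                  # "negbin" | "poisson"
    alpha: float | None          # NB2 dispersion (var = mu + alpha*mu^2)
    response_shape: str          # "linear" | "quadratic"
    sst_center: float
    covariates: list[str]
    fixed_values: dict[str, float]   # training means, used at projection
    cv_deviance: float = np.nan

    def design(self, df: pd.DataFrame) -> np.ndarray:
        sst_c = df["sst_august"].to_numpy(dtype=float) - self.sst_center
        cols = [np.ones(len(df)), sst_c]
        if self.response_shape == "quadratic":
            cols.append(sst_c**2)
        for c in self.covariates:
            cols.append(df[c].to_numpy(dtype=float))
        return np.column_stack(cols)

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        eta = self.design(df) @ self.params.to_numpy()
        return np.exp(eta)

    def thermal_optimum(self) -> float:
        """SST (°C) maximizing the fitted response; quadratic shape only."""
        if self.response_shape != "quadratic":
            raise ValueError("thermal optimum is defined for the quadratic shape")
        b1, b2 = self.params["sst_c"], self.params["sst_c2"]
        if b2 >= 0:
            raise ValueError("fitted quadratic term is not concave")
        return float(self.sst_center - b1 / (2.0 * b2))


@dataclass
class BRTComponent:
    """Boosted regression trees on log1p counts."""

    model: GradientBoostingRegressor
    feature_names: list[str]
    fixed_values: dict[str, float]
    seed: int
    hyperparameters: dict = field(default_factory=dict)

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        X = df[self.feature_names].to_numpy(dtype=float)
        return np.clip(np.expm1(self.model.predict(X)), 0.0, None)


@dataclass
class SDMEnsemble:
    """Weighted GLM + BRT ensemble with its covariate recipe."""

    glm_component: GLMComponent
    brt_component: BRTComponent
    weights: tuple[float, float]       # (w_glm, w_brt), sum to 1

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be nonnegative and sum to 1")

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        w_glm, w_brt = self.weights
        return w_glm * self.glm_component.predict(df) + \
            w_brt * self.brt_component.predict(df)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _glm_frame(surveys: SurveySet) -> pd.DataFrame:
    return surveys.records


def _fit_one_glm(y, X, family, colnames):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if family == "negbin":
            model = sm.NegativeBinomial(y, X)
            res = model.fit(disp=0, maxiter=200)
            converged = res.mle_retvals.get("converged", True)
        elif family == "poisson":
            model = sm.GLM(y, X, family=sm.families.Poisson())
            res = model.fit()
            converged = res.converged
        else:
            raise ValueError("family must be 'negbin' or 'poisson'")
    if not converged:
        raise RuntimeError(
            f"GLM did not converge: {getattr(res, 'mle_retvals', 'no diagnostics')}"
        )
    return res


def fit_glm(
    surveys: SurveySet,
    response_shape: str = "linear",
    family: str = "negbin",
    covariates: list[str] | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> GLMComponent:
    """Fit the count GLM component.

    ``response_shape='quadratic'`` adds a centered SST² term (the
    hump-shaped greenlip response); SST is centered at its training
    mean in both shapes.  Returns coefficients, standard errors, 95%
    confidence intervals, log-likelihood and a k-fold cross-validated
    Poisson deviance.
    """
    if response_shape not in ("linear", "quadratic"):
        raise ValueError("response_shape must be 'linear' or 'quadratic'")
    covariates = COVARIATES if covariates is None else covariates
    df = _glm_frame(surveys)
    n_coef = 2 + (1 if response_shape == "quadratic" else 0) + len(covariates)
    if len(df) < 10 * n_coef:
        raise ValueError(
            f"need at least {10 * n_coef} records for {n_coef} coefficients, "
            f"got {len(df)}"
        )
    if response_shape == "quadratic" and df["sst_august"].nunique() < 3:
        raise ValueError("quadratic shape needs at least 3 distinct SST values")

    center = float(df["sst_august"].mean())
    names = ["const", "sst_c"] + (["sst_c2"] if response_shape == "quadratic" else []) \
        + list(covariates)

    def build(frame: pd.DataFrame) -> np.ndarray:
        sst_c = frame["sst_august"].to_numpy(dtype=float) - center
        cols = [np.ones(len(frame)), sst_c]
        if response_shape == "quadratic":
            cols.append(sst_c**2)
        cols += [frame[c].to_numpy(dtype=float) for c in covariates]
        return np.column_stack(cols)

    y = df["count_per_100m2"].to_numpy(dtype=float)
    X = build(df)
    res = _fit_one_glm(y, X, family, names)
    k = X.shape[1]
    params = pd.Series(np.asarray(res.params)[:k], index=names)
    bse = pd.Series(np.asarray(res.bse)[:k], index=names)
    ci = pd.DataFrame(np.asarray(res.conf_int())[:k], index=names,
                      columns=["lower", "upper"])
    alpha = float(np.asarray(res.params)[k]) if family == "negbin" else None

    # k-fold CV Poisson deviance
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(df))
    folds = np.array_split(order, cv_folds)
    dev = 0.0
    for f in folds:
        test = np.zeros(len(df), dtype=bool)
        test[f] = True
        res_f = _fit_one_glm(y[~test], X[~test], family, names)
        mu = np.exp(X[test] @ np.asarray(res_f.params)[:k])
        dev += poisson_deviance(y[test], mu)

    fixed = {c: float(df[c].mean()) for c in covariates}
    return GLMComponent(params=params, bse=bse, conf_int=ci, llf=float(res.llf),
                        family=family, alpha=alpha, response_shape=response_shape,
                        sst_center=center, covariates=list(covariates),
                        fixed_values=fixed, cv_deviance=float(dev))


def fit_brt(
    surveys: SurveySet,
    tree_depth: int = 3,
    learning_rate: float = 0.01,
    n_trees: int = 2000,
    bag_fraction: float = 0.5,
    seed: int = 0,
) -> BRTComponent:
    """Fit the boosted-regression-tree component on log1p counts.

    Early stopping on a 20% internal holdout; deterministic under a
    fixed seed.
    """
    if n_trees <= 0:
        raise ValueError("n_trees must be positive")
    df = _glm_frame(surveys)
    if len(df) < 100:
        raise ValueError("BRT fitting needs at least 100 records")
    features = ["sst_august"] + COVARIATES
    X = df[features].to_numpy(dtype=float)
    y = np.log1p(df["count_per_100m2"].to_numpy(dtype=float))
    hyper = dict(max_depth=tree_depth, learning_rate=learning_rate,
                 n_estimators=n_trees, subsample=bag_fraction)
    model = GradientBoostingRegressor(
        **hyper, validation_fraction=0.2, n_iter_no_change=20,
        random_state=seed,
    )
    model.fit(X, y)
    fixed = {c: float(df[c].mean()) for c in COVARIATES}
    return BRTComponent(model=model, feature_names=features, fixed_values=fixed,
                        seed=seed, hyperparameters=hyper)


def ensemble_weights(
    glm_component: GLMComponent,
    brt_component: BRTComponent,
    validation: SurveySet,
    scheme: str = "deviance",
) -> tuple[float, float]:
    """Component weights from held-out deviance.

    ``w_i ∝ exp(-Δ_i / 2)`` where ``Δ_i`` is component i's Poisson
    deviance on the validation set minus the best component's; identical
    skill gives (0.5, 0.5) and a deviance gap > 20 drives the better
    component's weight above 0.99.  ``scheme='equal'`` returns equal
    weights.
    """
    if len(validation) == 0:
        raise ValueError("validation set is empty")
    if scheme == "equal":
        return (0.5, 0.5)
    if scheme != "deviance":
        raise ValueError("scheme must be 'deviance' or 'equal'")
    df = validation.records
    y = df["count_per_100m2"].to_numpy(dtype=float)
    dev = np.array([
        poisson_deviance(y, glm_component.predict(df)),
        poisson_deviance(y, brt_component.predict(df)),
    ])
    delta = dev - dev.min()
    w = np.exp(-delta / 2.0)
    w = w / w.sum()
    return (float(w[0]), float(w[1]))


# ---------------------------------------------------------------------------
# spatial prediction
# ---------------------------------------------------------------------------

def predict_abundance(
    ensemble: SDMEnsemble,
    covariate_grids: dict[str, RasterGrid],
) -> RasterGrid:
    """Predict abundance (individuals per 100 m²) on covariate grids.

    ``covariate_grids`` must contain ``sst_august``; any covariate not
    supplied as a grid is held at the recipe's fixed (training-mean)
    value.  The prediction is the weighted mean of the GLM and BRT cell
    predictions and is non-negative wherever the SST grid is valid.
    """
    if "sst_august" not in covariate_grids:
        raise ValueError("missing covariate grid: 'sst_august'")
    sst = covariate_grids["sst_august"]
    for name, g in covariate_grids.items():
        if not regrid_check(sst, g):
            raise ValueError(f"covariate grid {name!r} geometry differs from SST grid")
    mask = sst.mask
    df = pd.DataFrame({"sst_august": sst.values[mask]})
    recipe = ensemble.glm_component
    for c in recipe.covariates:
        if c in covariate_grids:
            df[c] = covariate_grids[c].values[mask]
        elif c in recipe.fixed_values:
            df[c] = recipe.fixed_values[c]
        else:
            raise ValueError(f"missing covariate: {c!r}")
    pred = np.clip(ensemble.predict(df), 0.0, None)
    values = np.full(sst.shape, np.nan)
    values[mask] = pred
    return RasterGrid(values=values, geometry=sst.geometry, mask=mask.copy(),
                      variable="abundance")


def project_decades(
    ensemble: SDMEnsemble,
    baseline_august: RasterGrid,
    anomalies: dict,
    fixed_covariates: dict[str, RasterGrid] | None = None,
) -> GridStack:
    """Abundance projections at decadal slices.

    ``anomalies`` maps a label — typically ``(decade, scenario)`` — to a
    fine-resolution August-SST anomaly grid on the baseline geometry
    (the downscaling output).  All non-SST covariates are held at the
    recipe's fixed values unless supplied in ``fixed_covariates``.
    """
    fixed_covariates = fixed_covariates or {}
    grids, labels = [], []
    for label, anom in anomalies.items():
        if not regrid_check(baseline_august, anom):
            raise ValueError(f"anomaly {label!r} is not on the baseline geometry")
        sst = baseline_august.with_values(baseline_august.values + anom.values,
                                          variable="sst_august")
        cov = {"sst_august": sst, **fixed_covariates}
        grids.append(predict_abundance(ensemble, cov))
        labels.append(label)
    return GridStack(grids=grids, labels=labels)
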