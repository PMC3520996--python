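"""Climate-model validation, ranking, outlier screening and ensemble
averaging.

Candidate models are compared against an observed baseline field with
four statistics — bias, pattern correlation, RMSE and centred RMSE —
then placed on a level playing field by ranking each statistic and
summing the ranks (the *cumulative rank*; smaller is better).  An
outlier analysis compares each model's future projection with the mean
projection of all other models, and the top-k models are averaged,
unweighted, into the ensemble anomaly used for downscaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .grids import GridStack, RasterGrid, regrid_check

__all__ = [
    "SkillStats",
    "skill_stats",
    "rank_models",
    "outlier_analysis",
    "select_and_average",
]


@dataclass(frozen=True)
class SkillStats:
    """Validation statistics of one model against the observed field.

    Satisfies ``rmse**2 == bias**2 + centred_rmse**2`` up to float
    tolerance.
    """

    bias: float
    pattern_correlation: float
    rmse: float
    centred_rmse: float


def skill_stats(model_field: RasterGrid, observed_field: RasterGrid) -> SkillStats:
    """Bias, pattern correlation, RMSE and centred RMSE over shared sea cells.

    bias = spatial mean(model) − spatial mean(observed); centred RMSE
    and pattern correlation are computed after removing each field's
    spatial mean.
    """
    if not regrid_check(model_field, observed_field):
        raise ValueError("model and observed fields must share geometry")
    valid = model_field.mask & observed_field.mask
    if valid.sum() < 3:
        raise ValueError("need at least 3 shared valid cells")
    m = model_field.values[valid]
    o = observed_field.values[valid]
    bias = float(m.mean() - o.mean())
    diff = m - o
    rmse = float(np.sqrt(np.mean(diff**2)))
    mc, oc = m - m.mean(), o - o.mean()
    centred_rmse = float(np.sqrt(np.mean((mc - oc) ** 2)))
    denom = np.sqrt(np.sum(mc**2) * np.sum(oc**2))
    if denom == 0:
        # at least one field is spatially constant; correlation undefined,
        # report 1 for identical-anomaly (both constant) and 0 otherwise
        corr = 1.0 if np.allclose(mc, 0) and np.allclose(oc, 0) else 0.0
    else:
        corr = float(np.sum(mc * oc) / denom)
    return SkillStats(bias=bias, pattern_correlation=corr, rmse=rmse,
                      centred_rmse=centred_rmse)


_STATS = ("bias", "pattern_cor", "rmse", "centred_rmse")


def rank_models(tables: dict[str, SkillStats]) -> pd.DataFrame:
    """Per-statistic ranks and cumulative rank, sorted best first.

    Rank 1 is best: smallest |bias|, largest pattern correlation,
    smallest RMSE and centred RMSE.  Ties receive the average of the
    tied ranks.  Returns a DataFrame indexed by model with columns
    ``bias, pattern_cor, rmse, centred_rmse, rank_bias, rank_cor,
    rank_rmse, rank_crmse, cumulative_rank``.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 models to rank")
    for name, t in tables.items():
        for attr in ("bias", "pattern_correlation", "rmse", "centred_rmse"):
            v = getattr(t, attr, None)
            if v is None or not np.isfinite(v):
                raise ValueError(f"model {name!r} is missing statistic {attr!r}")
    names = list(tables)
    df = pd.DataFrame(
        {
            "bias": [tables[n].bias for n in names],
            "pattern_cor": [tables[n].pattern_correlation for n in names],
            "rmse": [tables[n].rmse for n in names],
            "centred_rmse": [tables[n].centred_rmse for n in names],
        },
        index=pd.Index(names, name="model"),
    )
    df["rank_bias"] = rankdata(np.abs(df["bias"]), method="average")
    df["rank_cor"] = rankdata(-df["pattern_cor"], method="average")
    df["rank_rmse"] = rankdata(df["rmse"], method="average")
    df["rank_crmse"] = rankdata(df["centred_rmse"], method="average")
    df["cumulative_rank"] = (
        df["rank_bias"] + df["rank_cor"] + df["rank_rmse"] + df["rank_crmse"]
    )
    return df.sort_values("cumulative_rank", kind="stable")


def _mean_fields(anomalies: dict[str, GridStack | RasterGrid]) -> dict[str, list[RasterGrid]]:
    """Normalize each model's entry to a list of grids."""
    out = {}
    for name, entry in anomalies.items():
        out[name] = [g for _, g in entry] if isinstance(entry, GridStack) else [entry]
    return out


def outlier_analysis(
    anomalies: dict[str, GridStack | RasterGrid],
    flag_multiple: float = 3.0,
) -> pd.DataFrame:
    """Leave-one-out departure of each model's projection from the rest.

    score(m) = spatial-mean absolute difference between model m's
    anomaly and the cell-wise mean of all other models' anomalies,
    averaged over the stack's slices.  Models whose score exceeds
    ``flag_multiple`` times the median score are flagged.
    """
    if len(anomalies) < 3:
        raise ValueError("outlier analysis needs at least 3 models")
    per_model = _mean_fields(anomalies)
    names = list(per_model)
    n_slices = len(per_model[names[0]])
    if any(len(v) != n_slices for v in per_model.values()):
        raise ValueError("all models must cover the same slices")
    scores = np.zeros(len(names))
    for s in range(n_slices):
        fields = np.stack([per_model[n][s].values for n in names])
        mask = per_model[names[0]][s].mask
        for i in range(len(names)):
            others = np.delete(fields, i, axis=0).mean(axis=0)
            scores[i] += float(np.mean(np.abs(fields[i] - others)[mask]))
    scores /= n_slices
    med = float(np.median(scores))
    flagged = scores > flag_multiple * med if med > 0 else np.zeros(len(names), bool)
    return pd.DataFrame(
        {"outlier_score": scores, "flagged": flagged},
        index=pd.Index(names, name="model"),
    )


def select_and_average(
    anomalies: dict[str, GridStack],
    ranking: pd.DataFrame,
    k: int = 5,
) -> GridStack:
    """Unweighted cell-wise mean of the top-k ranked models' anomalies.

    The ensemble mask is the intersection of the member masks.  The
    returned stack carries the same slice labels as the members.
    """
    if k > len(anomalies):
        raise ValueError(f"k={k} exceeds the {len(anomalies)} available models")
    if k < 1:
        raise ValueError("k must be >= 1")
    top = [m for m in ranking.index if m in anomalies][:k]
    if len(top) < k:
        raise ValueError("ranking does not cover k models present in anomalies")
    ref = anomalies[top[0]]
    labels = list(ref.labels)
    grids = []
    for label in labels:
        members = [anomalies[m][label] for m in top]
        mask = np.logical_and.reduce([g.mask for g in members])
        mean = np.nanmean(np.stack([g.values for g in members]), axis=0)
        grids.append(RasterGrid(values=np.where(mask, mean, np.nan),
                                geometry=ref.geometry, mask=mask,
                                variable="ensemble_anomaly"))
    return GridStack(grids=grids, labels=labels)
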