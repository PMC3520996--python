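"""Statistics of the juvenile-mortality temperature experiment.

Juvenile abalone were held in replicate aquaria at two temperatures (the
lower and upper March SST categories of the species' distribution) and
per-tank mortality percentages compared with a one-way ANOVA.  The tank
is the unit of replication — individuals within a tank are
pseudo-replicates and never enter the test, which is what gives the
two-group, four-tanks-per-group design its (1, 6) degrees of freedom.

Besides the raw-data ANOVA this module reconstructs the F statistic
from printed summary statistics (group means, standard errors and n),
an exact algebraic identity with the raw-data decomposition, and
computes the mortality fold change between temperatures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MortalityExperiment",
    "AnovaResult",
    "one_way_anova",
    "anova_from_summary",
    "fold_change",
]


@dataclass
class MortalityExperiment:
    """Tank-level mortality percentages grouped by temperature.

    ``data`` columns: ``temperature`` (group label), ``tank``,
    ``mortality_pct`` in [0, 100].
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        m = self.data["mortality_pct"]
        if ((m < 0) | (m > 100)).any():
            raise ValueError("mortality percentages must lie in [0, 100]")

    def groups(self) -> list[np.ndarray]:
        return [g["mortality_pct"].to_numpy(dtype=float)
                for _, g in self.data.groupby("temperature", sort=True)]

    def summary(self) -> pd.DataFrame:
        """Per-group mean, SD, SE and n."""
        out = self.data.groupby("temperature", sort=True)["mortality_pct"].agg(
            mean="mean", sd="std", n="size")
        out["se"] = out["sd"] / np.sqrt(out["n"])
        return out


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    infinite: bool = False  # zero within-group variance with distinct means

    def as_dict(self) -> dict:
        return {"F": self.F, "df_between": self.df_between,
                "df_within": self.df_within, "p": self.p,
                "infinite": self.infinite}


def _anova_from_ss(ss_between: float, ss_within: float,
                   k: int, n_total: int) -> AnovaResult:
    df_b, df_w = k - 1, n_total - k
    ms_b = ss_between / df_b
    if ss_within <= 0:
        if ms_b <= 0:
            return AnovaResult(F=0.0, df_between=df_b, df_within=df_w, p=1.0)
        return AnovaResult(F=np.inf, df_between=df_b, df_within=df_w, p=0.0,
                           infinite=True)
    F = ms_b / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(F=float(F), df_between=df_b, df_within=df_w, p=p)


def one_way_anova(experiment: MortalityExperiment | pd.DataFrame) -> AnovaResult:
    """One-way ANOVA on tank-level mortality.

    ``F = MS_between / MS_within`` with degrees of freedom
    ``(k - 1, N - k)``; the p-value is the upper tail of the F
    distribution.  Zero within-group variance with distinct group means
    is reported as an infinite-F flag with p = 0.
    """
    if isinstance(experiment, pd.DataFrame):
        experiment = MortalityExperiment(data=experiment)
    groups = experiment.groups()
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("need at least 2 tanks per group")
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_b = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_w = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    return _anova_from_ss(ss_b, ss_w, len(groups), all_vals.size)


def anova_from_summary(
    means: list[float],
    ses: list[float],
    n: list[int] | int,
) -> AnovaResult:
    """Reconstruct the one-way ANOVA from group means, SEs and n.

    Recovers each group's SD as ``SE * sqrt(n)``, pools the within-group
    variance, and rebuilds the between-group sum of squares from the
    means — algebraically identical to :func:`one_way_anova` on any raw
    data with those summaries.  Summaries printed at limited precision
    reproduce the raw-data F only up to their rounding.
    """
    means = np.asarray(means, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if np.isscalar(n) or isinstance(n, int):
        n = [int(n)] * len(means)
    n = np.asarray(n, dtype=int)
    if len(means) != len(ses) or len(means) != len(n):
        raise ValueError("means, ses and n must have equal length")
    if (n < 2).any():
        raise ValueError("every group needs n >= 2")
    if (ses < 0).any():
        raise ValueError("standard errors must be nonnegative")
    sds = ses * np.sqrt(n)
    n_total = int(n.sum())
    grand = float(np.sum(n * means) / n_total)
    ss_b = float(np.sum(n * (means - grand) ** 2))
    ss_w = float(np.sum((n - 1) * sds**2))
    return _anova_from_ss(ss_b, ss_w, len(means), n_total)


def fold_change(mean_treatment: float, mean_control: float) -> float:
    """Ratio of treatment to control mean mortality.

    Undefined (raises) when the control mean is zero.
    """
    if mean_control == 0:
        raise ValueError("fold change undefined: control mean is zero")
    return float(mean_treatment) / float(mean_control)
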