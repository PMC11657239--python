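"""One-way ANOVA across flooring materials and distribution summaries.

The ANOVA is the textbook fixed-effects decomposition: with k groups and
N values overall,

    SS_total = SS_between + SS_within,
    F = (SS_between / (k-1)) / (SS_within / (N-k)),

and the p-value is the upper tail of the F distribution at
(k-1, N-k) degrees of freedom.  ``anova_from_ss`` rebuilds a table from
printed sums of squares, which is how published ANOVA tables are
checked; the mean squares are always recomputed as SS/df.

Distribution summaries follow the Tukey boxplot convention (whiskers at
the most extreme values within 1.5 x IQR of the quartiles) with
type-7 (linear-interpolation) quantiles, plus a plain histogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import ValidationError


@dataclass
class AnovaTable:
    ss_between: float
    ss_within: float
    ss_total: float
    df_between: int
    df_within: int
    df_total: int
    ms_between: float
    ms_within: float
    f_ratio: float
    p_value: float


def _build_table(ss_between: float, df_between: int,
                 ss_within: float, df_within: int) -> AnovaTable:
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    f_ratio = ms_between / ms_within
    p_value = float(sps.f.sf(f_ratio, df_between, df_within))
    return AnovaTable(
        ss_between=ss_between, ss_within=ss_within, ss_total=ss_between + ss_within,
        df_between=df_between, df_within=df_within, df_total=df_between + df_within,
        ms_between=ms_between, ms_within=ms_within, f_ratio=f_ratio, p_value=p_value,
    )


def anova_oneway(groups) -> AnovaTable:
    """One-way fixed-effects ANOVA over a list of value lists."""
    arrays = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(arrays) < 2:
        raise ValidationError("need at least 2 groups")
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValidationError(f"group {i} has fewer than 2 values")
        if not np.all(np.isfinite(g)):
            raise ValidationError(f"group {i} has non-finite values")
    all_values = np.concatenate(arrays)
    grand = all_values.mean()
    ss_between = float(sum(g.size * (g.mean() - grand) ** 2 for g in arrays))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in arrays))
    return _build_table(ss_between, len(arrays) - 1, ss_within, all_values.size - len(arrays))


def anova_from_ss(ss_between: float, df_between: int,
                  ss_within: float, df_within: int) -> AnovaTable:
    """Rebuild an ANOVA table from its sums of squares and df.

    Useful for verifying published tables; mean squares and F come from
    SS/df regardless of what a printed table claims.
    """
    if df_between <= 0 or df_within <= 0:
        raise ValidationError("degrees of freedom must be positive")
    if ss_between < 0 or ss_within <= 0:
        raise ValidationError("sums of squares must be positive")
    return _build_table(float(ss_between), int(df_between),
                        float(ss_within), int(df_within))


@dataclass
class DistributionSummary:
    """Boxplot statistics (Tukey convention) plus a histogram."""

    n: int
    median: float
    q1: float
    q3: float
    iqr: float
    whisker_lo: float
    whisker_hi: float
    outliers: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray


def summarize_distribution(values, bins=10) -> DistributionSummary:
    """Quartiles (type-7), 1.5 x IQR whiskers, outliers and a histogram."""
    x = np.asarray(values, dtype=np.float64)
    if x.size == 0:
        raise ValidationError("cannot summarise an empty sample")
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite values")
    q1, median, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    outliers = np.sort(x[(x < lo_fence) | (x > hi_fence)])
    counts, bin_edges = np.histogram(x, bins=bins)
    return DistributionSummary(
        n=int(x.size), median=float(median), q1=float(q1), q3=float(q3),
        iqr=float(iqr), whisker_lo=float(inside.min()), whisker_hi=float(inside.max()),
        outliers=outliers, bin_edges=bin_edges, counts=counts,
    )


def material_feature_clusters(features, k: int = 4, seed: int = 0) -> np.ndarray:
    """Exploratory k-means on 2-D (accel, gyro) SVM feature summaries.

    Mirrors the material-classification scatter view; k defaults to the
    number of materials.  Seeded with 10 restarts for reproducibility.
    Not part of the quantitative pipeline.
    """
    from sklearn.cluster import KMeans

    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < k:
        raise ValidationError("need a 2-D feature matrix with at least k rows")
    return KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(X)


def anova_table_rows(label: str, table: AnovaTable) -> list[dict]:
    """Classification / SS / df / MS / F / p rows in the published layout."""
    return [
        {"classification": label, "component": "between",
         "sum_of_squares": table.ss_between, "df": table.df_between,
         "mean_square": table.ms_between, "f_ratio": table.f_ratio,
         "p_value": table.p_value},
        {"classification": label, "component": "within",
         "sum_of_squares": table.ss_within, "df": table.df_within,
         "mean_square": table.ms_within, "f_ratio": np.nan, "p_value": np.nan},
        {"classification": label, "component": "total",
         "sum_of_squares": table.ss_total, "df": table.df_total,
         "mean_square": np.nan, "f_ratio": np.nan, "p_value": np.nan},
    ]
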