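"""Group statistics for organoid assays.

The three comparison procedures used across the assays, plus the boxplot
summary convention (median, interquartile range, 5th/95th percentiles):

* one-way ANOVA followed by Dunnett's many-to-one post hoc test against a
  designated control (transcytosis constructs, knockout lines),
* the Friedman rank test for complete block designs (permeability assays
  blocked by independent experiment), and
* the Kruskal-Wallis test followed by Dunn's pairwise post hoc test with
  tie-corrected variance and Bonferroni adjustment.

Decisions use adjusted p < 0.05 throughout (configurable ``alpha``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, DataError

__all__ = [
    "BoxplotSummary",
    "ComparisonResult",
    "boxplot_summary",
    "anova_dunnett",
    "friedman_test",
    "kruskal_dunn",
    "groups_from_frame",
]

ALPHA = 0.05


@dataclass
class BoxplotSummary:
    """Order statistics reported in the assay boxplots."""

    n: int
    median: float
    q1: float
    q3: float
    p5: float
    p95: float


@dataclass
class ComparisonResult:
    """Omnibus test plus optional per-comparison adjusted p-values.

    ``comparisons`` has columns comparison / statistic / p_adjusted /
    significant (adjusted p below ``alpha``).
    """

    test: str
    statistic: float
    df: float
    pvalue: float
    comparisons: pd.DataFrame | None = None
    alpha: float = ALPHA

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "test": self.test,
                "comparison": "omnibus",
                "statistic": self.statistic,
                "df": self.df,
                "p": self.pvalue,
                "p_adjusted": np.nan,
                "significant": self.pvalue < self.alpha,
            }
        ]
        if self.comparisons is not None:
            for _, row in self.comparisons.iterrows():
                rows.append(
                    {
                        "test": self.test,
                        "comparison": row["comparison"],
                        "statistic": row["statistic"],
                        "df": np.nan,
                        "p": np.nan,
                        "p_adjusted": row["p_adjusted"],
                        "significant": bool(row["significant"]),
                    }
                )
        return pd.DataFrame(rows)


def groups_from_frame(
    data: pd.DataFrame, value_col: str = "value", group_col: str = "condition"
) -> dict:
    """Split a tidy table into ordered label -> value-array groups."""
    out = {}
    for label in pd.unique(data[group_col]):
        out[label] = data.loc[data[group_col] == label, value_col].to_numpy(dtype=float)
    return out


def _as_groups(data, value_col="value", group_col="condition") -> dict:
    if isinstance(data, pd.DataFrame):
        data = groups_from_frame(data, value_col, group_col)
    groups = {k: np.asarray(v, dtype=float) for k, v in data.items()}
    if len(groups) < 2:
        raise DataError("need at least 2 conditions")
    for label, vals in groups.items():
        if vals.size < 2:
            raise DataError(f"group {label!r} needs n >= 2")
        if not np.isfinite(vals).all():
            raise DataError(f"group {label!r} contains non-finite values")
    return groups


def boxplot_summary(values) -> BoxplotSummary:
    """Median, quartiles and 5th/95th percentiles (linear interpolation
    between order statistics)."""
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise DataError("empty input")
    p5, q1, med, q3, p95 = np.percentile(vals, [5, 25, 50, 75, 95], method="linear")
    return BoxplotSummary(
        n=int(vals.size), median=float(med), q1=float(q1), q3=float(q3), p5=float(p5), p95=float(p95)
    )


def anova_dunnett(
    data,
    control: str,
    value_col: str = "value",
    group_col: str = "condition",
    alpha: float = ALPHA,
    seed: int = 0,
) -> ComparisonResult:
    """One-way ANOVA with Dunnett's two-sided many-to-one post hoc test.

    Adjusted p-values come from the max-|t| distribution of the multivariate
    t model for many-to-one contrasts (seeded numerical evaluation, so
    results are reproducible).
    """
    groups = _as_groups(data, value_col, group_col)
    if control not in groups:
        raise DataError(f"control label {control!r} not among groups {sorted(groups)}")
    labels = [k for k in groups if k != control]
    arrays = [groups[k] for k in labels]
    control_vals = groups[control]
    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0 or all(np.ptp(g) == 0 for g in groups.values()):
        raise AnalysisError("zero pooled variance: ANOVA undefined")

    f_stat, f_p = stats.f_oneway(*groups.values())
    k = len(groups)
    n_total = pooled.size
    df = (k - 1, n_total - k)

    res = stats.dunnett(
        *arrays,
        control=control_vals,
        alternative="two-sided",
        random_state=np.random.default_rng(seed),
    )
    comps = pd.DataFrame(
        {
            "comparison": [f"{lab} vs {control}" for lab in labels],
            "statistic": np.atleast_1d(res.statistic).astype(float),
            "p_adjusted": np.clip(np.atleast_1d(res.pvalue).astype(float), 0.0, 1.0),
        }
    )
    comps["significant"] = comps["p_adjusted"] < alpha
    return ComparisonResult(
        test="anova_dunnett",
        statistic=float(f_stat),
        df=df[0],
        pvalue=float(f_p),
        comparisons=comps,
        alpha=alpha,
    )


def friedman_test(matrix) -> ComparisonResult:
    """Friedman rank test on a complete blocks x conditions matrix.

    Within-block average ranks with tie correction:
    ``chi2_F = [12 / (n k (k+1)) sum_j R_j^2 - 3 n (k+1)] / C`` where
    ``C = 1 - sum(t^3 - t) / (n k (k^2 - 1))`` over tie groups. When every
    block is fully tied the statistic is 0 with p = 1. The p-value is the
    chi-square upper tail with k-1 degrees of freedom.
    """
    if isinstance(matrix, pd.DataFrame):
        matrix = matrix.to_numpy(dtype=float)
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise DataError("Friedman input must be a 2-D blocks x conditions matrix")
    n, k = X.shape
    if n < 2 or k < 2:
        raise DataError("need >= 2 blocks and >= 2 conditions")
    if not np.isfinite(X).all():
        raise DataError("incomplete matrix: non-finite entries")

    ranks = np.apply_along_axis(stats.rankdata, 1, X)
    Rj = ranks.sum(axis=0)
    chi = 12.0 / (n * k * (k + 1)) * float(Rj @ Rj) - 3.0 * n * (k + 1)
    ties = 0.0
    for row in X:
        _, counts = np.unique(row, return_counts=True)
        ties += float((counts**3 - counts).sum())
    correction = 1.0 - ties / (n * k * (k**2 - 1))
    if correction <= 0:
        return ComparisonResult(test="friedman", statistic=0.0, df=k - 1, pvalue=1.0)
    chi /= correction
    chi = max(chi, 0.0)
    p = float(stats.chi2.sf(chi, k - 1))
    return ComparisonResult(test="friedman", statistic=float(chi), df=k - 1, pvalue=p)


def _dunn_comparisons(groups: dict, alpha: float, adjust: str) -> pd.DataFrame:
    labels = list(groups)
    values = np.concatenate([groups[g] for g in labels])
    sizes = np.array([groups[g].size for g in labels])
    N = values.size
    ranks = stats.rankdata(values)
    mean_ranks = {}
    start = 0
    for lab, sz in zip(labels, sizes):
        mean_ranks[lab] = ranks[start : start + sz].mean()
        start += sz
    _, counts = np.unique(values, return_counts=True)
    tie_sum = float((counts**3 - counts).sum())
    base_var = N * (N + 1) / 12.0 - tie_sum / (12.0 * (N - 1))
    pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1 :]]
    m = len(pairs)
    rows = []
    for a, b in pairs:
        na, nb = groups[a].size, groups[b].size
        se = np.sqrt(base_var * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        p_adj = min(1.0, p * m) if adjust == "bonferroni" else p
        rows.append(
            {
                "comparison": f"{a} vs {b}",
                "statistic": float(z),
                "p_unadjusted": float(p),
                "p_adjusted": float(p_adj),
                "significant": p_adj < alpha,
            }
        )
    return pd.DataFrame(rows)


def kruskal_dunn(
    data,
    value_col: str = "value",
    group_col: str = "condition",
    alpha: float = ALPHA,
    adjust: str = "bonferroni",
) -> ComparisonResult:
    """Kruskal-Wallis omnibus test with Dunn's pairwise post hoc test.

    H uses the tie-corrected rank form (chi-square with k-1 df); Dunn z
    statistics use the tie-corrected rank variance and, by default,
    Bonferroni adjustment over all pairs. When every value is identical the
    omnibus is the degenerate H = 0, p = 1.
    """
    if adjust not in ("bonferroni", "none"):
        raise DataError(f"unknown adjustment {adjust!r}")
    groups = _as_groups(data, value_col, group_col)
    pooled = np.concatenate(list(groups.values()))
    k = len(groups)
    if np.ptp(pooled) == 0:
        comps = _dunn_comparisons(groups, alpha, adjust)
        return ComparisonResult(
            test="kruskal_dunn", statistic=0.0, df=k - 1, pvalue=1.0, comparisons=comps, alpha=alpha
        )
    h, p = stats.kruskal(*groups.values())
    comps = _dunn_comparisons(groups, alpha, adjust)
    return ComparisonResult(
        test="kruskal_dunn",
        statistic=float(h),
        df=k - 1,
        pvalue=float(p),
        comparisons=comps,
        alpha=alpha,
    )
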