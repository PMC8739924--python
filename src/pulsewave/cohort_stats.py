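"""Case-control cohort statistics.

Continuous features are summarised as median (Q1, Q3) and compared with the
Wilcoxon-Mann-Whitney test (normal approximation with tie-corrected
variance, two-sided) pairwise, plus a tie-corrected Kruskal-Wallis omnibus
test across the three lesion groups. Categorical tables are compared with
Pearson's chi-squared test without continuity correction. A one-way ANOVA F
can be reconstructed from per-group summary statistics (mean, SD, n) for
comparison against published baseline tables.

Pairwise P values are reported unadjusted by default, mirroring the usual
per-test significance marks in case-control tables; Bonferroni adjustment
of the significance threshold is available but off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .exceptions import ParameterError

__all__ = [
    "ContingencyTable",
    "GroupComparisonResult",
    "median_iqr",
    "mann_whitney_z",
    "kruskal_wallis",
    "chi_square",
    "anova_from_summary",
    "compare_groups",
    "comparison_frame",
]

#: quartile convention used throughout (numpy default, a.k.a. type 7)
QUARTILE_METHOD = "linear (type 7)"


@dataclass(frozen=True)
class ContingencyTable:
    """Counts of a categorical factor per group (groups x categories)."""

    counts: np.ndarray
    group_labels: tuple = ()
    category_labels: tuple = ()

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ParameterError("contingency table must be at least 2x2")
        if np.any(counts < 0):
            raise ParameterError("contingency counts must be non-negative")


@dataclass(frozen=True)
class GroupComparisonResult:
    """One feature's group summaries, omnibus test, and pairwise contrasts."""

    feature: str
    groups: tuple
    summaries: dict  # group -> (median, q1, q3)
    n_per_group: dict
    h_statistic: float
    df: int
    p_omnibus: float
    pairwise: dict  # (a, b) -> (U, Z, P)
    alpha: float
    significant_omnibus: bool
    significant_pairs: dict  # (a, b) -> bool
    quartile_method: str = QUARTILE_METHOD


def median_iqr(values) -> tuple[float, float, float]:
    """Median and quartiles by linear interpolation (type 7)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ParameterError("median_iqr needs at least one finite value")
    med, q1, q3 = np.percentile(v, [50, 25, 75])
    return float(med), float(q1), float(q3)


def _tie_term(all_values: np.ndarray) -> float:
    _, counts = np.unique(all_values, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def mann_whitney_z(x, y) -> tuple[float, float, float]:
    """Mann-Whitney U (of the first sample), tie-corrected Z, two-sided P."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ParameterError("both samples need at least 2 values")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sstats.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    tie = _tie_term(pooled)
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    if var <= 0:
        return u1, 0.0, 1.0
    z = (u1 - n1 * n2 / 2.0) / math.sqrt(var)
    p = min(1.0, 2.0 * sstats.norm.sf(abs(z)))
    return u1, z, p


def kruskal_wallis(groups) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H against a chi-squared reference."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 1 for a in arrays):
        raise ParameterError("need at least 2 groups, each with at least 1 value")
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = sstats.rankdata(pooled)
    h = 0.0
    start = 0
    for a in arrays:
        r = ranks[start : start + a.size].sum()
        h += r * r / a.size
        start += a.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    correction = 1.0 - _tie_term(pooled) / (n**3 - n)
    df = len(arrays) - 1
    if correction <= 0:
        return 0.0, df, 1.0
    h /= correction
    return float(h), df, float(sstats.chi2.sf(h, df))


def chi_square(table) -> tuple[float, int, float]:
    """Pearson chi-squared (no continuity correction) on a groups x categories table."""
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table, float)
    ContingencyTable(counts)  # validates shape and non-negativity
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ParameterError("contingency table has a zero marginal")
    x2, p, df, _ = sstats.chi2_contingency(counts, correction=False)
    return float(x2), int(df), float(p)


def anova_from_summary(means, sds, ns) -> tuple[float, int, int, float]:
    """Classic one-way ANOVA F reconstructed from group means, SDs, sizes."""
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if not (means.size == sds.size == ns.size) or means.size < 2:
        raise ParameterError("need matching means/sds/ns for at least 2 groups")
    if np.any(ns < 2):
        raise ParameterError("every group needs n >= 2")
    if np.any(sds <= 0):
        raise ParameterError("every group needs a positive SD")
    grand = float((ns * means).sum() / ns.sum())
    df1 = means.size - 1
    df2 = int(ns.sum()) - means.size
    ms_between = float((ns * (means - grand) ** 2).sum()) / df1
    ms_within = float(((ns - 1) * sds**2).sum()) / df2
    f = ms_between / ms_within
    return f, df1, df2, float(sstats.f.sf(f, df1, df2))


def compare_groups(
    features,
    labels=None,
    *,
    feature_names=None,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> list[GroupComparisonResult]:
    """Full per-feature group comparison.

    Parameters
    ----------
    features : DataFrame
        Cohort table; if ``labels`` is None it must contain a ``group``
        column. Non-feature columns (ids, demographics flags) are excluded
        via ``feature_names`` when given, else every numeric column except
        ``group`` is compared.
    alpha : float
        Per-test two-sided significance level for the flags.
    bonferroni : bool
        When true, pairwise flags use ``alpha`` divided by the number of
        pairwise contrasts per feature.
    """
    import pandas as pd

    df = pd.DataFrame(features)
    if labels is None:
        if "group" not in df.columns:
            raise ParameterError("no labels given and no 'group' column present")
        labels = df["group"].to_numpy()
        df = df.drop(columns=["group"])
    labels = np.asarray(labels)
    if feature_names is None:
        feature_names = [
            c for c in df.columns
            if c not in ("subject_id",) and np.issubdtype(df[c].dtype, np.number)
        ]
    groups = sorted(pd.unique(labels).tolist())
    if len(groups) < 2:
        raise ParameterError("need at least 2 groups to compare")
    for g in groups:
        if int((labels == g).sum()) < 2:
            raise ParameterError(f"group {g!r} has fewer than 2 subjects")
    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1 :]]
    pair_alpha = alpha / len(pairs) if bonferroni else alpha
    results = []
    for name in feature_names:
        col = df[name].to_numpy(dtype=float)
        per_group = {g: col[(labels == g) & np.isfinite(col)] for g in groups}
        summaries = {g: median_iqr(v) for g, v in per_group.items()}
        h, dof, p_omni = kruskal_wallis([per_group[g] for g in groups])
        pairwise = {}
        sig_pairs = {}
        for a, b in pairs:
            u, z, p = mann_whitney_z(per_group[a], per_group[b])
            pairwise[(a, b)] = (u, z, p)
            sig_pairs[(a, b)] = bool(p < pair_alpha)
        results.append(
            GroupComparisonResult(
                feature=name,
                groups=tuple(groups),
                summaries=summaries,
                n_per_group={g: int(v.size) for g, v in per_group.items()},
                h_statistic=h,
                df=dof,
                p_omnibus=p_omni,
                pairwise=pairwise,
                alpha=alpha,
                significant_omnibus=bool(p_omni < alpha),
                significant_pairs=sig_pairs,
            )
        )
    return results


def comparison_frame(results: list[GroupComparisonResult]):
    """Flatten comparison results to one row per feature per contrast."""
    import pandas as pd

    rows = []
    for res in results:
        for g in res.groups:
            m, q1, q3 = res.summaries[g]
            rows.append(
                {"feature": res.feature, "contrast": f"group{g}", "median": m,
                 "q1": q1, "q3": q3, "n": res.n_per_group[g],
                 "statistic": math.nan, "p": math.nan, "significant": ""}
            )
        rows.append(
            {"feature": res.feature, "contrast": "omnibus", "median": math.nan,
             "q1": math.nan, "q3": math.nan, "n": sum(res.n_per_group.values()),
             "statistic": res.h_statistic, "p": res.p_omnibus,
             "significant": str(res.significant_omnibus)}
        )
        for (a, b), (u, z, p) in res.pairwise.items():
            rows.append(
                {"feature": res.feature, "contrast": f"group{a}_vs_group{b}",
                 "median": math.nan, "q1": math.nan, "q3": math.nan,
                 "n": res.n_per_group[a] + res.n_per_group[b],
                 "statistic": z, "p": p,
                 "significant": str(res.significant_pairs[(a, b)])}
            )
    return pd.DataFrame(rows)
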