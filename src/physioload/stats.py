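"""Level-wise statistical comparisons: ANOVA, Tukey HSD, Benjamini-Hochberg.

For each feature column the report carries group summary statistics (mean,
median, SD, SE = SD/sqrt(n)), the one-way ANOVA F and p, Tukey's honestly
significant difference p per level pair (Tukey-Kramer for unbalanced
groups), and Benjamini-Hochberg-adjusted Welch two-sample t p-values per
pair. Welch's t is the base test feeding the BH adjustment (configurable).
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import FeatureTable

PAIRS = ((0, 1), (0, 2), (1, 2))


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA F test across >= 2 groups of >= 2 values.

    Degenerate inputs follow the F statistic's limits: zero between-group
    variance gives (F=0, p=1); zero within-group variance with distinct
    means gives (F=inf, p=0).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.shape[0] < 2 for g in groups):
        raise ValueError("ANOVA requires >= 2 groups with >= 2 values each")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = sps.f_oneway(*groups)
    f = np.where(np.isnan(f), 0.0, f)
    p = np.where(np.isnan(p), 1.0, p)
    if np.ndim(f) == 0:
        return float(f), float(p)
    return f, p


def tukey_hsd(groups: list[np.ndarray]) -> dict[tuple[int, int], float]:
    """Tukey HSD pairwise p-values (studentized range, pooled error variance).

    Returns ``{(i, j): p}`` for every group pair ``i < j``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    res = sps.tukey_hsd(*groups)
    return {
        (i, j): float(res.pvalue[i, j])
        for i, j in itertools.combinations(range(len(groups)), 2)
    }


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Monotone in the input ranks and capped at 1; rejecting hypotheses whose
    adjusted p is at most alpha controls the false discovery rate at alpha.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


def welch_t(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Welch two-sample t-test p-value."""
    return float(sps.ttest_ind(a, b, equal_var=False).pvalue)


def pairwise_report(table: FeatureTable, features: list[str] | None = None
                    ) -> pd.DataFrame:
    """Per-feature level comparison: one row per (feature, level pair).

    Columns: group summaries for both levels of the pair, the feature's
    ANOVA F/p across all levels present, the Tukey HSD pair p, and the
    BH-adjusted Welch-t pair p (adjustment applied across the pairs of each
    feature).
    """
    if features is None:
        features = table.columns
    levels = sorted(np.unique(table.labels).tolist())
    rows = []
    for feat in features:
        col = table.data[feat].to_numpy(dtype=float)
        groups = {lvl: col[table.labels == lvl] for lvl in levels}
        anova_f, anova_p = one_way_anova([groups[lvl] for lvl in levels])
        tukey = tukey_hsd([groups[lvl] for lvl in levels])
        pairs = [(i, j) for i, j in PAIRS if i in groups and j in groups]
        raw = np.array([welch_t(groups[i], groups[j]) for i, j in pairs])
        adj = benjamini_hochberg(raw)
        for k, (i, j) in enumerate(pairs):
            gi, gj = groups[i], groups[j]
            rows.append({
                "feature": feat,
                "pair": f"{i}-{j}",
                "mean_a": gi.mean(), "mean_b": gj.mean(),
                "median_a": float(np.median(gi)), "median_b": float(np.median(gj)),
                "sd_a": gi.std(ddof=1), "sd_b": gj.std(ddof=1),
                "se_a": gi.std(ddof=1) / np.sqrt(gi.size),
                "se_b": gj.std(ddof=1) / np.sqrt(gj.size),
                "anova_F": anova_f, "anova_p": anova_p,
                "p_tukey": tukey[(levels.index(i), levels.index(j))],
                "p_bh": adj[k],
            })
    return pd.DataFrame(rows, columns=[
        "feature", "pair", "mean_a", "mean_b", "median_a", "median_b",
        "sd_a", "sd_b", "se_a", "se_b", "anova_F", "anova_p", "p_tukey", "p_bh",
    ])


def group_summary(table: FeatureTable, features: list[str] | None = None
                  ) -> pd.DataFrame:
    """Mean / median / SD / SE per feature and workload level."""
    if features is None:
        features = table.columns
    rows = []
    for feat in features:
        col = table.data[feat].to_numpy(dtype=float)
        for lvl in sorted(np.unique(table.labels).tolist()):
            g = col[table.labels == lvl]
            rows.append({
                "feature": feat, "level": lvl, "n": g.size,
                "mean": g.mean(), "median": float(np.median(g)),
                "sd": g.std(ddof=1), "se": g.std(ddof=1) / np.sqrt(g.size),
            })
    return pd.DataFrame(rows)
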