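"""Univariate fold-change and significance tables.

For every (metabolite, group comparison) pair the table reports the log2
ratio of arithmetic group means, a two-sample test p-value (Student/Welch t
if both groups pass a Shapiro-Wilk normality check, Mann-Whitney U
otherwise), the Benjamini-Hochberg adjusted p-value (adjusted across the
metabolites within each comparison) and a star flag at the conventional
0.05 / 0.01 / 0.001 thresholds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import QuantMatrix

__all__ = [
    "log2_fold_change",
    "choose_test",
    "bh_adjust",
    "stars_for",
    "stats_table",
]


def log2_fold_change(m: QuantMatrix, comparison: tuple[str, str]) -> pd.Series:
    """log2(mean(group A) / mean(group B)) per metabolite.

    Arithmetic means of the (normalized) abundances; both groups need at
    least 2 samples and positive means.
    """
    ga, gb = comparison
    A, B = m.group_values(ga), m.group_values(gb)
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("both groups need at least 2 samples")
    ma, mb = A.mean(axis=0), B.mean(axis=0)
    if np.any(ma <= 0) or np.any(mb <= 0):
        raise ValueError("non-positive group mean; fold change undefined")
    # difference of logs keeps log2fc(A,B) == -log2fc(B,A) exact in floats
    return pd.Series(
        np.log2(ma) - np.log2(mb), index=m.feature_names, name=f"{ga}_vs_{gb}"
    )


def choose_test(samples_a, samples_b, alpha_normality: float = 0.05) -> str:
    """Pick ``"t"`` if both samples pass Shapiro-Wilk at ``alpha_normality``,
    else ``"mann_whitney"``."""
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 samples per group for the normality gate")
    pa = sps.shapiro(a).pvalue
    pb = sps.shapiro(b).pvalue
    return "t" if (pa > alpha_normality and pb > alpha_normality) else "mann_whitney"


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order.

    Sort ascending, multiply by m/rank, enforce monotone non-increasing from
    the largest rank downwards, cap at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def stars_for(p_adj: float) -> str:
    if p_adj < 0.001:
        return "***"
    if p_adj < 0.01:
        return "**"
    if p_adj < 0.05:
        return "*"
    return ""


def _two_sample_p(a: np.ndarray, b: np.ndarray, test: str, t_variant: str) -> float:
    if test == "t":
        res = sps.ttest_ind(a, b, equal_var=(t_variant == "student"))
    elif test == "mann_whitney":
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.pvalue)


def stats_table(
    m: QuantMatrix,
    comparisons: list[tuple[str, str]],
    alpha_normality: float = 0.05,
    t_variant: str = "welch",
    bh_scope: str = "per_comparison",
) -> pd.DataFrame:
    """Full fold-change/significance table across group comparisons.

    One row per (metabolite, comparison) with columns ``metabolite``,
    ``comparison``, ``log2fc``, ``test_used``, ``p_raw``, ``p_adj``,
    ``stars``. BH adjustment is applied across metabolites within each
    comparison by default (``bh_scope="global"`` pools all comparisons).
    """
    if t_variant not in ("welch", "student"):
        raise ValueError(f"unknown t_variant {t_variant!r}")
    if bh_scope not in ("per_comparison", "global"):
        raise ValueError(f"unknown bh_scope {bh_scope!r}")
    records = []
    for ga, gb in comparisons:
        fc = log2_fold_change(m, (ga, gb))
        A, B = m.group_values(ga), m.group_values(gb)
        for j, met in enumerate(m.feature_names):
            test = choose_test(A[:, j], B[:, j], alpha_normality)
            p = _two_sample_p(A[:, j], B[:, j], test, t_variant)
            records.append(
                {
                    "metabolite": met,
                    "comparison": f"{ga}_vs_{gb}",
                    "log2fc": float(fc.iloc[j]),
                    "test_used": test,
                    "p_raw": p,
                }
            )
    df = pd.DataFrame(
        records,
        columns=["metabolite", "comparison", "log2fc", "test_used", "p_raw"],
    )
    if df.empty:
        df["p_adj"] = pd.Series(dtype=float)
        df["stars"] = pd.Series(dtype=str)
        return df
    if bh_scope == "per_comparison":
        df["p_adj"] = df.groupby("comparison", sort=False)["p_raw"].transform(
            lambda s: bh_adjust(s.to_numpy())
        )
    else:
        df["p_adj"] = bh_adjust(df["p_raw"].to_numpy())
    df["stars"] = [stars_for(p) for p in df["p_adj"]]
    return df


def wide_table(stats: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long table into the per-comparison (log2fc, stars) layout."""
    if stats.empty:
        return pd.DataFrame()
    wide = stats.pivot(index="metabolite", columns="comparison")
    cols = []
    for comp in stats["comparison"].unique():
        for fieldname in ("log2fc", "stars", "p_raw", "p_adj", "test_used"):
            cols.append((fieldname, comp))
    wide = wide[cols]
    wide.columns = [f"{comp}:{fieldname}" for fieldname, comp in wide.columns]
    return wide.loc[stats["metabolite"].unique()]
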