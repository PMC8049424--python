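"""Two-group differential abundance: fold changes with p- and q-values.

Per feature, the log2 fold change between group means (pseudocount-
stabilised) and a two-sided test: Wilcoxon rank-sum with normal
approximation and tie correction (default; robust for skewed abundance
data) or Welch's t. Benjamini–Hochberg FDR q-values are reported
alongside the raw p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .tables import FeatureTable, format_key

__all__ = ["ComparisonResult", "compare_groups", "comparison_frame"]


@dataclass(frozen=True)
class ComparisonResult:
    feature_key: tuple[str, str]
    mean_a: float
    mean_b: float
    log2_fold_change: float
    p_value: float
    q_value: float


def _test_feature(a: np.ndarray, b: np.ndarray, test: str) -> float:
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return 1.0  # all observations tied: no evidence either way
    if test == "ranksum":
        res = sps.mannwhitneyu(b, a, alternative="two-sided", method="asymptotic")
        return float(res.pvalue)
    if test == "welch":
        res = sps.ttest_ind(b, a, equal_var=False)
        p = float(res.pvalue)
        return 1.0 if np.isnan(p) else p
    raise ValueError(f"unknown test {test!r}")


def compare_groups(
    table: FeatureTable,
    labels: Mapping[str, str],
    test: Literal["ranksum", "welch"] = "ranksum",
    pseudocount: float | None = None,
    group_order: tuple[str, str] | None = None,
) -> list[ComparisonResult]:
    """Compare feature abundances between two groups of samples.

    ``labels`` maps every sample id to one of two group names; with
    groups (A, B) — ``group_order`` or the sorted pair — the fold change
    is log2((mean_B + eps) / (mean_A + eps)). The pseudocount eps
    defaults to half the smallest positive value in the table (1e-6 if
    the table is all zero). Results are sorted by p-value then key.
    """
    samples = table.sample_ids
    unlabelled = [s for s in samples if s not in labels]
    if unlabelled:
        raise ValueError(f"unlabelled samples: {unlabelled}")
    groups = sorted({labels[s] for s in samples})
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    if group_order is not None:
        if sorted(group_order) != groups:
            raise ValueError(f"group_order {group_order} does not match labels {groups}")
        groups = list(group_order)
    ga, gb = groups
    idx_a = [i for i, s in enumerate(samples) if labels[s] == ga]
    idx_b = [i for i, s in enumerate(samples) if labels[s] == gb]
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("each group needs >= 2 samples")

    values = table.values
    if pseudocount is None:
        positive = values[values > 0]
        pseudocount = float(positive.min()) / 2 if positive.size else 1e-6

    keys = table.feature_keys
    raw: list[tuple[tuple[str, str], float, float, float, float]] = []
    for row, key in zip(values, keys):
        a, b = row[idx_a], row[idx_b]
        mean_a, mean_b = float(a.mean()), float(b.mean())
        lfc = float(np.log2((mean_b + pseudocount) / (mean_a + pseudocount)))
        raw.append((key, mean_a, mean_b, lfc, _test_feature(a, b, test)))

    pvals = np.array([r[4] for r in raw]) if raw else np.array([])
    qvals = multipletests(pvals, method="fdr_bh")[1] if raw else np.array([])
    results = [
        ComparisonResult(key, ma, mb, lfc, p, float(q))
        for (key, ma, mb, lfc, p), q in zip(raw, qvals)
    ]
    results.sort(key=lambda r: (r.p_value, r.feature_key))
    return results


def comparison_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    """Tabular view of comparison results (one row per feature)."""
    return pd.DataFrame(
        {
            "feature": [format_key(*r.feature_key) for r in results],
            "mean_a": [r.mean_a for r in results],
            "mean_b": [r.mean_b for r in results],
            "log2_fold_change": [r.log2_fold_change for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
        }
    )
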