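"""Two-group feature comparison with normality-gated tests and FDR.

Each feature is compared between the two cohorts with Student's t-test when
both groups pass a Shapiro–Wilk normality check (alpha = 0.05), otherwise
with the Mann–Whitney U test; two-sided p-values are corrected across each
feature family (fractal features and texture features separately) with the
Benjamini–Hochberg step-up procedure, and significance is declared at
adjusted p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "choose_test",
    "compare_feature",
    "fdr_adjust",
    "summarize_cohort",
]

ALPHA = 0.05


@dataclass
class StatResult:
    feature: str
    mean_sd_group1: Tuple[float, float]
    mean_sd_group2: Tuple[float, float]
    test_used: str          # "t_test" | "mann_whitney"
    p_raw: float
    p_adjusted: float = float("nan")
    significant: bool = False
    n1: int = 0
    n2: int = 0


def _clean(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[np.isfinite(x)]


def choose_test(x: Sequence[float], y: Sequence[float]) -> str:
    """t_test iff both samples pass Shapiro–Wilk at alpha = 0.05."""
    x, y = _clean(x), _clean(y)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each sample needs n >= 3 for the normality gate")
    for s in (x, y):
        if np.ptp(s) == 0:
            # constant sample: degenerate for Shapiro-Wilk, clearly non-normal
            return "mann_whitney"
        if stats.shapiro(s).pvalue < ALPHA:
            return "mann_whitney"
    return "t_test"


def compare_feature(x: Sequence[float], y: Sequence[float],
                    feature: str = "") -> StatResult:
    """Two-sided gated comparison; missing values are dropped per group.

    Identical zero-variance samples are a no-effect degenerate case and get
    p = 1 by convention.
    """
    x, y = _clean(x), _clean(y)
    test = choose_test(x, y)
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        p = 1.0
    elif test == "t_test":
        p = float(stats.ttest_ind(x, y).pvalue)
    else:
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    return StatResult(
        feature=feature,
        mean_sd_group1=(float(np.mean(x)), float(np.std(x, ddof=1))),
        mean_sd_group2=(float(np.mean(y)), float(np.std(y, ddof=1))),
        test_used=test,
        p_raw=p,
        n1=len(x),
        n2=len(y),
    )


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=ALPHA, method="fdr_bh")[1]


def summarize_cohort(table: pd.DataFrame, label_col: str = "label",
                     group1: str = "LGG", group2: str = "HGG",
                     feature_cols: Optional[Sequence[str]] = None
                     ) -> List[StatResult]:
    """Per-feature gated comparison with FDR applied across the given
    feature family.  Callers adjust fractal and texture families separately
    by passing the corresponding column subsets."""
    if feature_cols is None:
        feature_cols = [c for c in table.columns if c != label_col]
    feature_cols = list(feature_cols)
    if not feature_cols or table.empty:
        return []
    g1 = table[table[label_col] == group1]
    g2 = table[table[label_col] == group2]
    results = []
    for col in feature_cols:
        results.append(compare_feature(g1[col], g2[col], feature=col))
    adjusted = fdr_adjust([r.p_raw for r in results])
    for r, padj in zip(results, adjusted):
        r.p_adjusted = float(padj)
        r.significant = bool(padj < ALPHA)
    return results


def results_to_frame(results: List[StatResult]) -> pd.DataFrame:
    """Flatten StatResults into the familiar 'M ± SD | p' table layout."""
    rows = []
    for r in results:
        rows.append({
            "feature": r.feature,
            "group1_mean": r.mean_sd_group1[0],
            "group1_sd": r.mean_sd_group1[1],
            "group2_mean": r.mean_sd_group2[0],
            "group2_sd": r.mean_sd_group2[1],
            "test": r.test_used,
            "p_raw": r.p_raw,
            "p_adjusted": r.p_adjusted,
            "significant": r.significant,
            "n1": r.n1,
            "n2": r.n2,
        })
    return pd.DataFrame(rows)
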