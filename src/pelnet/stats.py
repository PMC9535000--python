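"""Rank-based group comparisons and FDR control.

These are the shared screening primitives: Wilcoxon rank-sum for
two-group contrasts, Kruskal–Wallis for the three-sector contrasts, and
Benjamini–Hochberg step-up q-values for every multi-feature screen
(significance declared at q <= 0.05 throughout the pipeline).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError


@dataclass
class TestResult:
    statistic: float
    pvalue: float
    method: str
    n_per_group: tuple
    qvalue: Optional[float] = None

    def __post_init__(self):
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValidationError(f"p-value {self.pvalue} outside [0, 1]")


def _has_ties(pooled: np.ndarray) -> bool:
    return len(np.unique(pooled)) < len(pooled)


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U) test.

    Exact enumeration of the U distribution for small tie-free samples
    (n_x + n_y <= 12), otherwise the normal approximation with mid-rank
    tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each group needs at least 2 observations")
    pooled = np.concatenate([x, y])
    exact = len(pooled) <= 12 and not _has_ties(pooled)
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(res.pvalue),
                      f"wilcoxon-{method}", (len(x), len(y)))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal–Wallis H with mid-rank tie correction and chi-square p
    on k - 1 degrees of freedom."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValidationError("each group needs at least 2 observations")
    res = sps.kruskal(*groups)
    return TestResult(float(res.statistic), float(res.pvalue),
                      "kruskal-wallis", tuple(len(g) for g in groups))


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """Step-up Benjamini–Hochberg q-values, in the input order.

    q-values are monotone (enforced by the step-up recursion) and never
    smaller than the raw p-values.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def feature_screen(values: pd.DataFrame, groups: pd.Series,
                   test: str = "auto") -> pd.DataFrame:
    """Per-feature rank test of ``values`` (features x samples) against a
    grouping, with BH q-values across features.

    ``test`` is ``wilcoxon`` (2 groups), ``kruskal`` (>= 2 groups) or
    ``auto`` (wilcoxon iff exactly 2 groups).
    """
    groups = groups.loc[values.columns]
    levels = sorted(groups.unique())
    if test == "auto":
        test = "wilcoxon" if len(levels) == 2 else "kruskal"
    rows = []
    for feat in values.index:
        parts = [values.loc[feat, groups == g].values for g in levels]
        if test == "wilcoxon":
            if len(levels) != 2:
                raise ValidationError("wilcoxon requires exactly 2 groups")
            r = wilcoxon_rank_sum(parts[0], parts[1])
        else:
            r = kruskal_wallis(parts)
        rows.append((feat, r.statistic, r.pvalue, r.method))
    out = pd.DataFrame(rows, columns=["feature", "statistic", "pvalue",
                                      "method"]).set_index("feature")
    out["qvalue"] = benjamini_hochberg(out["pvalue"].values)
    return out
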