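"""ROC/AUC group comparison and nonparametric cohort statistics.

Orientation is fixed package-wide: the Parkinson's-disease (PD) group is the
positive class, so AUC > 0.5 means the per-subject score tends to be larger in
PD than in essential tremor (ET); on rendered diagrams red ⇔ AUC → 1 ⇔
"typical for PD".  Raw p-values are reported throughout — no multiple-testing
correction is applied anywhere (diagram cells are exploratory, not
confirmatory tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

__all__ = ["CohortSample", "roc_auc", "mann_whitney_test", "correlation"]

#: Combined sample size up to which the exact Mann-Whitney null distribution
#: is used (tie-free samples); above it, the normal approximation with tie
#: correction.
EXACT_MW_MAX_N = 20


@dataclass
class CohortSample:
    """One scalar score per subject with its group label (PD = positive)."""

    values: np.ndarray
    group: str
    subject_ids: list | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("cohort scores must be finite")


def _as_group(x) -> np.ndarray:
    arr = np.asarray(x.values if isinstance(x, CohortSample) else x, dtype=float)
    if arr.size == 0:
        raise ValueError("group must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError("group values must be finite")
    return arr


def roc_auc(pos, neg) -> float:
    """Area under the ROC curve for positive-vs-negative scalar scores.

    Equals the Mann-Whitney probability [#(p > n) + 0.5 #(p = n)] / (|pos||neg|),
    computed via midranks.
    """
    pos = _as_group(pos)
    neg = _as_group(neg)
    combined = np.concatenate([pos, neg])
    ranks = sstats.rankdata(combined)
    u = np.sum(ranks[: pos.size]) - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def mann_whitney_test(a, b, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U test of the two samples.

    The exact null distribution is used for tie-free samples with combined
    n <= 20; otherwise the normal approximation with tie and continuity
    correction.  Returns (U statistic of ``a``, p-value).
    """
    a = _as_group(a)
    b = _as_group(b)
    combined = np.concatenate([a, b])
    tie_free = np.unique(combined).size == combined.size
    method = "exact" if (tie_free and combined.size <= EXACT_MW_MAX_N) else "asymptotic"
    res = sstats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def correlation(x, y, method: str = "spearman") -> tuple[float, float]:
    """Spearman or Pearson correlation with its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("correlation requires at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input vector")
    if method == "spearman":
        res = sstats.spearmanr(x, y)
    elif method == "pearson":
        res = sstats.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)
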