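"""Nonparametric comparison of standardization methods.

The SD NMI_c values form a complete two-way layout: the 12 evaluated ROIs
are blocks, the standardization methods (including the unstandardized
Original) are within-block treatments. Because SD NMI_c is typically
non-normal (checked with the Shapiro-Wilk test), the omnibus comparison is
the Friedman rank test,

    Q = 12 n / (k (k + 1)) * sum_j (Rbar_j - (k + 1) / 2)^2,

with n blocks, k treatments and Rbar_j the mean within-block rank of
treatment j (ties get average ranks; no additional tie-correction term is
applied). Q is referred to the chi-square distribution with k - 1 degrees
of freedom. If the omnibus test is significant, all k(k-1)/2 method pairs
are compared with two-sided Wilcoxon signed-rank tests (exact null for
small n after zero-difference removal, normal approximation with continuity
correction otherwise), Bonferroni-corrected by the number of pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .consistency import SDNMIcTable
from .errors import (
    DegenerateSampleError,
    IncompleteBlockError,
    SampleSizeError,
)

__all__ = [
    "test_normality",
    "friedman_compare",
    "pairwise_wilcoxon",
    "wilcoxon_pair",
    "ComparisonMatrix",
]

#: Largest sample size for which the exact signed-rank null is used.
EXACT_WILCOXON_MAX_N = 25


def test_normality(values) -> float:
    """Two-sided Shapiro-Wilk p-value for a sample of 3..5000 scalars."""
    arr = np.asarray(values, dtype=float).ravel()
    if not 3 <= arr.size <= 5000:
        raise SampleSizeError(
            f"Shapiro-Wilk requires 3 <= n <= 5000, got n = {arr.size}"
        )
    if np.ptp(arr) == 0:
        raise DegenerateSampleError("all sample values are identical")
    return float(sps.shapiro(arr).pvalue)


def _as_block_frame(table) -> pd.DataFrame:
    """Rows = blocks (ROIs), columns = treatments (methods)."""
    if isinstance(table, SDNMIcTable):
        frame = table.values.T
    else:
        frame = pd.DataFrame(table)
    if frame.isna().any().any():
        raise IncompleteBlockError("every block needs a value for every method")
    if frame.shape[0] < 2 or frame.shape[1] < 2:
        raise IncompleteBlockError("need >= 2 blocks and >= 2 methods")
    return frame


def friedman_compare(table) -> tuple[float, float]:
    """Friedman omnibus test over methods, ROIs as blocks.

    Accepts an :class:`SDNMIcTable` or any blocks-by-methods table. Returns
    (Q, p) with p from chi-square(k - 1). Average ranks for ties; no tie
    correction beyond that.
    """
    frame = _as_block_frame(table)
    n, k = frame.shape
    ranks = sps.rankdata(frame.to_numpy(), axis=1)
    rbar = ranks.mean(axis=0)
    q = 12.0 * n / (k * (k + 1)) * float(np.sum((rbar - (k + 1) / 2.0) ** 2))
    p = float(sps.chi2.sf(q, k - 1))
    return q, p


def wilcoxon_pair(
    a, b, *, zero_method: str = "wilcox"
) -> float:
    """Two-sided Wilcoxon signed-rank p-value for one paired comparison.

    Zero differences are dropped before ranking (``zero_method="wilcox"``;
    ``"pratt"`` keeps them in the ranking). The exact null distribution is
    used for n <= 25 non-zero differences, the normal approximation with
    continuity correction above.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = a - b
    n_nonzero = int(np.count_nonzero(d))
    if n_nonzero == 0:
        warnings.warn(
            "all paired differences are zero; reporting p = 1", stacklevel=2
        )
        return 1.0
    method = "exact" if n_nonzero <= EXACT_WILCOXON_MAX_N else "approx"
    try:
        res = sps.wilcoxon(
            a, b, zero_method=zero_method, correction=True,
            alternative="two-sided", method=method,
        )
    except ValueError:
        res = sps.wilcoxon(
            a, b, zero_method=zero_method, correction=True,
            alternative="two-sided", method="approx",
        )
    return float(res.pvalue)


@dataclass
class ComparisonMatrix:
    """Pairwise method comparison with Bonferroni-corrected p-values."""

    methods: list[str]
    friedman_statistic: float
    friedman_p: float
    alpha: float = 0.05
    computed: bool = True
    raw_p: pd.DataFrame | None = None
    corrected_p: pd.DataFrame | None = None
    m: int = field(init=False)

    def __post_init__(self) -> None:
        k = len(self.methods)
        self.m = k * (k - 1) // 2

    def to_long(self) -> pd.DataFrame:
        """Long form: method_a, method_b, raw_p, corrected_p, significant."""
        rows = []
        for i, a in enumerate(self.methods):
            for b in self.methods[i + 1 :]:
                raw = (
                    float(self.raw_p.loc[a, b]) if self.computed else float("nan")
                )
                corr = (
                    float(self.corrected_p.loc[a, b])
                    if self.computed
                    else float("nan")
                )
                rows.append(
                    {
                        "method_a": a,
                        "method_b": b,
                        "raw_p": raw,
                        "corrected_p": corr,
                        "significant": bool(self.computed and corr < self.alpha),
                    }
                )
        return pd.DataFrame(rows)


def pairwise_wilcoxon(
    table,
    alpha: float = 0.05,
    *,
    zero_method: str = "wilcox",
    force: bool = False,
) -> ComparisonMatrix:
    """Bonferroni-corrected pairwise signed-rank matrix, Friedman-gated.

    The pairwise matrix is computed only when the Friedman omnibus p-value
    is below ``alpha`` (override with ``force=True``); otherwise the matrix
    is returned with ``computed=False`` and no p-values. The correction is
    corrected_p = min(1, p * m) with m = k(k-1)/2 pairs.
    """
    frame = _as_block_frame(table)
    q, p = friedman_compare(frame)
    methods = list(frame.columns)
    cm = ComparisonMatrix(
        methods=methods, friedman_statistic=q, friedman_p=p, alpha=alpha
    )
    if p >= alpha and not force:
        cm.computed = False
        return cm

    k = len(methods)
    raw = pd.DataFrame(np.nan, index=methods, columns=methods)
    corr = pd.DataFrame(np.nan, index=methods, columns=methods)
    m = k * (k - 1) // 2
    for i, a in enumerate(methods):
        for b in methods[i + 1 :]:
            pval = wilcoxon_pair(frame[a], frame[b], zero_method=zero_method)
            raw.loc[a, b] = raw.loc[b, a] = pval
            corr.loc[a, b] = corr.loc[b, a] = min(1.0, pval * m)
    cm.raw_p = raw
    cm.corrected_p = corr
    return cm
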