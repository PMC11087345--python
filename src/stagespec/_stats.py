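"""Shared two-group testing with a normality gate.

The convention used throughout: Shapiro-Wilk at 0.05 in each group; if both
groups are compatible with normality, a two-sided Student's t-test (pooled
variance); otherwise a two-sided Wilcoxon rank-sum (Mann-Whitney U, exact
when sample sizes allow and there are no ties). Groups too small for the
normality test (n < 3) or with constant values fall through to the rank test.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["two_group_test"]


def _normalish(x: np.ndarray, alpha: float) -> bool:
    if len(x) < 3 or np.ptp(x) == 0:
        return False
    return stats.shapiro(x).pvalue >= alpha


def two_group_test(x, y, gate_alpha: float = 0.05) -> tuple[float, str]:
    """Two-sided p-value for a difference between two independent samples.

    Returns ``(p, test_name)`` with ``test_name`` in ``{"t", "wilcoxon"}``.
    If both groups are constant and equal the difference is vacuous: p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("two_group_test needs >= 2 samples per group")
    if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
        return 1.0, "wilcoxon"
    if _normalish(x, gate_alpha) and _normalish(y, gate_alpha):
        p = float(stats.ttest_ind(x, y, equal_var=True).pvalue)
        return p, "t"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.pvalue), "wilcoxon"
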