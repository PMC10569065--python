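"""Geometric fold-change of replicate efficiencies with logarithmic
standard error, plus a Welch t-test on the log10 values.

The point estimate is the ratio of geometric means,
ratio = 10^(mean(log10 a) - mean(log10 b)); its log10-scale standard
error combines the per-group sample SDs as sqrt(s_a^2/n_a + s_b^2/n_b)
and the reported interval is the geometric +-1 SE band
ratio * 10^(+-SE).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["ReplicateSet", "FoldChangeEstimate", "log_fold_change"]


@dataclass(frozen=True)
class ReplicateSet:
    """Positive replicate efficiency values (e.g. spores/total)."""

    values: tuple

    def __init__(self, values: Sequence[float]):
        v = tuple(float(x) for x in values)
        if len(v) < 2:
            raise ValueError("need at least 2 replicates")
        if any(x <= 0 for x in v):
            raise ValueError("all efficiency values must be > 0")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.values)

    def log10(self) -> np.ndarray:
        return np.log10(np.asarray(self.values))


@dataclass(frozen=True)
class FoldChangeEstimate:
    ratio: float
    se_log10: float
    ci_low: float  # ratio / 10^se_log10
    ci_high: float  # ratio * 10^se_log10
    t_stat: float
    p_value: float
    n1: int
    n2: int


def log_fold_change(a: ReplicateSet | Sequence[float], b: ReplicateSet | Sequence[float]) -> FoldChangeEstimate:
    """Geometric-mean ratio a/b with logarithmic standard error and a
    Welch (unequal-variance) two-sided t-test on the log10 replicates."""
    if not isinstance(a, ReplicateSet):
        a = ReplicateSet(a)
    if not isinstance(b, ReplicateSet):
        b = ReplicateSet(b)
    la, lb = a.log10(), b.log10()
    ratio = float(10.0 ** (la.mean() - lb.mean()))
    se = float(np.sqrt(la.var(ddof=1) / a.n + lb.var(ddof=1) / b.n))
    if se == 0.0:
        # zero variance in both groups: the t statistic is 0 when the
        # means agree and diverges otherwise
        diff = la.mean() - lb.mean()
        t_stat = 0.0 if diff == 0 else float(np.sign(diff)) * float("inf")
        p_value = 1.0 if diff == 0 else 0.0
    else:
        t_stat, p_value = stats.ttest_ind(la, lb, equal_var=False)
    return FoldChangeEstimate(
        ratio=ratio,
        se_log10=se,
        ci_low=float(ratio / 10.0 ** se),
        ci_high=float(ratio * 10.0 ** se),
        t_stat=float(t_stat),
        p_value=float(p_value),
        n1=a.n,
        n2=b.n,
    )
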