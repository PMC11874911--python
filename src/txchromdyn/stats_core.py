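"""Shared statistical machinery: t-tests, Wilcoxon tests, seeded permutation
engine, and a type-I calibration harness.

Classical tests delegate to scipy.stats; this module pins down the policies
the pipeline needs on top of them — two-sidedness, exact small-sample
Wilcoxon, degenerate-input handling (all-zero paired differences give p = 1
with a flag; zero-variance nonzero shifts give the smallest positive p), and
a permutation engine with the add-one rule so p-values are never 0 and are
fully reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import stats

#: smallest reportable p for degenerate zero-variance shifts
MIN_P = float(np.nextafter(0.0, 1.0))


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_a: int
    n_b: int
    seed: Optional[int] = None
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "method": self.method,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "seed": self.seed,
            "degenerate": self.degenerate,
        }


def welch_t(a, b) -> TestResult:
    """Two-sided Welch (unequal-variance) t-test."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("welch_t needs >= 3 values per group")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    if np.isnan(t):  # both groups constant
        return TestResult(0.0, 1.0, "welch_t", len(a), len(b), degenerate=True)
    return TestResult(float(t), float(p), "welch_t", len(a), len(b))


def paired_t(a, b) -> TestResult:
    """Two-sided paired t-test on matched samples."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("paired_t needs >= 2 matched pairs")
    d = a - b
    if np.all(d == 0):
        return TestResult(0.0, 1.0, "paired_t", len(a), len(b), degenerate=True)
    if np.std(d) == 0:
        # constant nonzero shift: difference is certain, p underflows
        stat = np.inf if d[0] > 0 else -np.inf
        return TestResult(stat, MIN_P, "paired_t", len(a), len(b), degenerate=True)
    t, p = stats.ttest_rel(a, b)
    return TestResult(float(t), float(p), "paired_t", len(a), len(b))


def wilcoxon_rank(a, b, paired: bool = False) -> TestResult:
    """Two-sided Wilcoxon signed-rank (paired) or rank-sum (unpaired).

    Exact null distribution for n <= 25, normal approximation with
    continuity correction otherwise.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if paired:
        if a.shape != b.shape or len(a) < 2:
            raise ValueError("paired test needs matched samples")
        d = a - b
        if np.all(d == 0):
            return TestResult(0.0, 1.0, "wilcoxon_signed_rank", len(a), len(b),
                              degenerate=True)
        method = "exact" if (len(d) <= 25 and np.all(d != 0)) else "approx"
        res = stats.wilcoxon(a, b, correction=True, method=method,
                             zero_method="wilcox")
        return TestResult(float(res.statistic), float(res.pvalue),
                          "wilcoxon_signed_rank", len(a), len(b))
    if len(a) < 3 or len(b) < 3:
        raise ValueError("rank-sum test needs >= 3 values per group")
    method = "exact" if max(len(a), len(b)) <= 25 else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(res.pvalue),
                      "wilcoxon_rank_sum", len(a), len(b))


def t_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Welch t statistic (no p-value) — default permutation statistic."""
    va = a.var(ddof=1) / len(a)
    vb = b.var(ddof=1) / len(b)
    denom = np.sqrt(va + vb)
    if denom == 0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


def pearson_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r between values and group membership (point-biserial)."""
    x = np.concatenate([a, b])
    g = np.concatenate([np.zeros(len(a)), np.ones(len(b))])
    if x.std() == 0:
        return 0.0
    return float(np.corrcoef(x, g)[0, 1])


def permutation_engine(
    a,
    b,
    statistic_fn: Callable[[np.ndarray, np.ndarray], float] = t_statistic,
    n_perm: int = 1000,
    seed: Optional[int] = None,
) -> TestResult:
    """Two-sided label-permutation test of group difference.

    p = (1 + #{|s_perm| >= |s_obs|}) / (n_perm + 1); never exactly 0.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, "permutation", len(a), len(b), seed=seed,
                          degenerate=True)
    rng = np.random.default_rng(seed)
    s_obs = statistic_fn(a, b)
    na = len(a)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(statistic_fn(perm[:na], perm[na:])) >= abs(s_obs):
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return TestResult(s_obs, p, "permutation", len(a), len(b), seed=seed)


def type_i_error_rate(
    test_fn: Callable[[np.ndarray, np.ndarray], TestResult],
    null_generator: Callable[[np.random.Generator], tuple],
    n_replicates: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of null replicates a test rejects at level alpha.

    Calibration harness shared by the permutation-based procedures: a
    well-calibrated two-sided test should land near alpha.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        a, b = null_generator(rng)
        if test_fn(a, b).p_value <= alpha:
            rejections += 1
    return rejections / n_replicates
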