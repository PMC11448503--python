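"""Shared statistical primitives.

Each function returns a :class:`TestResult` whose ``method`` field names the
exact variant used, so downstream tables record how every p-value was
obtained.  The implementations delegate to scipy/statsmodels where those
match the stated contracts; the test suite checks them against independent
enumeration oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats as ss
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with mid-ranks for ties.

    rho is the Pearson correlation of mid-ranks; the p-value uses the
    t-approximation with n − 2 degrees of freedom (two-sided), clamped at
    |rho| = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("undefined correlation: constant vector")
    rho, p = ss.spearmanr(x, y)
    return TestResult(float(rho), float(min(p, 1.0)), "spearman-t", (n,))


def bh_fdr(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_upper(k: int, K: int, n: int, N: int) -> TestResult:
    """One-tailed (upper) hypergeometric enrichment p-value, P(X >= k).

    X counts successes in a size-``n`` draw without replacement from a
    population of ``N`` containing ``K`` successes.
    """
    if not (0 <= K <= N):
        raise ValueError(f"require 0 <= K <= N, got K={K}, N={N}")
    if not (0 <= n <= N):
        raise ValueError(f"require 0 <= n <= N, got n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"require 0 <= k <= min(K, n), got k={k}, K={K}, n={n}")
    # sf(k-1) = P(X >= k); scipy computes in log space internally
    p = float(ss.hypergeom.sf(k - 1, N, K, n))
    return TestResult(float(k), min(max(p, 0.0), 1.0), "hypergeom-upper", (N, K, n))


def mann_whitney(x, y, alternative: str = "two-sided") -> TestResult:
    """Mann–Whitney U test; statistic is U of the first sample.

    Uses the exact permutation distribution when there are no ties and both
    samples have at most 10 observations; otherwise the normal approximation
    with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (not has_ties) and max(x.size, y.size) <= 10
    method = "exact" if exact else "asymptotic"
    res = ss.mannwhitneyu(x, y, alternative=alternative, method=method)
    label = "MW-exact" if exact else "MW-normal-tie-corrected"
    return TestResult(float(res.statistic), float(res.pvalue), label, (x.size, y.size))


def ks_two_sample(x, y) -> TestResult:
    """Two-sample Kolmogorov–Smirnov test, asymptotic p-value.

    D is the supremum over the pooled sample points of the ECDF difference;
    the p-value comes from the Kolmogorov distribution at effective size
    n·m/(n+m).
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per sample")
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / x.size
    cdf_y = np.searchsorted(y, pooled, side="right") / y.size
    d = float(np.max(np.abs(cdf_x - cdf_y)))
    n_eff = x.size * y.size / (x.size + y.size)
    p = float(ss.kstwobign.sf(d * np.sqrt(n_eff)))
    return TestResult(d, min(max(p, 0.0), 1.0), "KS-asymptotic", (x.size, y.size))
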