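"""Chi-square tail probabilities and multiple-testing thresholds.

Every test in the package (the 8-df pairwise interaction test, the 2-df
univariate test, the 1-df Hardy-Weinberg goodness-of-fit) reduces to an
upper-tail chi-square probability, computed here through the regularized
upper incomplete gamma function Q(df/2, x/2).  Tail values are evaluated
by :func:`scipy.special.gammaincc`, which keeps full relative accuracy far
below p = 1e-300; probabilities smaller than the double-precision floor
underflow to 0.0, and callers that need a total ordering among such
extremes rank by the statistic instead (the ordering is identical for a
fixed df).  :func:`chi2_logsf` exposes the log-scale tail for reporting.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import special
from scipy import stats as _scipy_stats

__all__ = ["TestResult", "chi2_sf", "chi2_logsf", "bonferroni_threshold"]


class TestResult(NamedTuple):
    """Outcome of a single chi-square test."""

    statistic: float
    df: int
    p_value: float


def _validate(x, df: int) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0) or np.any(~np.isfinite(arr)):
        raise ValueError("chi-square statistic must be finite and non-negative")
    if int(df) != df or df < 1:
        raise ValueError(f"degrees of freedom must be a positive integer, got {df!r}")
    return arr


def chi2_sf(x, df: int):
    """Upper-tail probability P(X >= x) for X ~ chi-square(df).

    Accepts a scalar or an ndarray of statistics.  ``chi2_sf(0, df) == 1``
    and the function is strictly decreasing in ``x``.  For df = 2 it equals
    exp(-x/2) exactly.
    """
    arr = _validate(x, df)
    p = special.gammaincc(df / 2.0, arr / 2.0)
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(p)
    return p


def _logsf_asymptotic(z: np.ndarray, a: float) -> np.ndarray:
    # log Q(a, z) for z >> a via the divergent asymptotic series
    # Q(a, z) ~ z^(a-1) e^(-z) / Gamma(a) * sum_k prod_{j<=k}(a-j) / z^k,
    # truncated at the smallest term; accurate to ~1e-12 once z > a + 50
    s = np.ones_like(z)
    term = np.ones_like(z)
    for k in range(1, 30):
        factor = a - k
        if factor == 0:
            break
        term = term * factor / z
        s = s + term
    return -z + (a - 1) * np.log(z) - special.gammaln(a) + np.log(s)


def chi2_logsf(x, df: int):
    """Natural log of the chi-square upper-tail probability.

    Stays finite where the tail underflows double precision (statistics
    above roughly 1400 at 8 df), switching to an asymptotic expansion of
    the upper incomplete gamma function in the deep tail.
    """
    arr = _validate(x, df)
    logp = _scipy_stats.chi2.logsf(arr, df)
    a = df / 2.0
    z = arr / 2.0
    deep = (~np.isfinite(logp)) & (z > a + 50)
    if np.any(deep):
        logp = np.where(deep, _logsf_asymptotic(np.maximum(z, a + 50), a), logp)
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(logp)
    return logp


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests.

    ``n_tests`` is the number of tests actually performed — for the pair
    scan, the number of pairs surviving the LD-width exclusion.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha!r}")
    if int(n_tests) != n_tests or n_tests < 1:
        raise ValueError(f"n_tests must be a positive integer, got {n_tests!r}")
    return alpha / n_tests
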