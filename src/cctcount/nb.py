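"""Negative binomial marginals, quantile transform, and Z-tests.

The negative binomial here follows the failures convention: X is the
number of failures before the r-th success with per-trial success
probability p, pmf C(x+r-1, r-1) p^r (1-p)^x, mean r(1-p)/p and variance
r(1-p)/p² (overdispersed: variance > mean).  Copula uniforms are pushed
through the left-continuous quantile function to obtain correlated
counts; per-variable hypotheses on the mean are tested with the normal
approximation to the distribution of the sample mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "NegBinParams",
    "ZTestResult",
    "nb_pmf",
    "nb_moments",
    "nb_quantile",
    "nb_cdf_table",
    "counts_from_copula",
    "z_test",
    "standardized_skewness",
]


@dataclass(frozen=True)
class NegBinParams:
    """Success parameter r > 0 (possibly non-integer) and success
    probability p in (0, 1)."""

    r: float
    p: float

    def __post_init__(self):
        if not self.r > 0.0:
            raise ValueError(f"r must be positive, got {self.r}")
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"p must lie in (0, 1), got {self.p}")

    @property
    def mean(self) -> float:
        return self.r * (1.0 - self.p) / self.p

    @property
    def variance(self) -> float:
        return self.r * (1.0 - self.p) / self.p**2

    def frozen(self):
        """The scipy frozen distribution (scipy's n, p match this convention)."""
        return stats.nbinom(self.r, self.p)


def nb_pmf(params: NegBinParams, x) -> np.ndarray | float:
    """P(X = x), evaluated in log space via the gamma function."""
    x_arr = np.asarray(x)
    if np.any(x_arr < 0) or not np.issubdtype(x_arr.dtype, np.integer) and np.any(
        x_arr != np.floor(x_arr)
    ):
        raise ValueError("x must be a non-negative integer")
    out = np.exp(stats.nbinom.logpmf(x_arr, params.r, params.p))
    return float(out) if np.isscalar(x) else out


def nb_moments(params: NegBinParams) -> tuple[float, float]:
    """(mean, variance) = (r(1-p)/p, r(1-p)/p²)."""
    return params.mean, params.variance


def nb_quantile(params: NegBinParams, u) -> np.ndarray | int:
    """Smallest integer x with CDF(x) >= u (left-continuous inverse)."""
    u_arr = np.asarray(u, dtype=float)
    if np.any(u_arr <= 0.0) or np.any(u_arr >= 1.0):
        raise ValueError("u must lie strictly inside (0, 1)")
    out = stats.nbinom.ppf(u_arr, params.r, params.p).astype(np.int64)
    return int(out) if np.isscalar(u) else out


def nb_cdf_table(params: NegBinParams, tail: float = 1e-13) -> np.ndarray:
    """CDF values on 0..x_max where x_max covers all u below 1 - tail.

    ``np.searchsorted(table, u, side='left')`` then equals the quantile
    function on that range; used to vectorize the copula-to-count
    transform inside Monte-Carlo loops.
    """
    xmax = int(stats.nbinom.ppf(1.0 - tail, params.r, params.p)) + 1
    return stats.nbinom.cdf(np.arange(xmax + 1), params.r, params.p)


def counts_from_copula(
    sample: np.ndarray, params_per_column: Sequence[NegBinParams]
) -> np.ndarray:
    """Transform copula uniforms columnwise into negative binomial counts.

    A monotone transform of each column, so within-column ordering (and
    hence concordance, up to ties) is preserved.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.ndim != 2:
        raise ValueError("sample must be a 2-d array (observations x variables)")
    if sample.shape[1] != len(params_per_column):
        raise ValueError(
            f"sample has {sample.shape[1]} columns but "
            f"{len(params_per_column)} parameter sets were given"
        )
    counts = np.empty(sample.shape, dtype=np.int64)
    for j, params in enumerate(params_per_column):
        table = nb_cdf_table(params)
        col = np.searchsorted(table, sample[:, j], side="left")
        # uniforms beyond the table's coverage fall back to the exact ppf
        over = col >= table.size
        if np.any(over):
            col[over] = stats.nbinom.ppf(
                sample[over, j], params.r, params.p
            ).astype(np.int64)
        counts[:, j] = col
    return counts


@dataclass(frozen=True)
class ZTestResult:
    """Per-variable sample means, Z statistics, and two-sided p-values."""

    sample_mean: np.ndarray
    z: np.ndarray
    p_value: np.ndarray


def z_test(
    counts: np.ndarray, null_mean, null_variance, n: int | None = None
) -> ZTestResult:
    """Two-sided Z-test of H0: mu = null_mean per column.

    Z = (x̄ - mu0) / sqrt(V0 / n) with the theoretical null variance V0;
    p = 2[1 - Φ(|Z|)].  ``counts`` may be a single column (1-d) or an
    (n x m) matrix.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    if counts.shape[0] == 1 and counts.shape[1] > 1 and np.ndim(null_mean) == 0:
        counts = counts.T  # a 1-d input is one column of observations
    n_obs = counts.shape[0] if n is None else int(n)
    if n_obs < 1:
        raise ValueError("sample size n must be at least 1")
    null_variance = np.asarray(null_variance, dtype=float)
    if np.any(null_variance <= 0.0):
        raise ValueError("null variance must be positive")
    xbar = counts.mean(axis=0)
    z = (xbar - np.asarray(null_mean, dtype=float)) / np.sqrt(null_variance / n_obs)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return ZTestResult(xbar, z, p)


def standardized_skewness(params: NegBinParams, n: int) -> float:
    """Skewness of the sample mean, γ/√n with γ = (2-p)/√((1-p) r).

    The diagnostic for the normal approximation: the Cauchy combination
    test holds its size once this is close to zero (roughly <= 0.05 at
    m = 30 combined tests).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    gamma = (2.0 - params.p) / np.sqrt((1.0 - params.p) * params.r)
    return float(gamma / np.sqrt(n))
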