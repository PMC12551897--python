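"""Global-null p-value combination tests.

Implements three classical ways of collapsing m per-hypothesis p-values
into a single p-value for the global null (all m individual nulls true):

* the Cauchy combination test (CCT), a weighted sum of tan{(0.5 - p_i)π}
  transforms whose null tail is approximately standard Cauchy and which is
  robust to dependence among the p_i;
* Fisher's method, -2 Σ log p_i referred to a chi-square with 2m degrees
  of freedom (valid under independence);
* the MinP test, the smallest p-value referred to its Beta(1, m) null law
  under independence, p = 1 - (1 - p_(1))^m.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "EPS",
    "CCT_TAIL_CROSSOVER",
    "PValueVector",
    "CombinationResult",
    "cct_combine",
    "fisher_combine",
    "minp_combine",
    "combine_all",
]

#: p-values are clipped to [EPS, 1 - EPS] before the tangent/log transforms,
#: so p = 0 or p = 1 never produces ±inf while the ordering is preserved.
EPS = 1e-15

#: Above this CCT statistic magnitude the arctan form of the Cauchy tail
#: loses precision; switch to the 1/(π ψ) tail expansion.
CCT_TAIL_CROSSOVER = 1e8


@dataclass(frozen=True)
class PValueVector:
    """The m individual p-values (and optional weights) entering a test.

    Parameters
    ----------
    values
        Probabilities in [0, 1], length m >= 1.
    weights
        Non-negative reals, length m, not all zero.  Defaults to equal
        weights.  Weights are normalized to sum to one before use; only
        the CCT consumes them.
    """

    values: np.ndarray
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __init__(self, values: Sequence[float], weights: Sequence[float] | None = None):
        values = np.atleast_1d(np.asarray(values, dtype=float))
        if values.ndim != 1 or values.size == 0:
            raise ValueError("p-value vector must be one-dimensional and non-empty")
        if np.any(~np.isfinite(values)) or np.any(values < 0.0) or np.any(values > 1.0):
            raise ValueError("p-values must lie in [0, 1]")
        if weights is None:
            weights = np.full(values.size, 1.0 / values.size)
        else:
            weights = np.atleast_1d(np.asarray(weights, dtype=float))
            if weights.shape != values.shape:
                raise ValueError(
                    f"weights length {weights.size} does not match {values.size} p-values"
                )
            if np.any(~np.isfinite(weights)) or np.any(weights < 0.0):
                raise ValueError("weights must be finite and non-negative")
            total = weights.sum()
            if total <= 0.0:
                raise ValueError("weights must not all be zero")
            weights = weights / total
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "weights", weights)

    @property
    def m(self) -> int:
        return self.values.size

    def clipped(self) -> np.ndarray:
        """Values clipped to the open interval [EPS, 1 - EPS]."""
        return np.clip(self.values, EPS, 1.0 - EPS)


@dataclass(frozen=True)
class CombinationResult:
    """Outcome of one combination test.

    ``statistic`` is Ψ_CCT, Ψ_F = -2 Σ log p_i, or p_(1) depending on the
    method; ``combined_p`` is the global-null p-value.  ``weights_applied``
    records whether the supplied weights entered the statistic (Fisher and
    MinP are defined unweighted and ignore them).
    """

    method: str
    statistic: float
    combined_p: float
    m: int
    weights_applied: bool = False

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "m": self.m,
            "statistic": self.statistic,
            "combined_p": self.combined_p,
            "weights_applied": self.weights_applied,
        }


def _cauchy_upper_tail(psi: float) -> float:
    """P(C > psi) for a standard Cauchy C, stable in both tails.

    The direct 0.5 - arctan(psi)/π form cancels catastrophically once
    |psi| is large; beyond ``CCT_TAIL_CROSSOVER`` the expansion
    1/(π psi) (and 1 - 1/(π |psi|) on the left) is exact to well below
    double-precision rounding.
    """
    if psi > CCT_TAIL_CROSSOVER:
        return 1.0 / (np.pi * psi)
    if psi < -CCT_TAIL_CROSSOVER:
        return 1.0 - 1.0 / (np.pi * (-psi))
    return 0.5 - np.arctan(psi) / np.pi


def cct_combine(pv: PValueVector) -> CombinationResult:
    """Cauchy combination test.

    Ψ = Σ ω_i tan{(0.5 - p_i)π} with weights normalized to sum to one;
    the combined p-value is the standard Cauchy upper tail at Ψ.
    """
    p = pv.clipped()
    psi = float(np.dot(pv.weights, np.tan((0.5 - p) * np.pi)))
    combined = _cauchy_upper_tail(psi)
    combined = min(max(combined, EPS), 1.0 - EPS)
    return CombinationResult("cct", psi, combined, pv.m, weights_applied=True)


def fisher_combine(pv: PValueVector) -> CombinationResult:
    """Fisher's combination test: -2 Σ log p_i ~ χ²(2m) under the null."""
    p = pv.clipped()
    stat = float(-2.0 * np.log(p).sum())
    combined = float(stats.chi2.sf(stat, 2 * pv.m))
    combined = min(max(combined, EPS), 1.0 - EPS)
    return CombinationResult("fisher", stat, combined, pv.m)


def minp_combine(pv: PValueVector) -> CombinationResult:
    """MinP test: p_(1) with Beta(1, m) null, p = 1 - (1 - p_(1))^m."""
    pmin = float(pv.clipped().min())
    # -expm1(m log1p(-p)) evaluates 1-(1-p)^m without cancellation for tiny p
    combined = float(-np.expm1(pv.m * np.log1p(-pmin)))
    combined = min(max(combined, EPS), 1.0 - EPS)
    return CombinationResult("minp", pmin, combined, pv.m)


_METHODS = {"cct": cct_combine, "fisher": fisher_combine, "minp": minp_combine}


def combine_all(pv: PValueVector, methods: Sequence[str] = ("cct", "fisher", "minp")):
    """Run several combination tests on the same vector."""
    try:
        return [_METHODS[name](pv) for name in methods]
    except KeyError as err:
        raise ValueError(f"unknown combination method {err.args[0]!r}") from None
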