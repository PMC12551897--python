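"""Sampling from exchangeable Archimedean copulas.

Draws m-dimensional dependent uniforms from the independence, Clayton,
Gumbel-Hougaard, and survival Clayton copulas via the Marshall-Olkin
frailty construction, and converts between the dependence parameter θ and
Kendall's τ.  Clayton concentrates dependence in the lower tail, the
Gumbel-Hougaard copula in the upper tail, and the survival Clayton (the
copula of 1 - U for Clayton U) mirrors Clayton's dependence into the
upper tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .combine import EPS

__all__ = [
    "FAMILIES",
    "CopulaSpec",
    "sample_copula",
    "theta_to_tau",
    "tau_to_theta",
    "empirical_kendall_tau",
]

FAMILIES = ("independence", "clayton", "gumbel", "survival_clayton")


def _validate_theta(family: str, theta: float) -> float:
    if family not in FAMILIES:
        raise ValueError(f"unknown copula family {family!r}; choose from {FAMILIES}")
    theta = float(theta)
    if family in ("clayton", "survival_clayton") and not theta > 0.0:
        raise ValueError(f"{family} copula requires theta > 0, got {theta}")
    if family == "gumbel" and not theta >= 1.0:
        raise ValueError(f"gumbel copula requires theta >= 1, got {theta}")
    return theta


@dataclass(frozen=True)
class CopulaSpec:
    """Family, dependence parameter θ, and dimension m of the joint law.

    Clayton and survival Clayton require θ > 0; Gumbel-Hougaard requires
    θ >= 1 (θ = 1 is exact independence).  The independence family ignores
    θ.
    """

    family: str
    theta: float = 0.0
    dim: int = 2

    def __post_init__(self):
        if self.family != "independence":
            _validate_theta(self.family, self.theta)
        if int(self.dim) < 1:
            raise ValueError(f"dimension must be a positive integer, got {self.dim}")
        object.__setattr__(self, "dim", int(self.dim))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _clayton(rng: np.random.Generator, n: int, m: int, theta: float) -> np.ndarray:
    # Marshall-Olkin: V ~ Gamma(1/theta, rate 1), U_i = (1 + E_i/V)^(-1/theta)
    v = rng.gamma(1.0 / theta, size=(n, 1))
    e = rng.exponential(size=(n, m))
    return (1.0 + e / v) ** (-1.0 / theta)


def _positive_stable(rng: np.random.Generator, alpha: float, size) -> np.ndarray:
    # Chambers-Mallows-Stuck for a positive alpha-stable frailty, 0 < alpha < 1
    w = rng.uniform(0.0, np.pi, size=size)
    e = rng.exponential(size=size)
    return (
        np.sin(alpha * w) / np.sin(w) ** (1.0 / alpha)
    ) * (np.sin((1.0 - alpha) * w) / e) ** ((1.0 - alpha) / alpha)


def _gumbel(rng: np.random.Generator, n: int, m: int, theta: float) -> np.ndarray:
    if theta == 1.0:
        # stable sampler is singular at alpha = 1; theta = 1 is independence
        return rng.uniform(size=(n, m))
    v = _positive_stable(rng, 1.0 / theta, size=(n, 1))
    e = rng.exponential(size=(n, m))
    return np.exp(-((e / v) ** (1.0 / theta)))


def sample_copula(spec: CopulaSpec, n: int, seed) -> np.ndarray:
    """Draw n observations from the m-dimensional copula.

    Parameters
    ----------
    spec
        Family, θ, and dimension.
    n
        Number of rows to draw.
    seed
        Integer seed, ``SeedSequence``, or an existing ``Generator``
        (consumed in place).  Identical (spec, n, seed) gives identical
        output; with a shared seed the survival Clayton sample equals
        1 - Clayton sample elementwise.

    Returns
    -------
    ndarray of shape (n, m) with entries strictly inside (0, 1) and
    Uniform(0, 1) margins.
    """
    if n < 1:
        raise ValueError(f"n must be a positive integer, got {n}")
    rng = _as_rng(seed)
    m = spec.dim
    if spec.family == "independence":
        u = rng.uniform(size=(n, m))
    elif spec.family == "clayton":
        u = _clayton(rng, n, m, spec.theta)
    elif spec.family == "survival_clayton":
        u = 1.0 - _clayton(rng, n, m, spec.theta)
    else:
        u = _gumbel(rng, n, m, spec.theta)
    # floating-point underflow can produce exact 0/1; keep the open interval
    return np.clip(u, EPS, 1.0 - EPS)


def theta_to_tau(family: str, theta: float) -> float:
    """Kendall's τ implied by θ: τ = θ/(θ+2) (Clayton), 1 - 1/θ (Gumbel)."""
    if family == "independence":
        return 0.0
    theta = _validate_theta(family, theta)
    if family in ("clayton", "survival_clayton"):
        return theta / (theta + 2.0)
    return 1.0 - 1.0 / theta


def tau_to_theta(family: str, tau: float) -> float:
    """θ achieving a given Kendall's τ (inverse of :func:`theta_to_tau`)."""
    if family not in FAMILIES:
        raise ValueError(f"unknown copula family {family!r}; choose from {FAMILIES}")
    tau = float(tau)
    if family == "independence":
        if tau != 0.0:
            raise ValueError("independence copula has tau = 0 only")
        return 0.0
    if family in ("clayton", "survival_clayton"):
        if not 0.0 < tau < 1.0:
            raise ValueError(f"{family} requires tau in (0, 1), got {tau}")
        return 2.0 * tau / (1.0 - tau)
    if not 0.0 <= tau < 1.0:
        raise ValueError(f"gumbel requires tau in [0, 1), got {tau}")
    return 1.0 / (1.0 - tau)


def empirical_kendall_tau(sample: np.ndarray, col_i: int = 0, col_j: int = 1) -> float:
    """Sample Kendall's τ between two columns (concordance minus discordance)."""
    sample = np.asarray(sample)
    if sample.shape[0] < 2:
        raise ValueError("need at least two observations")
    x, y = sample[:, col_i], sample[:, col_j]
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("Kendall's tau is undefined for a constant column")
    tau, _ = stats.kendalltau(x, y)
    return float(tau)
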