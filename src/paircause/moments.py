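"""Scalar building blocks for the pairwise causal-direction statistics.

Standardization, descriptive skewness/kurtosis, OLS residuals for a pair of
samples, and the maximum-entropy (nonpolynomial-moment) approximation of
differential entropy used by the entropy-based direction statistic.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StandardizedSample",
    "EntropyApproxConfig",
    "standardize",
    "sample_skew_kurt",
    "ols_residual",
    "entropy_approx",
]

#: differential entropy of a standard normal, (1 + log 2π)/2 nats
H_NU = 0.5 * (1.0 + np.log(2.0 * np.pi))


class DegenerateInputError(ValueError):
    """Raised when a sample is constant (zero variance) or too short."""


@dataclass(frozen=True)
class StandardizedSample:
    """A sample rescaled to mean 0, sample variance 1 (n−1 denominator)."""

    values: np.ndarray
    original_mean: float
    original_sd: float

    @property
    def n(self) -> int:
        return self.values.size

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


@dataclass(frozen=True)
class EntropyApproxConfig:
    """Constants of the maximum-entropy differential-entropy approximation.

    ``H_nu`` is the entropy of a standard normal; ``k1``/``k2`` weight the
    squared deviations of the two nonpolynomial moments E[log cosh u] and
    E[u exp(−u²/2)] from their Gaussian expectations; ``gamma`` is the
    Gaussian expectation of log cosh u.  Defaults are the constants of the
    pairwise maximum-likelihood-ratio literature.
    """

    H_nu: float = H_NU
    k1: float = 79.047
    k2: float = 7.4129
    gamma: float = 0.37457

    def __post_init__(self):
        if not (self.k1 > 0 and self.k2 > 0):
            raise ValueError("k1 and k2 must be positive")


def _as_1d(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    return arr


def standardize(x) -> StandardizedSample:
    """Center and scale ``x`` to mean 0 and unit sample variance.

    Raises
    ------
    DegenerateInputError
        if ``x`` has fewer than 3 values or zero variance.
    """
    arr = _as_1d(x)
    if arr.size < 3:
        raise DegenerateInputError(f"need at least 3 observations, got {arr.size}")
    mu = float(arr.mean())
    sd = float(arr.std(ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        raise DegenerateInputError("constant (zero-variance) sample")
    return StandardizedSample(values=(arr - mu) / sd, original_mean=mu, original_sd=sd)


def sample_skew_kurt(x, bias: bool = True) -> tuple[float, float]:
    """Sample skewness and kurtosis (Normal reference: skew 0, kurtosis 3).

    Moment (biased) estimators by default, matching descriptive-table
    practice; ``bias=False`` applies the usual small-sample corrections.
    """
    arr = _as_1d(x)
    n = arr.size
    if n < 4:
        raise DegenerateInputError(f"need at least 4 observations, got {n}")
    m = arr.mean()
    d = arr - m
    m2 = np.mean(d**2)
    if m2 == 0:
        raise DegenerateInputError("constant (zero-variance) sample")
    m3 = np.mean(d**3)
    m4 = np.mean(d**4)
    g1 = m3 / m2**1.5
    g2 = m4 / m2**2
    if bias:
        return float(g1), float(g2)
    G1 = g1 * np.sqrt(n * (n - 1)) / (n - 2)
    G2 = ((n + 1) * (g2 - 3.0) + 6.0) * (n - 1) / ((n - 2) * (n - 3)) + 3.0
    return float(G1), float(G2)


def ols_residual(y: StandardizedSample | np.ndarray, x: StandardizedSample | np.ndarray) -> np.ndarray:
    """Residual of ``y`` regressed on ``x`` with intercept.

    The returned vector is orthogonal to ``x`` and to the constant.
    """
    yv = np.asarray(y, dtype=float)
    xv = np.asarray(x, dtype=float)
    if yv.size != xv.size:
        raise ValueError(f"length mismatch: {yv.size} vs {xv.size}")
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    sxx = xc @ xc
    if sxx == 0:
        raise DegenerateInputError("regressor is constant")
    beta = (xc @ yc) / sxx
    return yc - beta * xc


def entropy_approx(u: StandardizedSample, cfg: EntropyApproxConfig | None = None,
                   tol: float = 1e-6) -> float:
    """Maximum-entropy approximation of differential entropy (nats).

    H̃(u) = H_ν − k1·(E[log cosh u] − γ)² − k2·(E[u·exp(−u²/2)])².

    Both correction terms vanish in expectation for a standard normal, so
    H̃ equals the Normal entropy there and is ≤ H_ν for every sample.  The
    input must already be standardized; entropy is not scale-invariant.
    """
    if cfg is None:
        cfg = EntropyApproxConfig()
    v = np.asarray(u, dtype=float)
    if abs(v.mean()) > tol or abs(v.std(ddof=1) - 1.0) > 100 * tol:
        raise ValueError("entropy_approx requires a standardized input "
                         f"(mean {v.mean():.2e}, sd {v.std(ddof=1):.6f})")
    t1 = np.mean(np.log(np.cosh(v))) - cfg.gamma
    t2 = np.mean(v * np.exp(-0.5 * v**2))
    return float(cfg.H_nu - cfg.k1 * t1**2 - cfg.k2 * t2**2)
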