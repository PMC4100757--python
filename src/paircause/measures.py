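"""Pairwise causal-direction statistics for linear non-Gaussian models.

In a pairwise LiNGAM (linear, non-Gaussian, acyclic) system one of two
standardized variables is exogenous: either x causes y (y = b·x + e) or y
causes x.  With non-Gaussian disturbances the direction is identifiable,
because only in the true direction is the regressor independent of the
regression residual.  Three statistics T(x, y) quantify this, all signed so
that a *positive* value indicates that the first argument is the causal
antecedent and a negative value the opposite:

``t_kernel``
    difference of kernel mutual informations between each variable and the
    opposite regression residual (the dependence measure the DirectLiNGAM
    algorithm uses);
``t_entropy``
    the maximum-entropy approximate likelihood-ratio contrast built from
    differential-entropy approximations of the variables and their
    standardized residuals;
``t_skew``
    the third-moment contrast r·(E[x²y] − E[xy²]) for positively skewed
    variables, which equals skew(x)·(r²−r³) > 0 under y = r·x + e and
    skew(y)·(r³−r²) < 0 under the reverse model.

Uncertainty is assessed with bootstrap-percentile confidence intervals.
Resamples are drawn from the full subject roster (rows with missing values
included) and incomplete pairs are dropped within each resample, so the
resampling distribution honours the observed missingness.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np

from .kernelmi import KernelMIConfig, default_kernel_config, kernel_mutual_information
from .moments import (DegenerateInputError, EntropyApproxConfig, entropy_approx,
                      ols_residual, sample_skew_kurt, standardize)

__all__ = ["CausalityResult", "t_kernel", "t_entropy", "t_skew", "bootstrap_ci"]

Direction = Literal["first_causes_second", "second_causes_first", "indecisive"]


@dataclass(frozen=True)
class CausalityResult:
    """Point estimate, bootstrap 95% percentile CI and direction call."""

    statistic_name: str
    value: float
    ci_low: float
    ci_high: float
    n_effective: int
    direction_call: Direction
    bootstrap_fraction_positive: float
    #: True when the percentile CI fails to bracket the point estimate
    #: (possible in pathological resampling situations; flagged, not fatal).
    ci_excludes_point: bool = False

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic_name,
            "value": self.value,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_effective": self.n_effective,
            "direction_call": self.direction_call,
            "bootstrap_fraction_positive": self.bootstrap_fraction_positive,
        }


def _standardized_pair(x, y):
    sx = standardize(x)
    sy = standardize(y)
    if sx.n != sy.n:
        raise ValueError(f"length mismatch: {sx.n} vs {sy.n}")
    return sx.values, sy.values


def t_kernel(x, y, cfg: KernelMIConfig | None = None) -> float:
    """Kernel-based direction statistic; positive ⇒ x causes y.

    T = M̂(y, resid of x on y) − M̂(x, resid of y on x): if x is exogenous
    its residual when regressed on y inherits dependence on y, while the
    residual of y on x is independent of x, so T > 0.  Exactly
    antisymmetric under argument swap.
    """
    xv, yv = _standardized_pair(x, y)
    if cfg is None:
        cfg = default_kernel_config(xv.size)
    r_x_on_y = ols_residual(xv, yv)
    r_y_on_x = ols_residual(yv, xv)
    return (kernel_mutual_information(yv, r_x_on_y, cfg)
            - kernel_mutual_information(xv, r_y_on_x, cfg))


def t_entropy(x, y, cfg: EntropyApproxConfig | None = None) -> float:
    """Entropy-approximation direction statistic; positive ⇒ x causes y.

    T = [H̃(y) + H̃(ê_{x|y})] − [H̃(x) + H̃(ê_{y|x})] with standardized
    residuals ê: the factorization along the true causal direction attains
    the smaller total (approximate) entropy, i.e. the larger likelihood.
    Exactly antisymmetric.
    """
    xv, yv = _standardized_pair(x, y)
    ex = standardize(ols_residual(xv, yv)).values
    ey = standardize(ols_residual(yv, xv)).values
    return (entropy_approx(standardize(yv).values, cfg)
            + entropy_approx(ex, cfg)
            - entropy_approx(standardize(xv).values, cfg)
            - entropy_approx(ey, cfg))


def t_skew(x, y, warn_zero_skew: float = 0.05) -> float:
    """Skewness-based direction statistic; positive ⇒ x causes y.

    Variables are standardized and each is sign-flipped to positive sample
    skewness (multiplying a variable by the sign of its skewness always
    yields positive skew, so this is not a restriction).  Then

        T = r·(mean[x²y] − mean[x·y²]),

    whose population value is skew(x)·(r²−r³) under y = r·x + e and
    skew(y)·(r³−r²) under x = r·y + e.  Uninformative for (near-)symmetric
    variables; such inputs are accepted but carry essentially no signal.
    """
    xv, yv = _standardized_pair(x, y)
    sk_x, _ = sample_skew_kurt(xv)
    sk_y, _ = sample_skew_kurt(yv)
    xv = xv if sk_x >= 0 else -xv
    yv = yv if sk_y >= 0 else -yv
    n = xv.size
    r = float(xv @ yv) / (n - 1)
    return float(r * (np.mean(xv**2 * yv) - np.mean(xv * yv**2)))


_STATS: dict[str, Callable] = {"kernel": t_kernel, "entropy": t_entropy, "skew": t_skew}


def _pairwise_complete(x, y):
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def bootstrap_ci(x, y, statistic: str = "kernel", B: int = 2000,
                 seed: int | np.random.SeedSequence | None = None,
                 alpha: float = 0.05, stat_kwargs: dict | None = None,
                 min_complete: int = 20) -> CausalityResult:
    """Bootstrap-percentile CI for a pairwise direction statistic.

    Subject rows are resampled with replacement from the full roster —
    including rows with missing entries — and pairwise-incomplete rows are
    dropped within each individual resample, mirroring how missing data
    must be handled for pairwise statistics (no imputation is available).

    Per-resample RNG streams are spawned deterministically from ``seed``,
    so results are reproducible and independent of execution order.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    if statistic not in _STATS:
        raise ValueError(f"unknown statistic {statistic!r}; pick from {sorted(_STATS)}")
    xv = np.asarray(x, dtype=float).ravel()
    yv = np.asarray(y, dtype=float).ravel()
    if xv.size != yv.size:
        raise ValueError(f"length mismatch: {xv.size} vs {yv.size}")
    fn = _STATS[statistic]
    kw = stat_kwargs or {}

    xc, yc = _pairwise_complete(xv, yv)
    if xc.size < min_complete:
        raise DegenerateInputError(
            f"only {xc.size} pairwise-complete observations (need {min_complete})")
    point = fn(xc, yc, **kw)

    rng = np.random.default_rng(seed)
    n = xv.size
    vals = np.empty(B)
    failed = 0
    for b in range(B):
        idx = rng.integers(0, n, n)
        xb, yb = _pairwise_complete(xv[idx], yv[idx])
        if xb.size < min_complete:
            failed += 1
            vals[b] = np.nan
            continue
        try:
            vals[b] = fn(xb, yb, **kw)
        except DegenerateInputError:
            failed += 1
            vals[b] = np.nan
    if failed > 0.10 * B:
        raise DegenerateInputError(
            f"{failed}/{B} resamples had fewer than {min_complete} complete pairs "
            "or were degenerate; data too sparse for bootstrap inference")
    good = vals[np.isfinite(vals)]
    lo, hi = np.percentile(good, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    frac_pos = float(np.mean(good > 0))
    if lo > 0:
        call: Direction = "first_causes_second"
    elif hi < 0:
        call = "second_causes_first"
    else:
        call = "indecisive"
    return CausalityResult(
        statistic_name=statistic, value=float(point),
        ci_low=float(lo), ci_high=float(hi), n_effective=int(xc.size),
        direction_call=call, bootstrap_fraction_positive=frac_pos,
        ci_excludes_point=not (lo <= point <= hi),
    )
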