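"""Distributional and regression diagnostics required before pairwise
causal-direction estimation.

The direction statistics are only informative for non-Gaussian variables,
and the linear model they assume requires the regressor to be independent
of (not merely uncorrelated with) the regression residual.  This module
provides the corresponding battery: normality tests (Kolmogorov–Smirnov
with Lilliefors correction, D'Agostino skewness, Anscombe–Glynn kurtosis),
Hoeffding's nonparametric independence test between a predictor and the
OLS residual, and a linear-vs-quadratic fit comparison.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors
import statsmodels.api as sm

from .moments import DegenerateInputError, ols_residual

__all__ = ["NormalityResult", "LinearityResult", "AssumptionReport",
           "normality_battery", "hoeffding_d", "hoeffding_independence",
           "linearity_check", "assumption_report"]


@dataclass(frozen=True)
class NormalityResult:
    ks_stat: float
    ks_p: float
    skew_z: float
    skew_p: float
    kurt_z: float
    kurt_p: float

    @property
    def all_non_gaussian(self) -> bool:
        """Every test rejects normality at the 0.001 level (the working
        requirement for the direction statistics)."""
        return max(self.ks_p, self.skew_p, self.kurt_p) < 1e-3


@dataclass(frozen=True)
class LinearityResult:
    linear_adj_r2: float
    quadratic_p: float
    delta_adj_r2: float


@dataclass(frozen=True)
class AssumptionReport:
    """Per-variable normality results plus the predictor-vs-residual
    Hoeffding independence test and linearity diagnostics for a pair."""

    normality: dict[str, NormalityResult]
    hoeffding_D: float
    hoeffding_p: float
    linearity: LinearityResult

    def to_dict(self) -> dict:
        return {
            "normality": {k: asdict(v) for k, v in self.normality.items()},
            "hoeffding": {"D": self.hoeffding_D, "p": self.hoeffding_p},
            "linearity": asdict(self.linearity),
        }


def normality_battery(x, lilliefors_correction: bool = True) -> NormalityResult:
    """KS normality test plus moment-based skewness/kurtosis tests.

    By default the KS p-value uses the Lilliefors correction, since mean
    and SD are estimated from the sample (the naive KS table is strongly
    anti-conservative in that case); ``lilliefors_correction=False`` gives
    the naive version.  The skewness test is D'Agostino's z-transform, the
    kurtosis test the Anscombe–Glynn z-transform.
    """
    v = np.asarray(x, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size < 20:
        raise DegenerateInputError(f"need at least 20 observations, got {v.size}")
    if v.std(ddof=1) == 0:
        raise DegenerateInputError("constant sample")
    if lilliefors_correction:
        ks_stat, ks_p = lilliefors(v, dist="norm")
    else:
        ks_stat, ks_p = stats.kstest(v, "norm", args=(v.mean(), v.std(ddof=1)))
    sz, sp = stats.skewtest(v)
    kz, kp = stats.kurtosistest(v)
    return NormalityResult(ks_stat=float(ks_stat), ks_p=float(ks_p),
                           skew_z=float(sz), skew_p=float(sp),
                           kurt_z=float(kz), kurt_p=float(kp))


def _less_matrix(v: np.ndarray) -> np.ndarray:
    """φ-matrix of pairwise comparisons: 1 if column < row, ½ if tied."""
    m = (v[:, None] > v[None, :]).astype(float) + 0.5 * (v[:, None] == v[None, :])
    np.fill_diagonal(m, 0.0)
    return m


def hoeffding_d(x, y) -> float:
    """Hoeffding's D statistic of bivariate independence.

    Rank-based U-statistic estimating 30·∫(F₁₂ − F₁F₂)² dF₁₂; 0 under
    independence (sample values may be slightly negative, support
    [−0.5, 1]), 1 for strictly monotone dependence.  Midranks handle ties.
    """
    xv = np.asarray(x, dtype=float).ravel()
    yv = np.asarray(y, dtype=float).ravel()
    if xv.size != yv.size:
        raise ValueError(f"length mismatch: {xv.size} vs {yv.size}")
    n = xv.size
    if n < 5:
        raise DegenerateInputError("Hoeffding's D needs at least 5 observations")
    R = stats.rankdata(xv)
    S = stats.rankdata(yv)
    Q = 1.0 + (_less_matrix(xv) * _less_matrix(yv)).sum(axis=1)
    D1 = np.sum((Q - 1) * (Q - 2))
    D2 = np.sum((R - 1) * (R - 2) * (S - 1) * (S - 2))
    D3 = np.sum((R - 2) * (S - 2) * (Q - 1))
    denom = n * (n - 1) * (n - 2) * (n - 3) * (n - 4)
    return float(30.0 * ((n - 2) * (n - 3) * D1 + D2 - 2 * (n - 2) * D3) / denom)


def hoeffding_independence(x, resid, n_perm: int = 2000,
                           seed: int | np.random.SeedSequence | None = None
                           ) -> tuple[float, float]:
    """Hoeffding's D with a permutation p-value.

    The null distribution is generated by permuting ``resid`` against
    ``x`` (``n_perm`` draws), which is exact under ties; the p-value is
    (1 + #{D_perm ≥ D_obs}) / (n_perm + 1).  Permutations only permute the
    precomputed rank-comparison matrices, so each draw costs O(n²) memory
    traffic rather than a fresh ranking.
    """
    xv = np.asarray(x, dtype=float).ravel()
    rv = np.asarray(resid, dtype=float).ravel()
    if xv.size != rv.size:
        raise ValueError(f"length mismatch: {xv.size} vs {rv.size}")
    n = xv.size
    if n < 30:
        raise DegenerateInputError("need at least 30 paired observations")
    rng = np.random.default_rng(seed)

    R = stats.rankdata(xv)
    lx = _less_matrix(xv)
    ly = _less_matrix(rv)
    S0 = stats.rankdata(rv)
    denom = n * (n - 1) * (n - 2) * (n - 3) * (n - 4)

    def d_from(ly_m, S):
        Q = 1.0 + (lx * ly_m).sum(axis=1)
        D1 = np.sum((Q - 1) * (Q - 2))
        D2 = np.sum((R - 1) * (R - 2) * (S - 1) * (S - 2))
        D3 = np.sum((R - 2) * (S - 2) * (Q - 1))
        return 30.0 * ((n - 2) * (n - 3) * D1 + D2 - 2 * (n - 2) * D3) / denom

    d_obs = d_from(ly, S0)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        if d_from(ly[np.ix_(p, p)], S0[p]) >= d_obs:
            count += 1
    return float(d_obs), (1.0 + count) / (n_perm + 1.0)


def linearity_check(x, y) -> LinearityResult:
    """Compare a linear with a linear+quadratic OLS fit of y on x.

    Reports the linear model's adjusted R², the p-value of the quadratic
    coefficient, and the adjusted-R² gain of adding the quadratic term.
    """
    xv = np.asarray(x, dtype=float).ravel()
    yv = np.asarray(y, dtype=float).ravel()
    ok = np.isfinite(xv) & np.isfinite(yv)
    xv, yv = xv[ok], yv[ok]
    if xv.size < 30:
        raise DegenerateInputError(f"need at least 30 observations, got {xv.size}")
    if xv.std(ddof=1) == 0:
        raise DegenerateInputError("degenerate regressor")
    xc = xv - xv.mean()   # center to tame collinearity of x and x²
    lin = sm.OLS(yv, sm.add_constant(xc)).fit()
    quad = sm.OLS(yv, sm.add_constant(np.column_stack([xc, xc**2]))).fit()
    return LinearityResult(
        linear_adj_r2=float(lin.rsquared_adj),
        quadratic_p=float(quad.pvalues[2]),
        delta_adj_r2=float(quad.rsquared_adj - lin.rsquared_adj),
    )


def assumption_report(x, y, n_perm: int = 2000,
                      seed: int | np.random.SeedSequence | None = None,
                      names: tuple[str, str] = ("x", "y")) -> AssumptionReport:
    """Full pre-causality battery for a pairwise-complete pair:
    per-variable normality, Hoeffding independence of x vs the OLS residual
    of y on x, and the linearity diagnostics."""
    xv = np.asarray(x, dtype=float).ravel()
    yv = np.asarray(y, dtype=float).ravel()
    ok = np.isfinite(xv) & np.isfinite(yv)
    xv, yv = xv[ok], yv[ok]
    resid = ols_residual(yv, xv)
    D, p = hoeffding_independence(xv, resid, n_perm=n_perm, seed=seed)
    return AssumptionReport(
        normality={names[0]: normality_battery(xv), names[1]: normality_battery(yv)},
        hoeffding_D=D, hoeffding_p=p,
        linearity=linearity_check(xv, yv),
    )
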