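"""Longitudinal cohort pipeline: TV-time exposure groups, covariate-adjusted
change analysis, obesity risk ratios, the temporality criterion, and power.

The temporality criterion operationalizes one of Hill's causal viewpoints:
the achieved level of variable A should predict the *future change* of
variable B, and not vice versa.  Here A is daily TV viewing time and B is
adiposity (waist circumference, BMI), with changes over six and ten years,
giving an 8-comparison matrix (4 forward, 4 reverse).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .synthetic import PanelDataset

__all__ = ["assign_tv_group", "assign_tv_groups", "change_table", "GroupChangeTable",
           "obesity_risk_ratio", "temporality_matrix", "f_test_power",
           "causality_power_sim", "TV_GROUPS"]

TV_GROUPS = ["constantly_low", "constantly_moderate", "constantly_high",
             "increased", "decreased", "unclassified"]

_LOW = 60.0    # ≤ 1 h/day, boundary belongs to "low"
_HIGH = 180.0  # ≥ 3 h/day, boundary belongs to "high"
_SHIFT = 60.0  # ≥ 1 h/day change between first and last wave


def assign_tv_group(tv1: float, tv2: float, tv3: float,
                    constant_band_precedence: bool = True) -> str:
    """Classify a subject's TV-time trajectory (min/day at the three waves).

    constantly_low: all waves ≤ 60; constantly_moderate: all strictly
    between 60 and 180; constantly_high: all ≥ 180; increased/decreased:
    at least a 60 min/day shift between waves 1 and 3; otherwise
    unclassified.  With ``constant_band_precedence`` (default) the
    constant-band rules are evaluated before the change rules — the five
    named groups are then mutually exclusive; flipping the flag gives the
    change rules priority, for sensitivity analysis.
    """
    vals = (tv1, tv2, tv3)
    if any(v is None or not np.isfinite(v) for v in vals):
        return "unclassified"

    def constant_band():
        if all(v <= _LOW for v in vals):
            return "constantly_low"
        if all(_LOW < v < _HIGH for v in vals):
            return "constantly_moderate"
        if all(v >= _HIGH for v in vals):
            return "constantly_high"
        return None

    def change():
        if tv3 - tv1 >= _SHIFT:
            return "increased"
        if tv1 - tv3 >= _SHIFT:
            return "decreased"
        return None

    first, second = (constant_band, change) if constant_band_precedence else (change, constant_band)
    return first() or second() or "unclassified"


def assign_tv_groups(data: PanelDataset, **kw) -> pd.Series:
    """Vector version of :func:`assign_tv_group` over a panel."""
    f = data.frame
    out = [assign_tv_group(a, b, c, **kw)
           for a, b, c in zip(f["tv1"], f["tv2"], f["tv3"])]
    return pd.Series(pd.Categorical(out, categories=TV_GROUPS), index=f.index,
                     name="tv_group")


# ---------------------------------------------------------------------------
# Adjusted group change analysis
# ---------------------------------------------------------------------------

@dataclass
class GroupChangeTable:
    """Per-group descriptives and covariate-adjusted mean changes.

    ``means`` holds raw group means of the level variables; ``adjusted``
    the model-adjusted mean change per group (covariates at their overall
    means); ``contrasts`` all pairwise group differences of adjusted change
    with Tukey–Kramer familywise-corrected p-values.
    """

    outcome: str
    horizon: str            # '6y' or '10y'
    means: pd.DataFrame
    adjusted: pd.DataFrame
    contrasts: pd.DataFrame

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# outcome={self.outcome} horizon={self.horizon}\n")
            self.means.to_csv(fh)
            fh.write("\n")
            self.adjusted.to_csv(fh)
            fh.write("\n")
            self.contrasts.to_csv(fh, index=False)


_DEFAULT_COVARIATES = ("sex", "age", "pa_index", "energy_intake", "smoker")


def change_table(data: PanelDataset, groups: pd.Series, outcome: str = "waist",
                 horizon: str = "10y", covariates=_DEFAULT_COVARIATES,
                 include_baseline: bool = True, alpha: float = 0.05,
                 min_group_n: int = 5) -> GroupChangeTable:
    """Raw group means and covariate-adjusted mean change with Tukey–Kramer
    pairwise comparisons.

    The change (wave 3 − wave 1 for '10y', wave 2 − wave 1 for '6y') is
    modelled by OLS on group indicators plus the covariates and the
    baseline level of the outcome; adjusted group means evaluate the fit
    at the grand covariate means.  Pairwise contrasts use the studentized
    range with the Tukey–Kramer allowance for unequal group sizes.
    """
    if outcome not in ("waist", "bmi"):
        raise ValueError("outcome must be 'waist' or 'bmi'")
    later = {"6y": 2, "10y": 3}[horizon]
    f = data.frame.copy()
    g = pd.Series(groups).reset_index(drop=True)
    if not isinstance(g.dtype, pd.CategoricalDtype):
        g = g.astype("category")
    f["tv_group"] = g.values
    base, end = f"{outcome}1", f"{outcome}{later}"
    f["change"] = f[end] - f[base]

    level_cols = [c for c in ["bmi0", "waist1", "bmi1", "waist2", "waist3",
                              "bmi2", "bmi3"] if c in f.columns]
    means = f.groupby("tv_group", observed=False)[level_cols + ["change"]].mean()
    means.insert(0, "n", f.groupby("tv_group", observed=False)["change"].count())

    adj_cols = ([base] if include_baseline else []) + list(covariates)
    used = f.dropna(subset=["change", *adj_cols])
    counts = used.groupby("tv_group", observed=False)["change"].count()
    keep = counts[counts >= min_group_n].index.tolist()
    keep = [g for g in keep if g != "unclassified"]
    if len(keep) < 2:
        raise ValueError("need at least 2 groups with enough complete subjects")
    used = used[used["tv_group"].isin(keep)]

    G = pd.get_dummies(used["tv_group"].cat.remove_unused_categories(),
                       drop_first=False, dtype=float)
    keep = list(G.columns)
    X = pd.concat([G, used[adj_cols].astype(float)], axis=1)
    if np.linalg.matrix_rank(X.values) < X.shape[1]:
        corr = np.corrcoef(X.values.T)
        bad = [X.columns[j] for j in range(X.shape[1])
               for i in range(j) if abs(corr[i, j]) > 0.999]
        raise ValueError(f"singular design matrix; collinear columns: {bad or 'unknown'}")
    fit = sm.OLS(used["change"].values, X.values).fit()

    k = len(keep)
    cov_means = used[adj_cols].astype(float).mean().values
    adj = fit.params[:k] + (fit.params[k:] @ cov_means if adj_cols else 0.0)
    V = fit.cov_params()
    ns = used.groupby("tv_group", observed=True)["change"].count().reindex(keep)
    adjusted = pd.DataFrame({"n": ns.values, "adjusted_change": adj}, index=keep)

    df_resid = fit.df_resid
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            c = np.zeros(X.shape[1])
            c[i], c[j] = 1.0, -1.0
            est = float(c @ fit.params)
            se = float(np.sqrt(c @ V @ c))
            q = abs(est) / se * np.sqrt(2.0)
            p = float(stats.studentized_range.sf(q, k, df_resid))
            rows.append({"group_a": keep[i], "group_b": keep[j],
                         "difference": est, "se": se, "p_tukey": p,
                         "significant": p < alpha})
    contrasts = pd.DataFrame(rows)
    return GroupChangeTable(outcome=outcome, horizon=horizon, means=means,
                            adjusted=adjusted, contrasts=contrasts)


def obesity_risk_ratio(data: PanelDataset, groups: pd.Series, wave: int = 3,
                       covariates=_DEFAULT_COVARIATES,
                       reference: str = "constantly_low",
                       bmi_threshold: float = 30.0) -> pd.DataFrame:
    """Risk ratios of obesity (BMI > threshold) per TV group vs reference.

    A log-link binomial GLM on group indicators plus covariates; when it
    fails to converge (common with log links), a Poisson GLM with robust
    (HC1) variance is used instead and flagged in the output.
    """
    f = data.frame.copy()
    f["tv_group"] = groups.values
    f["obese"] = (f[f"bmi{wave}"] > bmi_threshold).astype(float)
    f.loc[f[f"bmi{wave}"].isna(), "obese"] = np.nan
    used = f.dropna(subset=["obese", *covariates])
    used = used[used["tv_group"] != "unclassified"]
    grps = [g for g in TV_GROUPS[:5] if (used["tv_group"] == g).any()]
    if reference not in grps:
        raise ValueError(f"reference group {reference!r} absent from data")
    if used.loc[used["tv_group"] == reference, "obese"].sum() == 0:
        raise ValueError("no obese subjects in the reference group; "
                         "RR undefined (consider a risk-difference model)")
    others = [g for g in grps if g != reference]
    G = pd.DataFrame({g: (used["tv_group"] == g).astype(float) for g in others})
    X = sm.add_constant(pd.concat([G, used[list(covariates)].astype(float)], axis=1))
    y = used["obese"].values
    model_used = "log-binomial"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.GLM(y, X.values, family=sm.families.Binomial(
                sm.families.links.Log())).fit(maxiter=200)
            if not fit.converged or np.isnan(fit.bse).any():
                raise ValueError
        except Exception:
            model_used = "robust-poisson"
            fit = sm.GLM(y, X.values, family=sm.families.Poisson()).fit(cov_type="HC1")
    rows = [{"group": reference, "rr": 1.0, "ci_low": 1.0, "ci_high": 1.0,
             "n": int((used["tv_group"] == reference).sum()), "model": model_used}]
    for i, g in enumerate(others, start=1):
        beta, se = fit.params[i], fit.bse[i]
        rows.append({"group": g, "rr": float(np.exp(beta)),
                     "ci_low": float(np.exp(beta - 1.96 * se)),
                     "ci_high": float(np.exp(beta + 1.96 * se)),
                     "n": int((used["tv_group"] == g).sum()), "model": model_used})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Temporality criterion
# ---------------------------------------------------------------------------

def _pearson_fisher_ci(x, y, alpha=0.05):
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 30:
        raise ValueError(f"only {n} pairwise-complete observations (need 30)")
    r = float(np.corrcoef(x[ok], y[ok])[0, 1])
    z = np.arctanh(r)
    hw = stats.norm.ppf(1 - alpha / 2) / np.sqrt(n - 3)
    return r, float(np.tanh(z - hw)), float(np.tanh(z + hw)), n


def temporality_matrix(data: PanelDataset, alpha: float = 0.05) -> pd.DataFrame:
    """The 8-comparison temporality matrix with Fisher-z 95% CIs.

    Forward rows: baseline TV time vs the 6y/10y change of waist and BMI.
    Reverse rows: baseline waist/BMI vs the 6y/10y change of TV time.
    Changes are later wave minus baseline.  The temporality criterion for
    "TV time causes adiposity change" is satisfied when every forward CI
    excludes 0 and every reverse CI covers 0.
    """
    f = data.frame
    d = {
        "tv1": f["tv1"].values,
        "waist1": f["waist1"].values, "bmi1": f["bmi1"].values,
        "d6_waist": (f["waist2"] - f["waist1"]).values,
        "d10_waist": (f["waist3"] - f["waist1"]).values,
        "d6_bmi": (f["bmi2"] - f["bmi1"]).values,
        "d10_bmi": (f["bmi3"] - f["bmi1"]).values,
        "d6_tv": (f["tv2"] - f["tv1"]).values,
        "d10_tv": (f["tv3"] - f["tv1"]).values,
    }
    comparisons = [
        ("TV-time vs d6y_Waist", "tv1", "d6_waist", "forward"),
        ("Waist vs d6y_TV-time", "waist1", "d6_tv", "reverse"),
        ("TV-time vs d10y_Waist", "tv1", "d10_waist", "forward"),
        ("Waist vs d10y_TV-time", "waist1", "d10_tv", "reverse"),
        ("TV-time vs d6y_BMI", "tv1", "d6_bmi", "forward"),
        ("BMI vs d6y_TV-time", "bmi1", "d6_tv", "reverse"),
        ("TV-time vs d10y_BMI", "tv1", "d10_bmi", "forward"),
        ("BMI vs d10y_TV-time", "bmi1", "d10_tv", "reverse"),
    ]
    rows = []
    for label, a, b, direction in comparisons:
        r, lo, hi, n = _pearson_fisher_ci(d[a], d[b], alpha)
        rows.append({"comparison": label, "direction": direction, "r": r,
                     "ci_low": lo, "ci_high": hi, "n": n,
                     "significant": not (lo <= 0.0 <= hi)})
    out = pd.DataFrame(rows)
    fwd = out[out.direction == "forward"]["significant"]
    rev = out[out.direction == "reverse"]["significant"]
    out.attrs["criterion_satisfied_forward"] = bool(fwd.all() and not rev.any())
    return out


# ---------------------------------------------------------------------------
# Power
# ---------------------------------------------------------------------------

def f_test_power(n_total: int, k_groups: int, f2: float, alpha: float = 0.05) -> float:
    """Power of the fixed-effects omnibus F test for k group means.

    Noncentrality λ = f²·n with Cohen's f² the ratio of between- to
    within-group variance; df = (k−1, n−k).
    """
    if not (n_total > k_groups >= 2):
        raise ValueError("need n_total > k_groups >= 2")
    if f2 < 0:
        raise ValueError("f2 must be nonnegative")
    df1, df2 = k_groups - 1, n_total - k_groups
    crit = stats.f.ppf(1 - alpha, df1, df2)
    if f2 == 0:
        return float(alpha)
    return float(stats.ncf.sf(crit, df1, df2, f2 * n_total))


def causality_power_sim(grid, B_replicates: int = 50, B_bootstrap: int = 200,
                        seed: int | None = None, statistic: str = "kernel",
                        use_bootstrap: bool = True, **stat_kwargs) -> pd.DataFrame:
    """Monte-Carlo power of a direction statistic over a scenario grid.

    ``grid`` is an iterable of dicts with keys accepted by
    :class:`~paircause.synthetic.LingamPairConfig` (n, b, cause_dist,
    noise_dist, confound_weight).  For each scenario the fraction of
    replicates whose bootstrap CI excludes 0 on the correct side is the
    estimated power; with ``use_bootstrap=False`` the (much cheaper)
    fraction of correct point-estimate signs is reported instead.
    """
    from .measures import bootstrap_ci, _STATS
    from .synthetic import LingamPairConfig, generate_lingam_pair

    master = np.random.SeedSequence(seed)
    rows = []
    for scen in grid:
        streams = master.spawn(B_replicates)
        hits = 0
        for ss in streams:
            cfg = LingamPairConfig(seed=int(ss.generate_state(1)[0] % 2**31), **scen)
            pair = generate_lingam_pair(cfg).pairwise_complete()
            if use_bootstrap:
                res = bootstrap_ci(pair.x, pair.y, statistic=statistic,
                                   B=max(B_bootstrap, 100), seed=ss,
                                   stat_kwargs=stat_kwargs)
                hits += (res.direction_call == "first_causes_second")
            else:
                hits += (_STATS[statistic](pair.x, pair.y, **stat_kwargs) > 0)
        rows.append({**scen, "statistic": statistic,
                     "power": hits / B_replicates, "replicates": B_replicates})
    return pd.DataFrame(rows)
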