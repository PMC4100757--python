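"""Synthetic data with the structure the pairwise causal analysis assumes.

Two generators:

* :func:`generate_lingam_pair` — bivariate linear non-Gaussian (LiNGAM)
  pairs with a known causal direction, optionally degraded by a shared
  non-Gaussian confounder, for validating the direction statistics;
* :func:`generate_cohort` — a three-wave panel (TV viewing time in min/day,
  waist circumference in cm, BMI in kg/m², plus a pre-study BMI wave and
  noise covariates) whose marginal moments and TV↔adiposity correlations
  are calibrated to a population cohort of working-age adults, with a
  configurable forward effect of baseline TV time on subsequent adiposity
  change and an optional reverse effect.

Non-normal marginals use the Fleishman power method (a moment-matched cubic
of a standard normal), because mean/SD/skewness/kurtosis are exactly the
calibration targets available.  Correlations between Fleishman-transformed
variables are attenuated relative to the latent normal correlation; the
Vale–Maurelli inversion recovers the latent correlation that yields a
desired target on the transformed scale.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "LingamPairConfig", "CausalPair", "CohortConfig", "PanelDataset",
    "fleishman_coefficients", "generate_lingam_pair", "generate_cohort",
]


# ---------------------------------------------------------------------------
# Fleishman power method
# ---------------------------------------------------------------------------

def fleishman_coefficients(target_skew: float, target_kurtosis: float) -> tuple[float, float, float, float]:
    """Coefficients (a, b, c, d) with a + bZ + cZ² + dZ³ of Z~N(0,1) having
    mean 0, variance 1 and the requested skewness and kurtosis (Normal = 3).

    Solved numerically from the Fleishman moment system; raises ValueError
    for infeasible (skew, kurtosis) pairs (roughly kurtosis < skew² + 1 or
    outside the cubic-transform region).
    """
    if target_kurtosis <= target_skew**2 + 1:
        raise ValueError(
            f"(skew={target_skew}, kurtosis={target_kurtosis}) violates the "
            "moment feasibility bound kurtosis > skew² + 1")
    ex = target_kurtosis - 3.0
    s = target_skew

    def eqs(p):
        b, c, d = p
        return [
            b * b + 6 * b * d + 2 * c * c + 15 * d * d - 1.0,
            2 * c * (b * b + 24 * b * d + 105 * d * d + 2) - s,
            24 * (b * d + c * c * (1 + b * b + 28 * b * d)
                  + d * d * (12 + 48 * b * d + 141 * c * c + 225 * d * d)) - ex,
        ]

    for d0 in (0.0, 0.01, 0.05, 0.1, 0.15, 0.2, 0.3):
        for c0 in (0.10 * s, 0.15 * s, 0.25 * s, 0.4 * s):
            sol = optimize.root(eqs, [max(1.0 - 3 * d0, 0.1), c0, d0], method="hybr")
            if sol.success and np.max(np.abs(eqs(sol.x))) < 1e-10 and sol.x[0] > 0:
                b, c, d = sol.x
                return (-c, float(b), float(c), float(d))
    raise ValueError(
        f"no Fleishman solution for skew={target_skew}, kurtosis={target_kurtosis}")


def _fleishman_apply(z: np.ndarray, coef) -> np.ndarray:
    a, b, c, d = coef
    return a + z * (b + z * (c + z * d))


def _vale_maurelli_rho(target_r: float, coef1, coef2) -> float:
    """Latent normal correlation giving ``target_r`` between two Fleishman
    variables (cubic inversion)."""
    _, b1, c1, d1 = coef1
    _, b2, c2, d2 = coef2
    k1 = b1 * b2 + 3 * b1 * d2 + 3 * d1 * b2 + 9 * d1 * d2
    k2 = 2 * c1 * c2
    k3 = 6 * d1 * d2
    roots = np.roots([k3, k2, k1, -target_r])
    real = roots[np.abs(roots.imag) < 1e-9].real
    ok = real[(real >= -1) & (real <= 1)]
    if ok.size == 0:
        raise ValueError(f"target correlation {target_r} unreachable for these marginals")
    return float(ok[np.argmin(np.abs(ok - target_r))])


# ---------------------------------------------------------------------------
# Standardized non-Gaussian marginals
# ---------------------------------------------------------------------------

def _sample_marginal(dist, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n iid values with mean 0 and variance 1 from a named family.

    ``dist`` is a name or a tuple: ('fleishman', skew, kurt) or
    ('lognormal', sigma).
    """
    if isinstance(dist, (tuple, list)):
        name, *params = dist
    else:
        name, params = dist, []
    name = str(name).lower()
    if name == "exponential":
        return rng.exponential(size=n) - 1.0
    if name == "uniform":
        return rng.uniform(-np.sqrt(3.0), np.sqrt(3.0), size=n)
    if name == "laplace":
        return rng.laplace(scale=1.0 / np.sqrt(2.0), size=n)
    if name == "lognormal":
        sig = params[0] if params else 0.5
        raw = rng.lognormal(mean=0.0, sigma=sig, size=n)
        mu = np.exp(sig**2 / 2)
        sd = np.sqrt((np.exp(sig**2) - 1) * np.exp(sig**2))
        return (raw - mu) / sd
    if name == "fleishman":
        if len(params) != 2:
            raise ValueError("fleishman marginal needs (skew, kurtosis)")
        return _fleishman_apply(rng.standard_normal(n), fleishman_coefficients(*params))
    if name in ("gaussian", "normal"):
        return rng.standard_normal(n)
    raise ValueError(f"unknown marginal family {dist!r}")


def _is_gaussian(dist) -> bool:
    name = dist[0] if isinstance(dist, (tuple, list)) else dist
    return str(name).lower() in ("gaussian", "normal")


# ---------------------------------------------------------------------------
# LiNGAM pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LingamPairConfig:
    """Generating configuration for one bivariate causal scenario.

    ``confound_weight`` w interpolates between the pure causal model (w=0:
    x_t = b·x_o + e_t) and pure confounding (w=1: both variables are a
    shared skewed factor plus independent noise, x = (z+e₁)/√2,
    y = (z+e₂)/√2, with the direct coefficient scaled away as b·(1−w)).
    """

    n: int
    b: float = 1.0
    cause_dist: object = "exponential"
    noise_dist: object = "exponential"
    confound_weight: float = 0.0
    confound_dist: object = "exponential"
    seed: int | None = None
    standardize_output: bool = False

    def __post_init__(self):
        if self.n < 10:
            raise ValueError("n must be at least 10")
        if not (0.0 <= self.confound_weight <= 1.0):
            raise ValueError("confound_weight must lie in [0, 1]")


@dataclass(frozen=True)
class CausalPair:
    """Aligned candidate-cause / candidate-effect samples with ground truth."""

    x: np.ndarray            # candidate cause
    y: np.ndarray            # candidate effect
    truth: str               # 'x_causes_y' | 'independent' | 'confounded'
    unidentifiable: bool = False
    confounder: np.ndarray | None = None

    def pairwise_complete(self) -> "CausalPair":
        ok = np.isfinite(self.x) & np.isfinite(self.y)
        z = self.confounder[ok] if self.confounder is not None else None
        return CausalPair(self.x[ok], self.y[ok], self.truth, self.unidentifiable, z)


def generate_lingam_pair(config: LingamPairConfig) -> CausalPair:
    """Draw one pair from the configured linear non-Gaussian system.

    Truth label records the generating structure: 'x_causes_y' whenever the
    effective direct coefficient b·(1−w) is nonzero, 'confounded' at w=1,
    'independent' when b=0 and w=0.  A warning flag is set when both
    marginals are Gaussian and b≠0 — the direction is then unidentifiable
    in principle.
    """
    rng = np.random.default_rng(config.seed)
    n, w = config.n, config.confound_weight
    e_o = _sample_marginal(config.cause_dist, n, rng)
    e_t = _sample_marginal(config.noise_dist, n, rng)
    lam = w / 2.0
    b_eff = config.b * (1.0 - w)
    if lam > 0:
        z = _sample_marginal(config.confound_dist, n, rng)
        x = np.sqrt(1 - lam) * e_o + np.sqrt(lam) * z
    else:
        z = None
        x = e_o
    struct = b_eff * x + e_t
    if lam > 0:
        struct = struct / np.sqrt(b_eff**2 + 1.0)
        y = np.sqrt(1 - lam) * struct + np.sqrt(lam) * z
    else:
        y = struct

    unident = _is_gaussian(config.cause_dist) and _is_gaussian(config.noise_dist) and b_eff != 0
    if unident:
        warnings.warn("both marginals Gaussian with a direct effect: causal "
                      "direction is unidentifiable", stacklevel=2)
    if w == 1.0:
        truth = "confounded"
    elif b_eff != 0:
        truth = "x_causes_y"
    else:
        truth = "independent"
    if config.standardize_output:
        x = (x - x.mean()) / x.std(ddof=1)
        y = (y - y.mean()) / y.std(ddof=1)
    return CausalPair(x=x, y=y, truth=truth, unidentifiable=unident, confounder=z)


# ---------------------------------------------------------------------------
# Three-wave panel cohort
# ---------------------------------------------------------------------------

#: (mean, SD, skewness, kurtosis) of daily TV time in hours, one per wave.
_TV_MOMENTS = ((1.9, 1.2, 1.05, 6.01), (1.8, 1.1, 1.40, 8.47), (1.9, 1.2, 2.02, 15.45))


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the synthetic three-wave panel.

    Marginal-moment targets (mean, SD, skewness, kurtosis) are the cohort's
    descriptive table; TV time is parameterized in hours/day and emitted in
    minutes/day.  Adiposity at waves 2–3 is built structurally as
    wave-1 level + drift + effect·(baseline TV) + skewed noise, so only its
    wave-1 marginal is moment-matched; wave 2–3 means are matched through
    the drift terms.  ``effect_tv_on_*_change`` is the 10-year change
    increment per baseline TV hour (the 6-year effect is 60% of it);
    ``effect_adiposity_on_tvchange`` (min/day per SD of baseline waist)
    injects a reverse effect, default absent.  ``tv_autocorr`` is the
    between-wave correlation of the latent TV propensity (compound
    symmetry); the TV↔adiposity association loads on the persistent TV
    component only, which keeps adiposity levels uncorrelated with future
    TV *change* when the reverse effect is zero.
    """

    n_subjects: int = 2000
    tv_moments: tuple = _TV_MOMENTS
    waist_moments: tuple = (84.1, 12.3, 0.74, 3.59)
    bmi_moments: tuple = (25.1, 4.4, 1.15, 5.30)
    bmi0_moments: tuple = (20.3, 2.6, 0.8, 4.2)
    waist_wave_means: tuple = (84.1, 88.6, 91.9)
    bmi_wave_means: tuple = (25.1, 26.0, 26.5)
    cross_sectional_r: tuple = (0.126, 0.116)   # wave-1 TV↔(waist, BMI)
    effect_tv_on_waist_change: float = 0.55     # cm per baseline TV hour, 10y
    effect_tv_on_bmi_change: float = 0.18       # kg/m² per baseline TV hour, 10y
    effect_adiposity_on_tvchange: float = 0.0   # min/day per SD baseline waist
    change_sd_waist: tuple = (4.0, 6.0)         # SD of 6y / 10y waist change
    change_sd_bmi: tuple = (1.7, 2.5)
    change_noise_skew_kurt: tuple = (0.8, 4.5)
    tv_autocorr: float = 0.5
    waist_bmi_latent_r: float = 0.8
    bmi0_latent_r: tuple = (0.5, 0.6)           # with waist1 / bmi1 latents
    missing_rate: tuple = (0.0, 0.05, 0.12)
    p_female: float = 0.549
    age_mean_sd: tuple = (42.2, 5.0)
    seed: int | None = None

    def __post_init__(self):
        for m in (self.waist_moments, self.bmi_moments, self.bmi0_moments, *self.tv_moments):
            if m[1] <= 0:
                raise ValueError("all SDs must be positive")
            if m[3] <= m[2] ** 2 + 1:
                raise ValueError(f"infeasible moments {m}: kurtosis ≤ skew² + 1")
        if not all(0.0 <= r < 1.0 for r in self.missing_rate):
            raise ValueError("missing_rate entries must lie in [0, 1)")
        if not (0.0 < self.tv_autocorr < 1.0):
            raise ValueError("tv_autocorr must lie in (0, 1)")


_COLUMNS = ["id", "sex", "age", "tv1", "tv2", "tv3", "waist1", "waist2", "waist3",
            "bmi0", "bmi1", "bmi2", "bmi3", "pa_index", "energy_intake", "smoker"]


@dataclass
class PanelDataset:
    """Per-subject three-wave panel with a pre-study BMI wave.

    Columns: id; sex (1=female); age (years at wave 3); tv1..tv3 (min/day);
    waist1..waist3 (cm); bmi0..bmi3 (kg/m²; bmi0 = pre-study); pa_index;
    energy_intake (kcal/day); smoker (0/1).  Missing values are NaN.
    """

    frame: pd.DataFrame
    config: CohortConfig | None = None
    tv_floor_rate: float = 0.0

    def __post_init__(self):
        missing = [c for c in _COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"panel is missing columns: {missing}")
        for c in ["tv1", "tv2", "tv3"]:
            if (self.frame[c].dropna() < 0).any():
                raise ValueError(f"negative TV time in column {c}")
        for c in ["waist1", "waist2", "waist3", "bmi0", "bmi1", "bmi2", "bmi3"]:
            if (self.frame[c].dropna() <= 0).any():
                raise ValueError(f"non-positive values in column {c}")

    def __len__(self) -> int:
        return len(self.frame)

    def available_n(self) -> dict[str, int]:
        return {c: int(self.frame[c].notna().sum()) for c in _COLUMNS if c != "id"}

    def to_csv(self, path) -> None:
        """Write the panel as CSV plus a JSON sidecar with the generating
        configuration and seed (if the panel was generated)."""
        path = Path(path)
        self.frame.to_csv(path, index=False)
        if self.config is not None:
            sidecar = path.with_suffix(".json")
            sidecar.write_text(json.dumps(
                {"config": asdict(self.config), "tv_floor_rate": self.tv_floor_rate},
                indent=2, default=list))

    @classmethod
    def from_csv(cls, path) -> "PanelDataset":
        frame = pd.read_csv(path)
        return cls(frame=frame)


def generate_cohort(config: CohortConfig | None = None) -> PanelDataset:
    """Generate a three-wave panel with the configured causal structure.

    Construction: a persistent latent TV propensity P plus wave-specific
    transients give the TV latents (compound-symmetric correlation
    ``tv_autocorr``); wave-1 waist/BMI and pre-study BMI latents correlate
    with P at the level that yields the target wave-1 cross-sectional
    correlations after the Fleishman transform (Vale–Maurelli inversion).
    Adiposity change to waves 2/3 is drift + effect·(baseline TV hours,
    centered) + skewed noise, with noise SD set so the total change SD hits
    its target; 60% of the 10-year TV effect accrues by year 6.  Missing
    values are inserted completely at random, per variable and wave.
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects
    phi = cfg.tv_autocorr

    tv_coefs = [fleishman_coefficients(m[2], m[3]) for m in cfg.tv_moments]
    waist_coef = fleishman_coefficients(*cfg.waist_moments[2:])
    bmi_coef = fleishman_coefficients(*cfg.bmi_moments[2:])
    bmi0_coef = fleishman_coefficients(*cfg.bmi0_moments[2:])
    noise_coef = fleishman_coefficients(*cfg.change_noise_skew_kurt)

    # latent loading of adiposity on the persistent TV component
    a_w = _vale_maurelli_rho(cfg.cross_sectional_r[0], tv_coefs[0], waist_coef) / np.sqrt(phi)
    a_b = _vale_maurelli_rho(cfg.cross_sectional_r[1], tv_coefs[0], bmi_coef) / np.sqrt(phi)
    r_wb = cfg.waist_bmi_latent_r
    r0w, r0b = cfg.bmi0_latent_r
    cov = np.array([
        [1.0, a_w, a_b, min(r0w, a_b)],
        [a_w, 1.0, r_wb, r0w],
        [a_b, r_wb, 1.0, r0b],
        [min(r0w, a_b), r0w, r0b, 1.0],
    ])
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("latent correlation structure is not positive definite; "
                         "lower cross_sectional_r or latent correlations") from exc
    latents = rng.standard_normal((n, 4)) @ chol.T
    P, Zw, Zb, Zb0 = latents.T

    # Per-wave loadings on P are scaled so the first-order (Hermite) part of
    # cov(adiposity, TV_w) is constant across waves despite the wave-specific
    # marginal transforms; otherwise adiposity would pick up a spurious
    # correlation with TV *change* even with no reverse effect.
    h1 = np.array([c[1] + 3 * c[3] for c in tv_coefs])      # E[Z·fleish(Z)]
    sds = np.array([m[1] for m in cfg.tv_moments])
    lam = np.sqrt(phi) * (h1[0] * sds[0]) / (h1 * sds)
    if (lam >= 1.0).any():
        raise ValueError("tv_autocorr too high for the configured TV moments")
    tv_h = np.empty((3, n))
    floor_hits = 0
    for w in range(3):
        zt = lam[w] * P + np.sqrt(1 - lam[w] ** 2) * rng.standard_normal(n)
        mu, sd = cfg.tv_moments[w][:2]
        vals = mu + sd * _fleishman_apply(zt, tv_coefs[w])
        floor_hits += int((vals < 0).sum())
        tv_h[w] = np.maximum(vals, 0.0)
    floor_rate = floor_hits / (3 * n)

    waist1 = cfg.waist_moments[0] + cfg.waist_moments[1] * _fleishman_apply(Zw, waist_coef)
    bmi1 = cfg.bmi_moments[0] + cfg.bmi_moments[1] * _fleishman_apply(Zb, bmi_coef)
    bmi0 = cfg.bmi0_moments[0] + cfg.bmi0_moments[1] * _fleishman_apply(Zb0, bmi0_coef)

    tvc = tv_h[0] - tv_h[0].mean()   # centered baseline TV (hours)
    sd_tv = tv_h[0].std(ddof=1)

    def changes(effect, sd6, sd10, means):
        drift6 = means[1] - means[0]
        drift10 = means[2] - means[0]
        s6sq = sd6**2 - (0.6 * effect * sd_tv) ** 2
        sxsq = sd10**2 - (effect * sd_tv) ** 2 - s6sq
        if s6sq <= 0 or sxsq <= 0:
            raise ValueError("effect too large for the configured change SDs")
        eps6 = _fleishman_apply(rng.standard_normal(n), noise_coef) * np.sqrt(s6sq)
        epsx = _fleishman_apply(rng.standard_normal(n), noise_coef) * np.sqrt(sxsq)
        d6 = drift6 + 0.6 * effect * tvc + eps6
        d10 = drift10 + effect * tvc + eps6 + epsx
        return d6, d10

    dw6, dw10 = changes(cfg.effect_tv_on_waist_change, *cfg.change_sd_waist,
                        cfg.waist_wave_means)
    db6, db10 = changes(cfg.effect_tv_on_bmi_change, *cfg.change_sd_bmi,
                        cfg.bmi_wave_means)
    waist2, waist3 = waist1 + dw6, waist1 + dw10
    bmi2, bmi3 = bmi1 + db6, bmi1 + db10

    tv_min = 60.0 * tv_h
    if cfg.effect_adiposity_on_tvchange != 0.0:
        zsc = (waist1 - waist1.mean()) / waist1.std(ddof=1)
        tv_min[1] = np.maximum(tv_min[1] + cfg.effect_adiposity_on_tvchange * zsc, 0.0)
        tv_min[2] = np.maximum(tv_min[2] + cfg.effect_adiposity_on_tvchange * zsc, 0.0)

    frame = pd.DataFrame({
        "id": np.arange(1, n + 1),
        "sex": (rng.random(n) < cfg.p_female).astype(int),
        "age": rng.normal(*cfg.age_mean_sd, size=n).round(1),
        "tv1": tv_min[0], "tv2": tv_min[1], "tv3": tv_min[2],
        "waist1": waist1, "waist2": waist2, "waist3": waist3,
        "bmi0": bmi0, "bmi1": bmi1, "bmi2": bmi2, "bmi3": bmi3,
        "pa_index": rng.normal(2.5, 0.6, size=n).clip(0.5),
        "energy_intake": rng.normal(2200.0, 600.0, size=n).clip(800.0),
        "smoker": (rng.random(n) < 0.25).astype(int),
    })
    for w, rate in enumerate(cfg.missing_rate):
        if rate > 0:
            for col in (f"tv{w+1}", f"waist{w+1}", f"bmi{w+1}"):
                frame.loc[rng.random(n) < rate, col] = np.nan
    return PanelDataset(frame=frame, config=cfg, tv_floor_rate=floor_rate)
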