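# Methods

## The pairwise causal model

The core object is the bivariate linear non-Gaussian acyclic model
(LiNGAM): for standardized variables either `y = b·x + e` (x exogenous)
or `x = b·y + e` (y exogenous), with the disturbance independent of the
exogenous variable. For Gaussian data the two factorizations are
indistinguishable — covariance between an OLS residual and its regressor
is zero by construction, and for Gaussians uncorrelatedness exhausts
dependence. Non-Gaussian disturbances break the symmetry: regressing the
*cause* on the *effect* leaves a residual that is dependent (though
uncorrelated) on the regressor. Each direction statistic turns this into
a signed scalar, positive when the first argument is the antecedent.

### T_kernel

`T_kernel(x, y) = M(y, ê_{x|y}) − M(x, ê_{y|x})` where `M` is the kernel
generalized-variance (KGV) dependence contrast: Gaussian-RBF Gram
matrices of the two samples are centered, factorized by pivoted
incomplete Cholesky (stopping when the residual trace falls below
`eta·n`, default `eta = 1e-4`, rank cap 150), and the regularized kernel
canonical correlations ρᵢ are the singular values of
`D_x U_xᵀ U_y D_y` with `D = λ/(λ + nκ/2)` from each factor's spectrum;
`M = −½Σ log(1−ρᵢ²)`. Defaults follow kernel-ICA convention: `σ = 1`,
`κ = 2·10⁻²` for n ≤ 1000, else `σ = 0.5`, `κ = 2·10⁻³`.

Numerical notes: the low-rank path agrees with a dense eigendecomposition
to ~1e-7 (tested); ρ is clipped to `[0, 1−1e-12]` before the log;
eigenvalues below 1e-12 of the factor spectrum are dropped. With
practical kernel widths the KGV is an upward-biased estimate of mutual
information (for a bivariate Gaussian with ρ = 0.5 at n = 2000 it reads
≈ 0.20 vs the closed-form 0.144); this bias is immaterial here because
only the *difference* of two M values on the same sample enters the
statistic. The statistic is exactly antisymmetric because swapping the
arguments swaps the same two computed values.

### T_entropy

`T_entropy(x, y) = [H̃(y) + H̃(ê_{x|y})] − [H̃(x) + H̃(ê_{y|x})]` with
standardized residuals and the maximum-entropy approximation
`H̃(u) = H_ν − k₁(E[log cosh u] − γ)² − k₂(E[u·e^{−u²/2}])²`,
`H_ν = (1+log 2π)/2`. The constants `k₁ = 79.047`, `k₂ = 7.4129`,
`γ = 0.37457` are the reference values of the pairwise likelihood-ratio
literature and are exposed in `EntropyApproxConfig`. `H̃ ≤ H_ν` always
(subtracted squares), and the factorization along the true direction
attains the smaller total entropy, i.e. the larger approximate
likelihood. Inputs must be standardized — entropy is not scale-invariant
— so the function refuses inputs whose mean/SD are off tolerance.

### T_skew

For standardized variables sign-adjusted to positive skewness,
`T_skew = r·(mean[x²y] − mean[x·y²])`. Under `y = rx + e` its population
value is `skew(x)·(r²−r³) > 0`; under the reverse model
`skew(y)·(r³−r²) < 0`. It is cheap, exactly antisymmetric, and
informative only for skewed variables; near-symmetric inputs are
accepted but carry essentially no signal. It serves as the analytically
tractable member of the family (its closed form anchors the bootstrap
coverage test).

### Bootstrap inference

95% percentile intervals from B resamples (B = 2000 by default; smaller
B changes only CI width, never the point estimate). Resampling draws
subject rows from the *full* roster, including rows with missing
entries, and drops pairwise-incomplete rows within each resample — the
appropriate scheme when no imputation is available for pairwise
statistics. A resample with fewer than 20 complete pairs is discarded;
more than 10% such failures aborts with diagnostics. Per-resample RNG
streams are spawned from one master `SeedSequence`, so results are
reproducible and order-independent. The direction call is
`first_causes_second` / `second_causes_first` when the CI excludes 0,
else `indecisive`; the fraction of positive resamples is recorded (≈ 0.5
under full confounding). Percentile CIs can in pathological cases fail
to bracket the point estimate; this is flagged, not enforced away.

## Assumption battery

- Normality: Kolmogorov–Smirnov with the Lilliefors correction by
  default (mean/SD are estimated, so the naive KS table is
  anti-conservative; a naive mode exists one flag away), D'Agostino's
  skewness z-test and the Anscombe–Glynn kurtosis z-test.
- Independence: Hoeffding's D from the rank U-statistic (midranks for
  ties; support [−0.5, 1], comonotone data attain exactly 1), with a
  permutation p-value `(1 + #{D_perm ≥ D_obs})/(n_perm + 1)` — exact
  under ties and free of table interpolation. Permutations reuse the
  precomputed O(n²) comparison matrices, so each draw is cheap.
- Linearity: OLS of y on x vs on (x, x²) with x centered; reports linear
  adjusted R², the quadratic term's p, and the adjusted-R² gain.

## Cohort pipeline

TV-trajectory groups (min/day): constantly low (all waves ≤ 60),
constantly moderate (all strictly between 60 and 180), constantly high
(all ≥ 180), increased / decreased (≥ 60 shift between first and last
wave), else unclassified. Boundary values 60 and 180 belong to low and
high respectively; the constant-band rules take precedence over the
change rules (the groups are then disjoint), with a flag to flip the
precedence for sensitivity analysis.

Adjusted change analysis: OLS of (later − baseline) on group indicators
plus covariates (sex, age, activity index, energy intake, smoking, and
the baseline level); adjusted group means evaluate the fit at the grand
covariate means; all pairwise contrasts use the studentized-range
distribution with the Tukey–Kramer allowance for unequal n. Obesity
risk ratios come from a log-link binomial GLM, falling back to Poisson
with robust (HC1) variance on non-convergence (the fallback is flagged
in the output).

Temporality matrix: Pearson r with Fisher-z CIs for the 8 comparisons
(TV₁ vs Δ6y/Δ10y of waist and BMI; waist₁/BMI₁ vs Δ6y/Δ10y of TV). The
forward-only criterion is satisfied when all forward CIs exclude 0 and
no reverse CI does.

Power: omnibus fixed-effects F with noncentrality `λ = f²·n`,
df `(k−1, n−k)`; e.g. n = 959, k = 5, f² = 0.02, α = 0.05 gives 0.956.
`causality_power_sim` estimates direction-recovery power of the T
statistics over a (n, b, innovation family, confounding) grid, either
from bootstrap CIs or, cheaply, from point-estimate signs.

## Synthetic data

`generate_lingam_pair` draws standardized innovations from named families
(exponential, uniform, Laplace, lognormal, Fleishman with arbitrary
skew/kurtosis, Gaussian) and forms `y = b·x + e`. The confounding weight
w mixes in a shared skewed factor z: each variable loads `√(w/2)` on z
and the direct coefficient is scaled by `(1−w)`, so w = 0 is the pure
causal model and w = 1 is exactly `x = (z+e₁)/√2`, `y = (z+e₂)/√2` — two
variables with no direct link, each half-driven by the confounder. This
keeps independent noise in both variables at every w (a mixing rule that
put *all* variance on z at w = 1 would make the pair degenerate) and
makes the degradation of direction recovery smooth in w. A pair that is
Gaussian in both innovations with b ≠ 0 is flagged unidentifiable.

`generate_cohort` builds the three-wave panel:

- **Marginals.** Fleishman cubics of standard normals matched to
  (mean, SD, skewness, kurtosis) targets. Defaults are the calibration
  table of a working-age cohort: TV time (h/day) (1.9, 1.2, 1.05, 6.01),
  (1.8, 1.1, 1.40, 8.47), (1.9, 1.2, 2.02, 15.45) across waves; wave-1
  waist (84.1, 12.3, 0.74, 3.59) and BMI (25.1, 4.4, 1.15, 5.30);
  pre-study BMI mean 20.3 (SD/shape 2.6/0.8/4.2, chosen — only the mean
  is tabulated). The solver refuses infeasible pairs
  (kurtosis ≤ skew² + 1). TV time is floored at 0 *after* moment
  matching (the physical constraint is absent from the moment targets);
  at the default targets ~2% of values are floored, which raises
  realized TV skewness from 1.05 to ≈ 1.2 and shrinks the SD by ≈ 2%.
  The flooring rate is reported on the dataset.
- **Correlation structure.** A persistent latent TV propensity P plus
  wave transients (compound symmetry, `tv_autocorr` = 0.5 by default — a
  free parameter with no table-anchored value). Wave-1 adiposity latents
  load on P at the level that produces the target wave-1 cross-sectional
  correlations (0.126 waist, 0.116 BMI) after the Fleishman transform
  (Vale–Maurelli cubic inversion). Per-wave loadings on P are rescaled
  by the first Hermite coefficient of each wave's transform so that the
  first-order covariance between adiposity and TV is constant across
  waves; without this, the wave-varying TV marginals would induce a
  spurious correlation between adiposity level and future TV *change*
  even with no reverse effect. Later-wave cross-sectional correlations
  are emergent from persistence rather than separately targeted.
- **Causal structure.** Adiposity change = drift (matching the tabulated
  wave means) + effect·(centered baseline TV hours) + skewed Fleishman
  noise, with 60% of the 10-year effect accrued by year 6 and noise SDs
  set so the total change SDs hit their targets. The change SDs
  (6y/10y: 4.0/6.0 cm waist, 1.7/2.5 kg/m² BMI) are not tabulated
  anywhere and were chosen once as realistic cohort values; together
  with the longitudinal correlation targets (0.101/0.110 waist,
  0.078/0.085 BMI) they imply the default effects 0.55 cm and
  0.18 kg/m² per baseline TV hour over 10 years. Wave-2/3 adiposity
  marginals are therefore emergent (level + change), not separately
  moment-matched — matching both would be overdetermined. The optional
  reverse effect adds min/day of TV at waves 2–3 per SD of baseline
  waist (default 0).
- **Missingness** is MCAR per variable and wave (defaults 0/5%/12%,
  echoing the growing per-wave attrition of the calibration tables); no
  dropout selectivity is modelled. Covariates (sex, age, activity,
  energy intake, smoking) are independent noise — they carry no
  confounding in the generator, so adjusted and unadjusted analyses
  agree in expectation.

What the generator does *not* emulate: attrition selectivity, the 1-hour
reporting grid of interview TV data (values are continuous minutes),
sex differences in TV time, measurement error, and any confounding
between covariates and exposure. Passing tests therefore validate the
*estimators* under the assumed model, not robustness to those real-data
features.

## Validation problem sizes

The test suite exercises: direction recovery on 100 pairs at n = 1000
(and a Gaussian unidentifiable control), full-confounding indecision at
n = 300 with 200 bootstrap resamples over 20 datasets, null calibration
of all four assumption tests at 400 replicates each, the temporality
pattern at n = 2500 over 30 replicates with calibration recovery checked
at n = 10⁴, closed-form T_skew endpoints at n = 10⁶, and percentile-CI
coverage over 300 nested simulations at n = 300, B = 300 (a size at
which the percentile interval's asymptotics hold; measured coverage
≈ 0.97). With the reverse effects exactly zero the four reverse
temporality tests are exact 5%-level nulls, so the *joint* all-8 pattern
holds in only ~3/4 of replicates by construction (≈ 0.95⁴ × forward
power); the per-comparison rates are the meaningful calibration quantity
and each exceeds 90%.

## Known limitations

- The KGV contrast is not a calibrated mutual-information estimate at
  default hyperparameters (positive finite-sample bias); only contrasts
  and orderings are interpreted.
- T_skew is uninformative for symmetric variables; T_entropy has
  visibly lower power than T_kernel under partial confounding.
- The log-binomial RR model frequently fails to converge at moderate
  prevalence; the robust-Poisson fallback is standard but changes the
  variance estimator.
- Group assignment requires complete TV data; subjects with any missing
  wave are unclassified rather than partially classified.
- Hoeffding's permutation p is lower-bounded at 1/(n_perm+1).
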