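# Methods

This note documents the generating model, the estimators, the numerical
choices and the design decisions behind `wmh_atrophy`. Volumes are in ml,
rates in ml/year, WMH burden per doubling (log2 ml), CSF concentrations in
pg/ml, TIV in ml.

## 1. Synthetic cohort generator

Each diagnostic group is described by a `GroupParams` preset. Per subject:

- **Covariates.** Age ~ N(mean, sd) (rounded to 0.1 y), gender Bernoulli,
  MMSE truncated normal, TIV ~ N(mean, sd), log2 WMH ~ N(mean, sd) — the
  location is a median and the scale an IQR/1.349, the conventional
  normal-equivalent SD. CSF Abeta42 and tau are normal, floored at
  physiological minima, and present for a `csf_fraction` subset. Five
  vascular-risk flags are independent Bernoullis.
- **Baseline volumes.** Linear in centered TIV and centered log2 WMH
  (plus an optional gender term) with normal residuals; intercepts are the
  mean volume of a female subject at average TIV/WMH. A clip guard keeps
  hippocampus < brain < TIV (it essentially never binds at the calibrated
  SDs).
- **Latent rates.** `rate = alpha + beta' (centered covariates) + b`, with
  `(b_B, b_H)` drawn from the 2x2 slope covariance via eigendecomposition
  (so zero-variance and singular covariances are allowed). The optional
  TIV x WMH term uses (TIV - mean)/100 x (log2WMH - mean), i.e. the change
  in the WMH effect per 100 ml of head size.
- **Observations.** Nominal follow-up visits per group (months), converted
  to years with uniform +/-`interval_jitter_yr` jitter. Dropout is
  monotone: each follow-up is attended with its retention probability given
  the previous visit was attended. With `mar_strength > 0`, the retention
  log-odds decrease with the standardized latent brain slope — dropout is
  then missing-at-random given the latent rate, which the ML mixed model
  tolerates. Every attended follow-up yields one baseline-anchored scan
  pair: `y = rate * t + e`, `e ~ N(0, resid_sd)` (optionally scaled by
  sqrt(t)).

All randomness flows from a single `numpy` `SeedSequence`; identical
configurations give byte-identical CSV output.

### Calibration presets

The presets reproduce a 198-control / 345-MCI / 154-AD cohort: group
demographics, baseline-volume regressions (e.g. control hippocampus
5.2 ml adjusted mean, -0.06 ml per WMH doubling), mean atrophy rates
(0.07 / 0.14 / 0.20 ml/yr hippocampal; 6.31 / 10.69 / 15.08 ml/yr whole
brain), WMH-rate associations (0.005 and 0.3 ml/yr per doubling in
controls), and a CSF-subset preset (n = 100) with Abeta42/tau rate effects.
Slope SDs are set so the Wald CI widths of the mean rates match the
reported interval widths at the group sizes; the slope correlation and the
brain WMH coefficient then jointly fix the conditional (brain-adjusted)
hippocampal WMH coefficient through
`beta_H|B = beta_H - (Sigma_HB / Sigma_BB) * beta_B` (0.003 ml/yr per
doubling in controls and MCI). For the MCI preset the reported point
values for the brain WMH coefficient, the slope SDs and the conditional
coefficient are not jointly attainable with |rho| <= 1, so the brain WMH
coefficient is set to 0.2 — inside its reported uncertainty interval —
with rho = 0.63. Visit schedules and retention tuples are chosen so the
maximum (and typical) number of scan pairs per subject matches the
reported per-group scan counts.

### What the generator does and does not emulate

It emulates the joint distribution of the analysed quantities: covariates,
baseline volumes, latent rates, scan-pair BSI outcomes, dropout. It does
not emulate images for the cohort (the BSI engine is exercised on
phantoms), scanner/site effects, practice effects, non-linear trajectories,
or measurement error in WMH itself.

## 2. Boundary shift integral

For two aligned images I1, I2 with masks M1, M2:

1. **Boundary region** `dilate(M1 ∪ M2, r_d) \ erode(M1 ∩ M2, r_e)` with
   6-connected structuring elements (radii default 1).
2. **Normalization**: both images are divided by the mean intensity of the
   eroded intersection, putting tissue at ~1 and making the fixed clip
   window meaningful across scans.
3. **Clip window** [0.25, 0.75] of normalized intensity, mapped to [0, 1].
4. **BSI** = voxel volume x sum over the region of
   (clip(I1) - clip(I2)); the symmetric variant averages the forward and
   reversed computation (with the argument-symmetric region used here they
   agree to rounding). Positive values mean volume loss from scan 1 to 2.

An empty boundary region warns and returns 0.

**Phantoms.** Validation images are built from *analytic signed-distance
fields* of a sphere (brain, R = 24 mm) containing an ellipsoid
(hippocampus, 8 x 5 x 5 mm semi-axes) on a 64-cubed 1 mm grid. Atrophy of a
requested volume is applied by thresholding the sorted interior distance
values at exactly the voxel count to remove, so the ground truth is an
exact voxel count; a sub-voxel center offset breaks lattice-symmetry ties
that would otherwise quantize achievable shrink volumes. Gaussian
smoothing (sigma = 0.5 voxel) imitates partial volume; optional white noise
is added relative to the normalized intensity scale. Noise-free BSI is
within 5% of the voxel-count truth at 0.1–2.0 ml shrinks; with 5%-of-
contrast noise the 20-seed mean is within 10%.

## 3. Cross-sectional models

`fit_baseline_model` is OLS of a baseline volume on centered log2 WMH,
centered TIV and a male indicator (female reference), with t-based 95%
CIs; the intercept is the adjusted mean volume. Rank deficiency is
reported with the offending columns named. `compare_groups_continuous` is
the nested-OLS F-test across diagnostic groups (optionally TIV-adjusted);
`compare_groups_categorical` is an exact conditional test for r x c tables
that enumerates all tables with the observed margins recursively using
log-gamma probabilities (two-sided by probability ordering, with a <= 1e-9
relative slack for float ties), and falls back to seeded Monte-Carlo
permutation when the enumeration budget is exceeded. The 2x2 case is
cross-checked against the hypergeometric distribution.

## 4. Longitudinal models

**Univariate.** Because every design row is `t_ij * u_i` with `u_i`
subject-level, each subject's marginal likelihood depends on the data only
through `k_i = #pairs`, `s_i = sum t^2`, `q_i = t'y`, `w_i = y'y`, and the
marginal variance is `d_i = sigma_e^2 + sigma_b^2 s_i`. The fixed effects
are profiled by GLS and the two variance components optimized on the log
scale with L-BFGS-B (ftol 1e-13), making a fit a few milliseconds at
n ~ 200. ML (not REML) is used throughout so likelihood-ratio tests of
nested fixed effects are valid; with ~200 subjects the ML variance bias is
negligible. Wald CIs use the GLS covariance at the ML variance estimates.
A sigma_b estimate at the search boundary (or an all-singleton design,
where sigma_b is unidentified) triggers a warning. Empirical-Bayes rates
are `u_i' beta + sigma_b^2 (q_i - m_i s_i) / d_i`.

**Joint bivariate.** Slopes `(b_B, b_H) ~ N(0, Sigma)` with Sigma
parameterized by its log-Cholesky factor (l11, l21, l22), plus the two
residual log-SDs. Per subject the precision update is the 2x2 matrix
`M = Sigma^-1 + diag(s_B/sigma_eB^2, s_H/sigma_eH^2)`, inverted in closed
form, so the whole likelihood is vectorized. Subjects observed for only
one outcome enter with the corresponding s = 0, i.e. their exact marginal
likelihood (valid under MAR). Optimization is Nelder–Mead polished by
L-BFGS-B from univariate-fit starting values.

**Adjusted association.** The conditional WMH effect on the hippocampal
rate given the concurrent whole-brain rate is
`beta_H|B = beta_H - (Sigma_HB / Sigma_BB) * beta_B`; its SE is obtained by
the delta method over the observed-information covariance of the *full*
parameter vector (all fixed effects plus the five variance parameters),
computed from a central-difference Hessian of the negative log-likelihood.
The estimand is refused when the conditioning outcome's slope variance is
numerically zero.

**Model extensions.** CSF Abeta42 and tau enter as (value - mean)/10 x
interval terms on the biomarker subset; the TIV x WMH product (per 100 ml)
tests head-size modulation of the WMH effect, with a df = 2 LRT removing
both WMH terms.

## 5. Pipeline

`run_pipeline` executes simulate / cross-sectional / longitudinal / plots
stages into an output directory, writing a `manifest.json` with SHA-256
hashes and per-stage seeds; stage failures name the failing stage. Seeds
fan out as `(seed * 10000 + offset) mod (2^31 - 1)` per stage. CSVs are
reloaded with round-trip float parsing so analysis-only reruns are
bit-identical to in-memory runs. `recovery_study` repeats generate + fit
across seeds and summarizes estimand recovery.

## 6. Verification strategy

- Exact oracles: noise-free cohorts (coefficients recovered to machine
  precision), voxel-count phantom truth, brute-force hypergeometric
  enumeration, likelihood factorization (diagonal Sigma joint likelihood
  equals the sum of univariate likelihoods).
- Reference implementations: statsmodels `MixedLM` (ML) agrees to 1e-4
  relative; `scipy.stats.fisher_exact` for 2x2 tables. These are
  test-only dependencies.
- Calibration: CI coverage within [92%, 98%] over 200 replicates; ANOVA
  and LRT type-I error within [3%, 7%] under the null.
- Large-sample consistency: slope-covariance recovery within 5% at
  n = 3000; conditional estimand agrees with a two-stage per-subject OLS
  oracle within 10% at large n / low noise.

## 7. Limitations

- Linear trajectories and normal random effects only; no heavy-tailed or
  non-monotone atrophy.
- The BSI engine assumes aligned, bias-corrected images; no registration
  or inhomogeneity correction is provided.
- Wald inference for variance-derived quantities (slope correlation,
  adjusted estimand) relies on asymptotic normality; very small groups may
  need profile or bootstrap intervals.
- The exact r x c test enumerates up to a budget (default 1e7 tables);
  beyond that p-values are Monte-Carlo with seed-reported reproducibility.
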