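# Methods

## Model and procedure

### Cox engine

All hazard ratios come from Cox proportional-hazards models fitted by
maximum partial likelihood. For subject *i* with covariate row `x_i`,
`h_i(t) = h0(t) exp(x_i' beta)`; the partial likelihood is the product
over event times of the subject's relative hazard against the risk set.
Tied event times are handled by Efron's correction by default (ICU
follow-up recorded in days produces many ties, and Efron is the less
biased of the two standard corrections); Breslow is available and is
used wherever exact correspondence with the classical log-rank test is
wanted, because the score test of a binary group indicator at beta = 0
under Breslow ties *is* the log-rank chi-square on tie-free data. With
tied deaths the two differ by the hypergeometric factor (n−d)/(n−1) in
the log-rank variance; the package keeps the classical variance, so
exact equality is asserted only on tie-free data.

Optimization is Newton–Raphson from beta = 0 with step-halving (up to 10
halvings per step), convergence when the score sup-norm or the relative
log-likelihood change falls below 1e-8, at most 50 iterations.
Covariates are centered internally (the partial likelihood is
location-invariant) so exp(eta) stays in range. A monotone partial
likelihood — the typical outcome of a dichotomization cut that separates
the groups — is flagged when any |beta_j| exceeds 15 and reported as
non-convergence rather than raised; scan points with non-converged fits
are excluded from smoothing and logged. No Firth-type penalization is
applied; it is noted as an extension.

Standard errors come from the observed information. Per-subject score
residuals (and dfbeta = residual × inverse information) are available on
every fitted model; they use Breslow risk-set weights at the fitted
beta, a negligible approximation under Efron ties at our tie densities,
and they are the backbone of the band construction below.

### Cutpoint scan

For a grid of cutoffs (inclusive of both ends: 20–35 by 0.5 gives 31
cutoffs), the scanned covariate is dichotomized — direction
`risk-below` codes 1 for subjects *below* the cutoff (BMI convention:
HR > 1 means excess risk at low values), `risk-above` codes 1 at/above
(HbA1c convention) — and an adjusted Cox model `indicator + adjusters`
is fitted per cutoff. Cutoffs whose cut leaves fewer than
`min_events_per_group` (default 5) deaths on either side, or whose fit
does not converge, are flagged and excluded from smoothing; at least 4
usable cutoffs are required.

### Spline smoothing and the simultaneous band

The usable log-HRs are smoothed with a restricted (natural) cubic spline
with 4 knots at the 5th/35th/65th/95th percentiles of the usable
cutoffs (Harrell's truncated-power construction, linear beyond the
boundary knots), fitted by weighted least squares with weights 1/se².
Inverse-variance weighting keeps the huge-SE points near the
distribution tails from dominating the fit.

The band is `exp(fit ± z_{1−α/(2m)} · SE_f)` with multiplicity m = the
number of *usable scan points* (not the fine evaluation grid; the tested
cutoffs are the family being corrected for). The fine grid has ≥ 200
points spanning the full scan range.

`SE_f` deserves emphasis. The m scan points are computed from one and
the same cohort and are correlated with coefficients near 1 at adjacent
cutoffs. The naive WLS covariance (B'WB)⁻¹ treats them as independent
and shrinks the curve SE by roughly sqrt(m/4); in simulation the
resulting "simultaneous" band excluded HR = 1 somewhere in about two
thirds of effect-free cohorts. The package therefore estimates the full
m×m covariance of the scan points from their influence functions — for
each cutoff, the dfbeta vector of the group coefficient over subjects;
the covariance of two scan points is the inner product of their dfbeta
vectors (an infinitesimal-jackknife / Lin–Wei sandwich argument) — and
propagates it through the WLS projection. With this covariance the band
excludes HR = 1 under the null in ~1% of cohorts at alpha = 0.05
(500 simulated cohorts of n = 2000), i.e. conservatively, as a
Bonferroni band should. The naive covariance remains available as a
fallback when `smooth_scan` is called without dfbetas.

### Threshold calls

`detect_threshold` reports the maximal sub-intervals of the evaluation
grid where the band's lower limit exceeds 1 (side "risk": the group
coded 1 has elevated hazard) or the upper limit is below 1 (side
"protection"), and a headline value — the left boundary of the first
risk interval. Note that the headline marks where excess risk becomes
*detectable*, which is a power-dependent quantity: for a true step
effect the dichotomized contrast is positive (diluted) below the true
threshold too, so with growing n the crossing point moves below the true
threshold. In simulations with a true HbA1c step at 9.3% (HR 1.74), the
median headline is ≈ 8.8 at n = 199 (detection in ~24% of cohorts) but
≈ 7.9 at n = 2000 (detection in 84%). Consumers who want the threshold
*location* rather than the detection onset should read the fitted
curve's shape, not the band crossing.

### Group model and adjusted curves

`group_cox` stratifies the scanned covariate at fixed bounds
(lower-inclusive; defaults 20/24/35 give four BMI strata) and fits one
Cox model with k−1 indicators against the lowest stratum, adjusted by
default for APACHE II and HbA1c. Adjusted survival curves use the
corrected-group-prognosis method: for each stratum, the cohort average
of individual predicted curves `exp(−Λ0(t)·exp(eta_i))` with the stratum
indicators forced and each subject's own adjusters retained, where Λ0 is
the Breslow baseline. With all coefficients zero every curve collapses
to the Nelson–Aalen-based `exp(−Λ0)`; the curves are invariant to affine
rescaling of the adjusters. Mean-covariate substitution was rejected
because averaging predictions is the defensible modern reading and both
reduce to Kaplan–Meier when effects vanish. No confidence bands are
produced for adjusted curves (bootstrap noted as an extension), and
discharge alive is treated as censoring, not as a competing risk.

### Descriptive statistics

Survivor/nonsurvivor comparisons use the pooled-variance Student t for
approximately normal variables (summarized mean ± sd), the asymptotic
Mann–Whitney U for skewed ones (median, IQR), and the Pearson chi-square
*without* continuity correction for categorical ones; the variable→test
map is fixed in `tables.TABLE1_VARIABLES`. Glucose tolerance follows the
ADA HbA1c bands — normal < 5.7%, prediabetes [5.7, 6.5), diabetes ≥ 6.5%
— with a known diabetes history overriding the measurement in
`classify_glucose`; the *descriptive* glucose-tolerance rows of the
baseline table classify by HbA1c alone, which is the convention the
published count patterns are consistent with. WHO BMI bins are
half-open lower-inclusive: [18.5, 25), [25, 30), [30, 40), [40, ∞) —
the published category labels leave values such as 24.95 or exactly 40
formally unassigned, and lower-inclusive bins are the standard
resolution. Correlations are reported as r² (Pearson or Spearman) with
the two-sided p for zero correlation.

## Synthetic cohort generator

The generator emulates a ~200-patient mixed ICU cohort with high
severity and ~43% in-hospital mortality. Structure:

- **Covariates.** (BMI, HbA1c, hemoglobin) are drawn through a Gaussian
  copula with pairwise correlations sqrt(r²); marginals are truncated
  normal for BMI (mean 26.1, sd 6.7 kg/m², bounds 13–60) and hemoglobin,
  truncated log-normal for HbA1c. APACHE II is truncated normal
  (20.7 ± 8, bounds 0–71, rounded); SOFA is a noisy linear function of
  APACHE; age, sex, laboratory values and treatment flags are filled in
  with severity-linked marginals matched to the emulated cohort's
  summaries (flags by logistic models on centered APACHE II).
- **Outcomes.** Death time is exponential per subject with
  log-hazard = log(baseline) + hba1c_effect(hba1c) + bmi_effect(bmi)
  + apache_loghr_per_point·apache2. Cox estimation is baseline-free, so
  an exponential truth loses no generality. Discharge alive is an
  independent exponential (default rate 0.0247/day); follow-up is
  min(death, discharge, 365 d) and event = 1 iff death comes first.
  Raising the discharge rate can only shorten censoring times
  (inverse-transform sampling on a dedicated substream), so the event
  fraction is monotone in it on matched seeds.
- **Effects.** `ThresholdEffect(threshold, loghr)` is a step;
  `PiecewiseLinearEffect(breakpoints, slopes)` is continuous with
  nearest-segment extrapolation, anchored at 0 at the first breakpoint
  (constant shifts are absorbed by the baseline).
- **Seeding.** One integer seed spawns independent substreams
  (covariates, death, discharge, flags) via `SeedSequence`, so cohorts
  are bit-reproducible and partial changes (e.g. only the censoring
  rate) leave the other streams untouched.

### Generator defaults (calibration)

Defaults were fixed once, by Monte-Carlo calibration against the
emulated cohort's published summaries, before any acceptance experiment
was run:

- HbA1c marginal: log-location log(5.8), log-sd 0.29, bounds 3.5–16%.
  A log-normal matched to the published full-cohort IQR (5.3–6.3) would
  put essentially no mass above 9.3% — the real cohort is a mixture with
  a diabetic right tail (known-diabetes subgroup median 6.7, upper
  quartile 8.5, implying roughly 5% of patients above 9.3%). The default
  reproduces that tail (P(HbA1c ≥ 9.3) ≈ 5%) at the cost of a wider IQR
  (≈ 4.9–7.1) than the printed one. This is a deliberate trade-off: the
  threshold analyses are meaningless in a cohort with no hyperglycemic
  exposure.
- Default BMI effect: slopes −0.0351 (per kg/m², below 24), 0 (24–30),
  −0.1010 (above 30), solving for dichotomized contrasts of log 1.4 at
  cutoff 23 and log 2.0 at cutoff 33 under the BMI marginal — the two
  printed low/high-end hazard ratios of the emulated study.
- Default HbA1c effect: step of log 1.74 at 9.3%.
- APACHE II: 0.08 log-HR per point.
- Baseline hazard 0.00412/day: solves mean[λ/(λ+μ)] = 0.432 (the
  published mortality) under the default effects; with discharge rate
  0.0247/day the median follow-up is ≈ 16 days, matching the published
  median.
- Known-diabetes flag: logistic in HbA1c (slope 1.5 per %, intercept
  −1.377 at 6.5%), calibrated to a 25% marginal.

`GeneratorConfig.null_effects()` removes every hazard effect and
rescales the baseline by the parent config's mean relative hazard
(fixed-seed Monte Carlo), so null cohorts keep the same event fraction
and censoring balance while making the hazard identical across patients.
Under this null, a univariate BMI Cox Wald test rejects at ≈ 4.5%
(1000 cohorts, alpha 0.05), and the scan band's false-exclusion rate is
≈ 1%.

## Simulation experiments (`cutscan.studies`)

- **Threshold recovery**: cohorts with only the 9.3% step effect
  (n = 2000, 200 seeds), HbA1c scan 4.5–12.0 by 0.25 risk-above
  (the BMI grid is the published one; the HbA1c grid is this package's
  choice, spanning the observed range at finer resolution than the
  reported threshold), APACHE-adjusted; collects the headline of each
  threshold call. As discussed above the median headline sits near 7.9
  at this sample size because the headline estimates detection onset,
  not threshold location; the experiment reports the honest value.
- **Null band coverage**: 500 effect-free cohorts (n = 2000), BMI scan;
  fraction of cohorts where the band excludes 1 anywhere. Expected
  ≤ alpha; observed ≈ 0.01.
- **U-shape sign-pattern recovery**: cohorts with a literal U-shaped BMI
  effect — slopes −0.1172 below 24, 0 on 24–30, +0.1200 above 30,
  solving contrast(23) = log 1.4 and contrast(27) = 0. A monotone
  "protective" effect cannot produce an opposite-signed scan, since the
  below-vs-above contrast of a monotone effect has one sign at every
  cutoff; the U is the configuration under which the three-sign pattern
  is a well-posed target. Recovery = band lower > 1 at cutoff 21, band
  covering 1 at 27, band upper < 1 at 34 on the risk-below scan;
  observed ≈ 99% at n = 2000 (200 seeds).
- **Simulator calibration**: mean event fraction over 200 default
  cohorts of n = 199 (target 0.432 ± 0.05) and the BMI–HbA1c r² on one
  n = 10,000 cohort (target window 0.03–0.07).

Experiment sizes (200/500/200 cohorts at n = 2000) were chosen so the
Monte-Carlo SE of each rate is ≲ 1.5% while the full battery runs in
about 90 s on one CPU.

## What the synthetic data does and does not show

The generator reproduces the first-order structure the analysis relies
on: event fraction, censoring balance, covariate correlations, a
severity gradient, and configurable nonlinear truth on the log hazard.
It does not model ICU length-of-stay dynamics, time-varying covariates,
informative discharge (censoring is independent of covariates — the
weakest testable assumption, since no discharge model is published),
competing risks, or measurement error in BMI/HbA1c. Passing tests
therefore demonstrate that the *procedure* recovers configured truths
under clean proportional-hazards sampling — not that it would be
unconfounded on real ICU data.

## Numerical choices and degenerate inputs

- Convergence: score sup-norm < 1e-8 or relative log-likelihood change
  < 1e-8; max 50 Newton iterations; 10 step-halvings.
- Separation: |beta| > 15 → non-converged with a "monotone" diagnostic.
- Constant covariate or singular information → DegenerateDesignError.
- Degenerate cut (everyone on one side) → flagged scan point.
- KM ties use the simultaneous-death product-limit convention; the
  Greenwood SE is set to 0 where the curve reaches 0.
- Spline knots must be distinct; coincident knots raise an error.
- Grid construction is round-safe (integer step counts), inclusive of
  both endpoints.

## Known limitations

- The headline of a threshold call is a detection-onset estimator
  (see above); no debiased threshold-location estimator is provided.
- The band's simultaneity is Bonferroni over tested cutoffs; no
  Šidák/permutation alternatives.
- No maximally-selected-rank-statistics cutpoint selection; the scan
  deliberately reports the whole curve instead of an "optimal" cut.
- Score residuals use Breslow weights even for Efron fits.
- The four-group model requires every stratum to be nonempty with at
  least one event; it does not merge sparse strata automatically.
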