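# cutscan

Threshold and shape detection for continuous risk factors in survival
data: **cutpoint-scanned Cox hazard ratios with spline smoothing and
Bonferroni simultaneous bands**, plus the descriptive machinery of an
ICU cohort study and a synthetic cohort generator to test it all on.

## The problem

In critically ill patients, the relation between a continuous risk
factor and in-hospital mortality is often not linear: chronic
hyperglycemia (HbA1c) appears harmful only above some threshold, and
body-mass index shows the "obesity paradox" — excess risk at low BMI,
none in the overweight range, apparent protection at high BMI. A
standard way to expose such structure without assuming a functional
form is the dichotomization scan:

1. For each cutoff *c* on a grid (e.g. BMI 20–35 kg/m² in steps of 0.5),
   split the cohort at *c* and fit a Cox proportional-hazards model
   `h(t | x) = h₀(t) · exp(β·1[group] + γ·APACHE II)`,
   recording the adjusted log hazard ratio `β̂(c)` and its SE.
2. Smooth `β̂(c)` across cutoffs with a four-knot restricted (natural)
   cubic spline, fitted by inverse-variance-weighted least squares.
3. Surround the fitted curve `exp(f̂(c))` with a simultaneous band
   `exp(f̂(c) ± z₁₋α/(2m) · SE_f(c))`, Bonferroni-corrected over the
   *m* tested cutoffs. Because all scan points come from one cohort,
   `SE_f` is propagated from the full covariance of the scan points
   (score-residual influence functions), not from the naive WLS formula.
4. Report the covariate ranges where the band excludes HR = 1 — a
   threshold call.

The package wraps this in statsmodels-style model/results objects
(`CoxPH → CoxPHResults`, `CutpointScan → CutpointScanResults`), with
Kaplan–Meier and corrected-group-prognosis adjusted survival curves,
baseline ("Table 1") statistics with ADA glucose-tolerance and WHO BMI
categories, and a fully configurable synthetic ICU-cohort generator.

## Worked example

```python
import numpy as np
from cutscan import GeneratorConfig, generate_cohort, CutpointScan, ScanSpec

cohort = generate_cohort(GeneratorConfig(n_patients=2000, seed=7))

spec = ScanSpec(covariate="bmi", grid_lo=20, grid_hi=35, step=0.5,
                direction="risk-below", adjust_for=["apache2"])
res = CutpointScan(cohort, spec).fit()
print(res.summary())
```

Output (seed 7):

```
Cutpoint scan of 'bmi' (20-35 step 0.5, risk-below, adjusted for ['apache2'])
  usable cutoffs: 31 of 31 (Bonferroni m = 31, alpha = 0.05)
  spline knots: [20.75, 25.25, 29.75, 34.25]
  band excludes 1 on [20.8, 35] (risk)
  headline threshold: 20.8
```

Each of the 31 cutoffs got an adjusted Cox fit; the band excludes
HR = 1 almost everywhere because the generator's default BMI effect is
protective across the whole range (hazard falls with BMI), so patients
below *any* cutoff are at excess risk relative to those above it — at
n = 2000 that is detectable at nearly every cutoff. `res.points_frame` holds
the per-cutoff log-HRs and SEs, `res.band.to_frame()` the smoothed
curve with its band.

The same machinery from the shell:

```bash
cutscan simulate --n 2000 --seed 7 --out cohort.csv
cutscan scan --input cohort.csv --covariate bmi --lo 20 --hi 35 \
        --step 0.5 --direction risk-below --adjust apache2 --out bmi
cutscan run-all --outdir results/ --seed 7     # full study replica
```

`run-all` writes the cohort, the baseline table, both scans (HbA1c and
BMI) with bands and threshold calls, the four-group BMI Cox model, the
adjusted survival curves, and a manifest with SHA-256 checksums of every
output — re-running with the same seed reproduces them byte for byte.

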