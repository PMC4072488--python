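"""Simulation study designs: the experiments that validate the scan.

Each function defines one repeated-simulation experiment — the cohort
configuration it runs under and the statistic it measures — so that the
test suite and the reproduction script exercise identical conditions.

Seeds: every experiment takes a base seed and derives per-replicate
seeds through ``numpy.random.SeedSequence`` spawning, so replicates are
independent and the whole experiment is reproducible from one integer.
"""

from __future__ import annotations

import numpy as np

from .datagen import GeneratorConfig, PiecewiseLinearEffect, ThresholdEffect, generate_cohort
from .exceptions import ScanFailureError
from .cox import CoxPH
from .scan import CutpointScan, ScanSpec, detect_threshold

__all__ = [
    "hba1c_scan_spec",
    "bmi_scan_spec",
    "threshold_recovery_config",
    "u_shape_config",
    "threshold_recovery",
    "null_band_coverage",
    "shape_recovery",
    "simulator_calibration",
]

# U-shaped BMI effect for the shape-recovery experiment: hazard elevated
# below BMI 24 and above BMI 30, flat between.  Slopes solve for a
# dichotomized contrast of log 1.4 at cutoff 23 (the printed low-end HR
# of the cohort being emulated) and an exact null contrast at cutoff 27
# under the default BMI marginal.
U_SHAPE_SLOPE_LOW = -0.1172
U_SHAPE_SLOPE_HIGH = 0.1200


def hba1c_scan_spec(alpha: float = 0.05) -> ScanSpec:
    """Default HbA1c scan: 4.5-12.0% by 0.25, risk above the cutoff."""
    return ScanSpec(
        covariate="hba1c", grid_lo=4.5, grid_hi=12.0, step=0.25,
        direction="risk-above", adjust_for=["apache2"], alpha=alpha,
    )


def bmi_scan_spec(alpha: float = 0.05) -> ScanSpec:
    """Default BMI scan: 20-35 kg/m^2 by 0.5, risk below the cutoff."""
    return ScanSpec(
        covariate="bmi", grid_lo=20.0, grid_hi=35.0, step=0.5,
        direction="risk-below", adjust_for=["apache2"], alpha=alpha,
    )


def _seeds(base_seed: int, n: int) -> list[int]:
    # keep derived seeds below 2**31
    return [int(s) % (2**31) for s in np.random.SeedSequence(base_seed).generate_state(n)]


def threshold_recovery_config(n: int = 2000, seed: int = 0) -> GeneratorConfig:
    """Cohort with a pure HbA1c threshold: log-HR log(1.74) at/above 9.3%."""
    return GeneratorConfig(
        n_patients=n, seed=seed,
        hba1c_effect=ThresholdEffect(9.3, float(np.log(1.74))),
        bmi_effect=None,
    )


def u_shape_config(n: int = 2000, seed: int = 0) -> GeneratorConfig:
    """Cohort with the U-shaped BMI effect and no HbA1c effect."""
    return GeneratorConfig(
        n_patients=n, seed=seed,
        hba1c_effect=None,
        bmi_effect=PiecewiseLinearEffect(
            (20.0, 24.0, 30.0, 35.0), (U_SHAPE_SLOPE_LOW, 0.0, U_SHAPE_SLOPE_HIGH)
        ),
    )


def threshold_recovery(n_cohorts: int = 200, n: int = 2000, seed: int = 0) -> dict:
    """Scan HbA1c cohorts with a true 9.3% threshold; collect headlines.

    Returns the per-cohort detected headline thresholds and their median;
    the scan recovers the configured threshold when the median lands
    within the grid resolution of 9.3.
    """
    headlines = []
    n_detected = 0
    for s in _seeds(seed, n_cohorts):
        df = generate_cohort(threshold_recovery_config(n=n, seed=s))
        try:
            res = CutpointScan(df, hba1c_scan_spec()).fit()
        except ScanFailureError:
            continue
        call = res.threshold_call
        if call.headline is not None:
            n_detected += 1
            headlines.append(call.headline)
    med = float(np.median(headlines)) if headlines else float("nan")
    return {
        "n_cohorts": n_cohorts,
        "n_detected": n_detected,
        "headlines": headlines,
        "median_headline": med,
    }


def null_band_coverage(n_cohorts: int = 500, n: int = 2000, seed: int = 0) -> dict:
    """False-positive rate of the Bonferroni band under a null cohort.

    Cohorts are generated with every hazard effect removed; the band
    should exclude HR = 1 anywhere in at most ~alpha of replicates
    (Bonferroni is conservative).
    """
    base = GeneratorConfig(n_patients=n, seed=0).null_effects()
    n_excl = 0
    n_run = 0
    for s in _seeds(seed, n_cohorts):
        cfg = GeneratorConfig(**{**_cfg_dict(base), "seed": s})
        df = generate_cohort(cfg)
        try:
            res = CutpointScan(df, bmi_scan_spec()).fit()
        except ScanFailureError:
            continue
        n_run += 1
        if not res.threshold_call.is_empty:
            n_excl += 1
    return {
        "n_cohorts": n_run,
        "n_excluding": n_excl,
        "rate": n_excl / n_run if n_run else float("nan"),
    }


def shape_recovery(n_cohorts: int = 200, n: int = 2000, seed: int = 0) -> dict:
    """Sign-pattern recovery of the U-shaped BMI effect.

    Pattern at the band evaluated at BMI 21 / 27 / 34 on the risk-below
    scan: lower > 1 at 21 (excess hazard below the cutoff), band covering
    1 at 27 (flat region), upper < 1 at 34 (the group below the cutoff is
    protected relative to the high-BMI extreme).
    """
    n_ok = 0
    n_run = 0
    for s in _seeds(seed, n_cohorts):
        df = generate_cohort(u_shape_config(n=n, seed=s))
        try:
            res = CutpointScan(df, bmi_scan_spec()).fit()
        except ScanFailureError:
            continue
        n_run += 1
        band = res.band
        def at(c):
            i = int(np.argmin(np.abs(band.eval_grid - c)))
            return band.lower[i], band.upper[i]
        lo21, _ = at(21.0)
        lo27, up27 = at(27.0)
        _, up34 = at(34.0)
        if lo21 > 1.0 and lo27 <= 1.0 <= up27 and up34 < 1.0:
            n_ok += 1
    return {"n_cohorts": n_run, "n_recovered": n_ok, "rate": n_ok / n_run if n_run else float("nan")}


def simulator_calibration(n_seeds: int = 200, seed: int = 0, n_big: int = 10_000) -> dict:
    """Default-config calibration: mean event fraction and BMI-HbA1c r^2.

    The event fraction averages n=199 cohorts over ``n_seeds`` seeds; the
    copula calibration is checked on one large (n_big) cohort.
    """
    fracs = []
    for s in _seeds(seed, n_seeds):
        df = generate_cohort(GeneratorConfig(n_patients=199, seed=s))
        fracs.append(df["event"].mean())
    big = generate_cohort(GeneratorConfig(n_patients=n_big, seed=_seeds(seed + 1, 1)[0]))
    r = np.corrcoef(big["bmi"], big["hba1c"])[0, 1]
    return {
        "mean_event_fraction": float(np.mean(fracs)),
        "n_seeds": n_seeds,
        "bmi_hba1c_r2": float(r**2),
        "n_big": n_big,
    }


def null_rejection_rate(n_cohorts: int = 1000, n: int = 199, alpha: float = 0.05, seed: int = 0) -> float:
    """Type-I error of a univariate BMI Cox fit on null cohorts."""
    base = GeneratorConfig(n_patients=n, seed=0).null_effects()
    rej = 0
    n_run = 0
    for s in _seeds(seed, n_cohorts):
        cfg = GeneratorConfig(**{**_cfg_dict(base), "seed": s})
        df = generate_cohort(cfg)
        fit = CoxPH.from_dataframe(df, ["bmi"]).fit()
        if not fit.converged:
            continue
        n_run += 1
        if fit.pvalues[0] < alpha:
            rej += 1
    return rej / n_run


def _cfg_dict(cfg: GeneratorConfig) -> dict:
    return {f: getattr(cfg, f) for f in cfg.__dataclass_fields__}


def reference_table1_cohort():
    """Synthetic patient table reproducing the published marginal counts.

    Rebuilds a 199-admission cohort whose survival arms and categorical
    marginals match the published baseline table of the emulated study
    (113 survivors / 86 nonsurvivors; male 65/46; mechanical ventilation
    69/68; hemodialysis 15/30; vasopressor 39/64; known diabetes 26/24;
    HbA1c glucose-tolerance categories 51-40-22 / 41-23-22) and whose
    no-known-DM subgroup contains 51 prediabetes and 16 HbA1c-defined
    diabetes patients among 149.  The joint assignment of known-DM by
    HbA1c category within each arm is not published and is filled in
    synthetically (any fill-in consistent with the marginals gives the
    same table percentages).  Continuous fillers are arbitrary
    deterministic values; only count-based rows are meaningful.
    """
    import pandas as pd

    rows = []

    def arm(event, n, male, mv, hd, vaso, cats):
        # cats: list of (n, hba1c_value, known_dm) covering the arm
        recs = []
        for n_c, h, dm in cats:
            recs += [{"hba1c": h, "known_dm": dm}] * n_c
        assert len(recs) == n
        for i, r in enumerate(recs):
            rows.append(
                {
                    "event": event,
                    "male": 1 if i < male else 0,
                    "mech_vent": 1 if i < mv else 0,
                    "hemodialysis": 1 if i < hd else 0,
                    "vasopressor": 1 if i < vaso else 0,
                    "time": 1.0 + (i % 30),
                    "age": 40 + (i % 40),
                    "apache2": 10 + (i % 25),
                    "sofa": 2 + (i % 12),
                    "bmi": 20.0 + (i % 18),
                    "lactate": 5.0 + (i % 20),
                    "crp": 30.0 + (i % 150),
                    "glucose": 90.0 + (i % 120),
                    "hemoglobin": 8.0 + (i % 7),
                    **r,
                }
            )

    # survivors: HbA1c cats 51 normal / 40 pre / 22 DM; 26 known-DM
    arm(
        0, 113, 65, 69, 15, 39,
        [(46, 5.0, 0), (5, 5.0, 1), (33, 6.0, 0), (7, 6.0, 1), (8, 7.0, 0), (14, 7.0, 1)],
    )
    # nonsurvivors: 41 / 23 / 22; 24 known-DM
    arm(
        1, 86, 46, 68, 30, 64,
        [(36, 5.0, 0), (5, 5.0, 1), (18, 6.0, 0), (5, 6.0, 1), (8, 7.0, 0), (14, 7.0, 1)],
    )
    df = pd.DataFrame(rows)
    df.insert(0, "id", np.arange(1, len(df) + 1))
    return df
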