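"""Cutpoint scan: dichotomization, spline smoothing, bands, group model."""

import numpy as np
import pytest
from scipy import stats

from cutscan.datagen import GeneratorConfig, generate_cohort
from cutscan.exceptions import ConfigError, DegenerateCutError, ScanFailureError
from cutscan.scan import (
    CutpointScan,
    ScanPoint,
    ScanSpec,
    assign_groups,
    detect_threshold,
    dichotomize,
    group_cox,
    rcs_basis,
    smooth_scan,
)
from cutscan.studies import _seeds, bmi_scan_spec


def make_points(cutoffs, loghrs, se=0.1):
    return [
        ScanPoint(c, lh, se, 50, 50, 20, 20, True, True) for c, lh in zip(cutoffs, loghrs)
    ]


@pytest.mark.parametrize(
    "x,cutoff,direction,expected",
    [
        ([22, 25], 23, "risk-below", [1, 0]),
        ([9.2, 9.4], 9.3, "risk-above", [0, 1]),
        ([9.3, 9.2], 9.3, "risk-above", [1, 0]),  # boundary: >= cutoff
    ],
)
def test_dichotomize_conventions(x, cutoff, direction, expected):
    assert dichotomize(np.array(x), cutoff, direction).tolist() == expected


def test_dichotomize_degenerate_cut_signals():
    with pytest.raises(DegenerateCutError):
        dichotomize(np.array([25.0, 30.0]), 20.0, "risk-above")  # everyone >= 20


def test_bmi_grid_has_31_inclusive_cutoffs():
    spec = ScanSpec(covariate="bmi", grid_lo=20, grid_hi=35, step=0.5)
    grid = spec.grid()
    assert len(grid) == 31
    assert grid[0] == 20.0 and grid[-1] == 35.0


def test_spec_validation():
    with pytest.raises(ConfigError):
        ScanSpec(covariate="bmi", grid_lo=35, grid_hi=20)
    with pytest.raises(ConfigError):
        ScanSpec(covariate="bmi", grid_lo=20, grid_hi=21, step=0.5)  # only 3 points


def test_scan_determinism(default_cohort):
    spec = bmi_scan_spec()
    a = CutpointScan(default_cohort, spec).fit()
    b = CutpointScan(default_cohort, spec).fit()
    assert a.points_frame.equals(b.points_frame)
    assert np.array_equal(a.band.hr_fit, b.band.hr_fit)
    assert np.array_equal(a.band.lower, b.band.lower)


def test_direction_duality(default_cohort):
    """Flipping the direction complements the indicator; the group log-HR
    negates exactly while the adjusted fit is unchanged."""
    lo = ScanSpec(covariate="bmi", grid_lo=22, grid_hi=30, step=1.0,
                  direction="risk-below", adjust_for=["apache2"])
    hi = ScanSpec(covariate="bmi", grid_lo=22, grid_hi=30, step=1.0,
                  direction="risk-above", adjust_for=["apache2"])
    pa = CutpointScan(default_cohort, lo).run_scan()
    pb = CutpointScan(default_cohort, hi).run_scan()
    for a, b in zip(pa, pb):
        if a.usable and b.usable:
            assert a.loghr == pytest.approx(-b.loghr, abs=1e-6)
            assert a.se == pytest.approx(b.se, abs=1e-6)


def test_duplicated_cohort_same_loghr_smaller_se(default_cohort):
    """Doubling every record leaves the Breslow partial-likelihood maximizer
    unchanged (risk-set ratios are scale-free) but halves the information.
    Breslow ties are required: duplication creates ties, and Efron's
    correction is not exactly scale-invariant."""
    import pandas as pd

    spec = ScanSpec(covariate="bmi", grid_lo=22, grid_hi=30, step=1.0,
                    adjust_for=["apache2"])
    doubled = pd.concat([default_cohort, default_cohort], ignore_index=True)
    pa = CutpointScan(default_cohort, spec, ties="breslow").run_scan()
    pb = CutpointScan(doubled, spec, ties="breslow").run_scan()
    for a, b in zip(pa, pb):
        if a.usable:
            assert b.loghr == pytest.approx(a.loghr, abs=1e-6)
            assert b.se < a.se


def test_min_events_filter_excludes_sparse_cutoffs(default_cohort):
    spec = ScanSpec(covariate="hba1c", grid_lo=4.5, grid_hi=12.0, step=0.25,
                    direction="risk-above", adjust_for=["apache2"],
                    min_events_per_group=5)
    points = CutpointScan(default_cohort, spec).run_scan()
    sparse = [p for p in points if not p.usable]
    assert sparse, "extreme cutoffs should be excluded at n=199"
    for p in sparse:
        assert p.note != ""


def test_smooth_constant_zero_gives_unit_hr_and_symmetric_band():
    spec = ScanSpec(covariate="bmi", grid_lo=20, grid_hi=35, step=0.5)
    band = smooth_scan(make_points(spec.grid(), np.zeros(31)), spec)
    assert np.allclose(band.hr_fit, 1.0, atol=1e-10)
    assert np.allclose(band.lower * band.upper, 1.0, atol=1e-10)  # symmetric on log scale
    assert np.all(band.lower <= band.hr_fit) and np.all(band.hr_fit <= band.upper)


def test_smooth_reproduces_exact_line():
    """A natural cubic spline nests the linear function: exactly linear
    log-HRs are reproduced to numerical precision, including beyond knots."""
    spec = ScanSpec(covariate="bmi", grid_lo=20, grid_hi=35, step=0.5)
    grid = spec.grid()
    y = 0.05 * (grid - 27.0)
    band = smooth_scan(make_points(grid, y), spec)
    expected = np.exp(0.05 * (band.eval_grid - 27.0))
    assert np.allclose(band.hr_fit, expected, atol=1e-8)


def test_band_uses_bonferroni_quantile():
    """Bandwidth on the log scale equals z_{1-alpha/(2m)} / z_{1-alpha/2}
    times the pointwise-width band."""
    spec = ScanSpec(covariate="bmi", grid_lo=20, grid_hi=35, step=0.5, alpha=0.05)
    grid = spec.grid()
    band = smooth_scan(make_points(grid, np.zeros(31)), spec)
    assert band.m == 31
    z_b = stats.norm.ppf(1 - 0.05 / 62)
    width = np.log(band.upper) - np.log(band.lower)
    # recompute the naive se_fit from the WLS formula independently
    B = rcs_basis(grid, band.knots)
    cov = np.linalg.inv(B.T @ B) * 0.1**2
    Be = rcs_basis(band.eval_grid, band.knots)
    se = np.sqrt(np.einsum("ij,jk,ik->i", Be, cov, Be))
    assert np.allclose(width, 2 * z_b * se, atol=1e-10)


def test_smooth_requires_four_usable_points():
    spec = ScanSpec(covariate="bmi", grid_lo=20, grid_hi=35, step=0.5)
    pts = make_points(spec.grid()[:3], [0.1, 0.2, 0.3])
    with pytest.raises(ScanFailureError):
        smooth_scan(pts, spec)


def test_detect_threshold_calls():
    from cutscan.scan import SplineBand

    grid = np.linspace(4.5, 12.0, 201)
    hr = np.where(grid >= 9.3, 1.6, 1.05)
    band = SplineBand(grid, hr, hr * 0.9, hr * 1.1, m=31, knots=np.array([5, 7, 9, 11]))
    call = detect_threshold(band)
    assert not call.is_empty
    assert call.intervals[0][2] == "risk"
    assert call.headline == pytest.approx(9.3, abs=0.05)
    # a null band covering 1 everywhere yields an empty call
    null = SplineBand(grid, np.ones_like(grid), np.full_like(grid, 0.9),
                      np.full_like(grid, 1.1), m=31, knots=np.array([5, 7, 9, 11]))
    assert detect_threshold(null).is_empty
    assert detect_threshold(null).headline is None


def test_detect_threshold_protection_side():
    from cutscan.scan import SplineBand

    grid = np.linspace(20, 35, 200)
    hr = np.where(grid > 30, 0.7, 1.0)
    band = SplineBand(grid, hr, hr * 0.9, hr * 1.05, m=31, knots=np.array([21, 25, 29, 33]))
    call = detect_threshold(band)
    sides = {s for _, _, s in call.intervals}
    assert sides == {"protection"}
    assert call.headline is None


@pytest.mark.parametrize(
    "bmi,expected",
    [([18, 22, 30, 40], [1, 2, 3, 4]), ([23.95], [2]), ([24.0], [3]), ([20.0], [2]), ([35.0], [4])],
)
def test_group_assignment_lower_inclusive(bmi, expected):
    assert assign_groups(np.array(bmi), (20, 24, 35)).tolist() == expected


def test_group_cox_recovers_reference_contrasts(big_cohort):
    res = group_cox(big_cohort, "bmi", (20, 24, 35), ["apache2", "hba1c"])
    tab = res.summary()
    assert res.fit.converged
    assert len(tab) == 4
    # default truth is protective in BMI: upper strata have HR < 1 vs group 1
    assert tab.loc[tab.group == 4, "HR"].iloc[0] < 1.0


def test_group_cox_empty_stratum_named():
    cfg = GeneratorConfig(n_patients=120, seed=5)
    df = generate_cohort(cfg)
    with pytest.raises(ConfigError, match="stratum"):
        group_cox(df, "bmi", (20, 24, 80), ["apache2"])


def test_group_cox_null_pvalues_uniform():
    """Under an effect-free hazard the Wald p of a stratum contrast is
    uniform: KS test over 400 simulated cohorts at alpha 0.01."""
    base = GeneratorConfig(n_patients=400, seed=0).null_effects()
    cfg_fields = {f: getattr(base, f) for f in base.__dataclass_fields__}
    pvals = []
    for s in _seeds(77, 400):
        df = generate_cohort(GeneratorConfig(**{**cfg_fields, "seed": s}))
        try:
            res = group_cox(df, "bmi", (20, 24, 35), ["apache2"])
        except ConfigError:
            continue
        if res.fit.converged:
            j = res.fit.names.index("group2")
            pvals.append(res.fit.pvalues[j])
    assert len(pvals) > 300
    _, p = stats.kstest(pvals, "uniform")
    assert p > 0.01
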