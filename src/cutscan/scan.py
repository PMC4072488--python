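"""Dichotomization cutpoint scan of adjusted Cox hazard ratios.

The procedure at the heart of the package: slide a cutoff across a
continuous risk factor (BMI, HbA1c), refit an adjusted Cox model at each
cutoff with the dichotomized group indicator, smooth the resulting
log-hazard-ratio curve with a four-knot restricted cubic spline fitted by
inverse-variance-weighted least squares, and surround it with a
Bonferroni-corrected simultaneous confidence band.  Covariate ranges
where the band excludes HR = 1 are reported as threshold calls.

Usage follows the model/results idiom::

    spec = ScanSpec(covariate="bmi", grid_lo=20, grid_hi=35, step=0.5,
                    direction="risk-below", adjust_for=["apache2"])
    res = CutpointScan(cohort_df, spec).fit()
    res.points          # per-cutoff adjusted log-HRs (DataFrame)
    res.band            # SplineBand over a fine grid
    res.threshold_call  # ranges where the band excludes 1
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cox import CoxPH, CoxPHResults, SurvivalData
from .exceptions import (
    ConfigError,
    DegenerateCutError,
    DegenerateDesignError,
    ScanFailureError,
    SchemaError,
)

__all__ = [
    "ScanSpec",
    "ScanPoint",
    "SplineBand",
    "ThresholdCall",
    "CutpointScan",
    "CutpointScanResults",
    "dichotomize",
    "rcs_basis",
    "group_cox",
    "GroupCoxResults",
    "assign_groups",
]


@dataclass
class ScanSpec:
    """Configuration of one cutpoint scan.

    direction="risk-below" codes the indicator 1 for subjects *below* the
    cutoff (HR > 1 then means excess risk at low values; the BMI
    convention), "risk-above" codes 1 at/above the cutoff (the HbA1c
    convention).
    """

    covariate: str
    grid_lo: float
    grid_hi: float
    step: float = 0.5
    direction: str = "risk-below"
    adjust_for: list[str] = field(default_factory=list)
    min_events_per_group: int = 5
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.grid_lo >= self.grid_hi:
            raise ConfigError("grid_lo must be < grid_hi")
        if self.step <= 0:
            raise ConfigError("step must be > 0")
        if self.direction not in ("risk-below", "risk-above"):
            raise ConfigError(f"direction must be risk-below|risk-above, got {self.direction!r}")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.min_events_per_group < 0:
            raise ConfigError("min_events_per_group must be >= 0")
        if len(self.grid()) < 4:
            raise ConfigError("grid must contain at least 4 cutoffs (spline needs 4 knots)")

    def grid(self) -> np.ndarray:
        """Inclusive cutoff grid: 20..35 by 0.5 gives 31 points."""
        n = int(round((self.grid_hi - self.grid_lo) / self.step))
        g = self.grid_lo + self.step * np.arange(n + 1)
        return g[g <= self.grid_hi + 1e-9]


@dataclass
class ScanPoint:
    """One cutoff's dichotomized adjusted log-HR and bookkeeping."""

    cutoff: float
    loghr: float
    se: float
    n_low: int
    n_high: int
    events_low: int
    events_high: int
    converged: bool
    usable: bool
    note: str = ""

    @property
    def hr(self) -> float:
        return float(np.exp(self.loghr))


@dataclass
class SplineBand:
    """Smoothed HR curve with simultaneous Bonferroni band."""

    eval_grid: np.ndarray
    hr_fit: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    m: int  # number of usable cutoffs = Bonferroni multiplicity
    knots: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cutoff": self.eval_grid,
                "hr": self.hr_fit,
                "lower": self.lower,
                "upper": self.upper,
            }
        )


@dataclass
class ThresholdCall:
    """Covariate ranges where the simultaneous band excludes HR = 1.

    side="risk" marks ranges with lower band > 1 (the dichotomized group
    coded 1 has elevated hazard), side="protection" ranges with upper
    band < 1.  headline is the left boundary of the first risk range.
    """

    intervals: list[tuple[float, float, str]]
    headline: float | None

    @property
    def is_empty(self) -> bool:
        return not self.intervals

    def to_dict(self) -> dict:
        return {
            "intervals": [
                {"lo": float(a), "hi": float(b), "side": s} for a, b, s in self.intervals
            ],
            "headline": None if self.headline is None else float(self.headline),
        }


def dichotomize(x: np.ndarray, cutoff: float, direction: str) -> np.ndarray:
    """Group indicator for one cutoff.

    risk-below: 1 iff x < cutoff; risk-above: 1 iff x >= cutoff.  A cut
    that puts everyone in one group raises DegenerateCutError.
    """
    x = np.asarray(x, dtype=float)
    if direction == "risk-below":
        ind = (x < cutoff).astype(float)
    elif direction == "risk-above":
        ind = (x >= cutoff).astype(float)
    else:
        raise ConfigError(f"direction must be risk-below|risk-above, got {direction!r}")
    if ind.min() == ind.max():
        raise DegenerateCutError(
            f"cutoff {cutoff} puts all subjects on one side ({direction})"
        )
    return ind


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted (natural) cubic spline design matrix, Harrell form.

    Columns: intercept, x, and k-2 nonlinear terms; the fitted function is
    linear beyond the boundary knots.  Nonlinear terms are scaled by
    (t_k - t_1)^2 for conditioning.
    """
    x = np.asarray(x, dtype=float)
    t = np.sort(np.asarray(knots, dtype=float))
    k = t.size
    if k < 3 or np.unique(t).size != k:
        raise DegenerateDesignError("spline knots must be distinct and at least 3")
    scale = (t[-1] - t[0]) ** 2

    def pos3(u):
        return np.clip(u, 0, None) ** 3

    cols = [np.ones_like(x), x]
    for j in range(k - 2):
        c = (
            pos3(x - t[j])
            - pos3(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
            + pos3(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])
        )
        cols.append(c / scale)
    return np.column_stack(cols)


class CutpointScan:
    """Cutpoint-scan model over a cohort table.

    Parameters
    ----------
    df : DataFrame with at least ``time``, ``event``, the scanned
        covariate, and every adjustment covariate.
    spec : ScanSpec
    ties : Cox tie correction used at every cutoff.
    """

    def __init__(self, df: pd.DataFrame, spec: ScanSpec, ties: str = "efron"):
        self.spec = spec
        self.ties = ties
        cols = [spec.covariate, *spec.adjust_for]
        self.data = SurvivalData.from_dataframe(df, cols)
        self._x = self.data.X[:, 0]
        self._adjust = self.data.X[:, 1:]

    def _fit_cutoff(self, cutoff: float) -> tuple[ScanPoint, np.ndarray | None]:
        try:
            ind = dichotomize(self._x, cutoff, self.spec.direction)
        except DegenerateCutError:
            return (
                ScanPoint(cutoff, np.nan, np.nan, 0, 0, 0, 0, False, False, "degenerate cut"),
                None,
            )
        ev = self.data.event
        e1, e0 = int(ev[ind == 1].sum()), int(ev[ind == 0].sum())
        n1, n0 = int(ind.sum()), int((1 - ind).sum())
        if self.spec.direction == "risk-below":
            n_low, n_high, ev_low, ev_high = n1, n0, e1, e0
        else:
            n_low, n_high, ev_low, ev_high = n0, n1, e0, e1
        if min(e1, e0) < self.spec.min_events_per_group:
            return (
                ScanPoint(
                    cutoff, np.nan, np.nan, n_low, n_high, ev_low, ev_high, False, False,
                    f"fewer than {self.spec.min_events_per_group} events in one group",
                ),
                None,
            )
        X = np.column_stack([ind, self._adjust])
        try:
            fit = CoxPH(
                self.data.time, self.data.event, X,
                names=["group", *self.spec.adjust_for], ties=self.ties,
            ).fit()
        except DegenerateDesignError as exc:
            return (
                ScanPoint(
                    cutoff, np.nan, np.nan, n_low, n_high, ev_low, ev_high, False, False, str(exc)
                ),
                None,
            )
        point = ScanPoint(
            cutoff,
            float(fit.params[0]),
            float(fit.bse[0]),
            n_low, n_high, ev_low, ev_high,
            fit.converged,
            fit.converged,
            "" if fit.converged else fit.message,
        )
        dfb = fit.dfbeta()[:, 0] if fit.converged else None
        return point, dfb

    def run_scan(self) -> list[ScanPoint]:
        """One adjusted Cox fit per grid cutoff; deterministic."""
        return [self._fit_cutoff(c)[0] for c in self.spec.grid()]

    def fit(self, n_eval: int = 201) -> "CutpointScanResults":
        fitted = [self._fit_cutoff(c) for c in self.spec.grid()]
        points = [p for p, _ in fitted]
        dfbetas = {p.cutoff: d for p, d in fitted if d is not None}
        band = smooth_scan(points, self.spec, n_eval=n_eval, dfbetas=dfbetas)
        return CutpointScanResults(model=self, points=points, band=band)


def smooth_scan(
    points: list[ScanPoint],
    spec: ScanSpec,
    n_eval: int = 201,
    dfbetas: dict[float, np.ndarray] | None = None,
) -> SplineBand:
    """Four-knot restricted-cubic-spline smoothing of the scanned log-HRs.

    Weighted least squares with weights 1/se^2; knots at the 5/35/65/95th
    percentiles of the usable cutoffs; the simultaneous band uses the
    normal quantile for 1 - alpha/(2 m), m = number of usable cutoffs.

    The scan points all derive from the same cohort and are strongly
    positively correlated, so the naive WLS covariance (which treats
    them as independent) badly understates the uncertainty of the
    fitted curve.  When per-cutoff dfbeta vectors are supplied the
    smoother instead propagates the infinitesimal-jackknife covariance
    of the scan points through the WLS projection (a sandwich), which
    restores conservative simultaneous coverage; without them it falls
    back to the naive covariance.
    """
    usable = [p for p in points if p.usable and np.isfinite(p.loghr) and np.isfinite(p.se)]
    m = len(usable)
    if m < 4:
        raise ScanFailureError(
            f"only {m} usable cutpoints (need >= 4): "
            + "; ".join(f"{p.cutoff}: {p.note}" for p in points if not p.usable)
        )
    if n_eval < 200:
        n_eval = 200
    c = np.array([p.cutoff for p in usable])
    y = np.array([p.loghr for p in usable])
    w = np.array([1.0 / p.se**2 for p in usable])
    knots = np.percentile(c, [5, 35, 65, 95])
    if np.unique(knots).size < 4:
        raise DegenerateDesignError("coincident spline knots")
    B = rcs_basis(c, knots)
    sw = np.sqrt(w)
    BW = B * sw[:, None]
    try:
        coef, *_ = np.linalg.lstsq(BW, y * sw, rcond=None)
        bread = np.linalg.inv(B.T @ (w[:, None] * B))
    except np.linalg.LinAlgError as exc:
        raise DegenerateDesignError(f"singular spline design: {exc}") from exc
    if dfbetas is not None:
        if not all(p.cutoff in dfbetas for p in usable):
            raise ScanFailureError("dfbetas missing for some usable cutoffs")
        D = np.stack([dfbetas[p.cutoff] for p in usable])  # m x n subjects
        scan_cov = D @ D.T
        A = bread @ (B.T * w)  # 4 x m projection y -> coef
        cov = A @ scan_cov @ A.T
    else:
        cov = bread
    grid = np.linspace(spec.grid_lo, spec.grid_hi, n_eval)
    Be = rcs_basis(grid, knots)
    fit = Be @ coef
    se_fit = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Be, cov, Be), 0.0))
    z = stats.norm.ppf(1 - spec.alpha / (2 * m))
    return SplineBand(
        eval_grid=grid,
        hr_fit=np.exp(fit),
        lower=np.exp(fit - z * se_fit),
        upper=np.exp(fit + z * se_fit),
        m=m,
        knots=knots,
    )


def detect_threshold(band: SplineBand) -> ThresholdCall:
    """Maximal grid sub-intervals where the band excludes HR = 1."""
    risk = band.lower > 1.0
    prot = band.upper < 1.0
    intervals: list[tuple[float, float, str]] = []
    for mask, side in ((risk, "risk"), (prot, "protection")):
        padded = np.r_[False, mask, False]
        starts = np.nonzero(padded[1:] & ~padded[:-1])[0]
        ends = np.nonzero(~padded[1:] & padded[:-1])[0] - 1
        for a, b in zip(starts, ends):
            intervals.append((float(band.eval_grid[a]), float(band.eval_grid[b]), side))
    intervals.sort(key=lambda iv: iv[0])
    headline = next((iv[0] for iv in intervals if iv[2] == "risk"), None)
    return ThresholdCall(intervals=intervals, headline=headline)


@dataclass
class CutpointScanResults:
    """Scan output: per-cutoff fits, smoothed band, threshold calls."""

    model: CutpointScan
    points: list[ScanPoint]
    band: SplineBand

    @property
    def spec(self) -> ScanSpec:
        return self.model.spec

    @property
    def points_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cutoff": p.cutoff,
                    "loghr": p.loghr,
                    "se": p.se,
                    "hr": p.hr,
                    "n_low": p.n_low,
                    "n_high": p.n_high,
                    "events_low": p.events_low,
                    "events_high": p.events_high,
                    "converged": p.converged,
                    "usable": p.usable,
                    "note": p.note,
                }
                for p in self.points
            ]
        )

    @property
    def threshold_call(self) -> ThresholdCall:
        return detect_threshold(self.band)

    def summary(self) -> str:
        call = self.threshold_call
        lines = [
            f"Cutpoint scan of '{self.spec.covariate}' "
            f"({self.spec.grid_lo}-{self.spec.grid_hi} step {self.spec.step}, "
            f"{self.spec.direction}, adjusted for {self.spec.adjust_for or 'nothing'})",
            f"  usable cutoffs: {self.band.m} of {len(self.points)} "
            f"(Bonferroni m = {self.band.m}, alpha = {self.spec.alpha})",
            f"  spline knots: {np.round(self.band.knots, 3).tolist()}",
        ]
        if call.is_empty:
            lines.append("  band covers HR = 1 everywhere: no threshold detected")
        else:
            for a, b, side in call.intervals:
                lines.append(f"  band excludes 1 on [{a:.3g}, {b:.3g}] ({side})")
            if call.headline is not None:
                lines.append(f"  headline threshold: {call.headline:.3g}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Stratified group model (BMI strata vs reference)
# ---------------------------------------------------------------------------


def assign_groups(x: np.ndarray, bounds: tuple[float, ...]) -> np.ndarray:
    """1-based stratum labels from lower-inclusive bounds.

    bounds (20, 24, 35): group 1 = x < 20, group 2 = [20, 24),
    group 3 = [24, 35), group 4 = x >= 35.
    """
    bounds = tuple(bounds)
    if list(bounds) != sorted(bounds):
        raise ConfigError("group bounds must be increasing")
    return np.searchsorted(np.asarray(bounds, float), np.asarray(x, float), side="right") + 1


@dataclass
class GroupCoxResults:
    """Per-stratum hazard ratios vs the first (reference) stratum."""

    fit: CoxPHResults
    bounds: tuple[float, ...]
    group_labels: np.ndarray
    group_sizes: list[int]
    group_events: list[int]

    @property
    def n_groups(self) -> int:
        return len(self.bounds) + 1

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "group": 1,
                "HR": 1.0,
                "lower": np.nan,
                "upper": np.nan,
                "p": np.nan,
                "n": self.group_sizes[0],
                "events": self.group_events[0],
            }
        ]
        for g in range(2, self.n_groups + 1):
            hr, lo, hi = self.fit.wald_interval(f"group{g}")
            j = self.fit.names.index(f"group{g}")
            rows.append(
                {
                    "group": g,
                    "HR": hr,
                    "lower": lo,
                    "upper": hi,
                    "p": self.fit.pvalues[j],
                    "n": self.group_sizes[g - 1],
                    "events": self.group_events[g - 1],
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "bounds": list(self.bounds),
            "groups": self.summary().to_dict(orient="records"),
            "fit": self.fit.to_dict(),
        }


def group_cox(
    df: pd.DataFrame,
    covariate: str = "bmi",
    bounds: tuple[float, ...] = (20.0, 24.0, 35.0),
    adjust_for: list[str] = ("apache2", "hba1c"),
    ties: str = "efron",
) -> GroupCoxResults:
    """Cox model with k-1 stratum indicators (reference = first stratum).

    Every stratum must be nonempty with at least one event.
    """
    adjust_for = list(adjust_for)
    data = SurvivalData.from_dataframe(df, [covariate, *adjust_for])
    labels = assign_groups(data.X[:, 0], bounds)
    k = len(bounds) + 1
    sizes, events = [], []
    for g in range(1, k + 1):
        in_g = labels == g
        sizes.append(int(in_g.sum()))
        events.append(int(data.event[in_g].sum()))
        if sizes[-1] == 0:
            raise ConfigError(f"stratum {g} is empty")
        if events[-1] == 0:
            raise ConfigError(f"stratum {g} has no events")
    dummies = np.column_stack([(labels == g).astype(float) for g in range(2, k + 1)])
    X = np.column_stack([dummies, data.X[:, 1:]])
    names = [f"group{g}" for g in range(2, k + 1)] + adjust_for
    fit = CoxPH(data.time, data.event, X, names=names, ties=ties).fit()
    return GroupCoxResults(
        fit=fit, bounds=tuple(bounds), group_labels=labels,
        group_sizes=sizes, group_events=events,
    )
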