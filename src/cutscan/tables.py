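"""Descriptive cohort statistics: baseline table, classifications, correlations.

Covers the standard reporting of an ICU cohort study: survivor vs
nonsurvivor comparisons (pooled-variance t, Mann-Whitney U, Pearson
chi-square without continuity correction), ADA glucose-tolerance
categories from HbA1c, WHO BMI categories, and squared correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError, SchemaError

__all__ = [
    "classify_glucose",
    "classify_bmi",
    "compare_groups",
    "correlation_r2",
    "build_table1",
    "Table1Summary",
]

GLUCOSE_CATEGORIES = ["normal", "prediabetes", "diabetes"]
BMI_CATEGORIES = ["underweight", "normal", "overweight", "obesity I-II", "extreme obesity"]

#: Table-layout map: how each cohort variable is summarized and tested.
#: mean +/- sd with pooled-variance t for approximately normal variables,
#: median (IQR) with Mann-Whitney U for skewed ones, n (%) with Pearson
#: chi-square for flags.
TABLE1_VARIABLES: list[tuple[str, str]] = [
    ("age", "continuous-normal"),
    ("male", "categorical"),
    ("apache2", "continuous-normal"),
    ("sofa", "continuous-skewed"),
    ("bmi", "continuous-normal"),
    ("known_dm", "categorical"),
    ("hba1c", "continuous-skewed"),
    ("glucose", "continuous-skewed"),
    ("lactate", "continuous-skewed"),
    ("crp", "continuous-skewed"),
    ("hemoglobin", "continuous-normal"),
    ("mech_vent", "categorical"),
    ("hemodialysis", "categorical"),
    ("vasopressor", "categorical"),
]


def classify_glucose(hba1c, known_dm=False):
    """ADA glucose-tolerance category from HbA1c (%, NGSP).

    normal < 5.7, prediabetes [5.7, 6.5), diabetes >= 6.5; a known
    history of diabetes overrides the HbA1c value.  Vectorized.
    """
    h = np.asarray(hba1c, dtype=float)
    if np.any(h <= 0) or not np.all(np.isfinite(h)):
        raise ConfigError("hba1c must be finite and > 0")
    dm = np.asarray(known_dm, dtype=bool)
    cat = np.where(dm | (h >= 6.5), "diabetes", np.where(h >= 5.7, "prediabetes", "normal"))
    return cat.item() if np.ndim(hba1c) == 0 and np.ndim(known_dm) == 0 else cat


def classify_bmi(bmi):
    """WHO body-size category, lower-inclusive bins at 18.5 / 25 / 30 / 40."""
    b = np.asarray(bmi, dtype=float)
    if np.any(b <= 0) or not np.all(np.isfinite(b)):
        raise ConfigError("bmi must be finite and > 0")
    idx = np.searchsorted([18.5, 25.0, 30.0, 40.0], b, side="right")
    cat = np.asarray(BMI_CATEGORIES, dtype=object)[idx]
    return cat if np.ndim(bmi) else str(cat)


def compare_groups(values, group, kind: str):
    """Two-group comparison: (summary_group0, summary_group1, statistic, p).

    kind="continuous-normal": mean +/- sd summaries, pooled-variance
    Student t.  kind="continuous-skewed": median (IQR), Mann-Whitney U
    (normal approximation with tie correction).  kind="categorical":
    n (%) of the positive level, Pearson chi-square without continuity
    correction on the full contingency table.
    """
    values = np.asarray(values)
    group = np.asarray(group).astype(int)
    g0, g1 = values[group == 0], values[group == 1]
    if g0.size == 0 or g1.size == 0:
        raise ConfigError("both groups must be nonempty")
    if kind == "continuous-normal":
        if np.std(g0) == 0 and np.std(g1) == 0:
            raise ConfigError("zero variance in both groups for t-test")
        stat, p = stats.ttest_ind(g0.astype(float), g1.astype(float), equal_var=True)
        s0 = f"{np.mean(g0):.1f} ± {np.std(g0, ddof=1):.1f}"
        s1 = f"{np.mean(g1):.1f} ± {np.std(g1, ddof=1):.1f}"
        return s0, s1, float(stat), float(p)
    if kind == "continuous-skewed":
        stat, p = stats.mannwhitneyu(
            g0.astype(float), g1.astype(float), alternative="two-sided", method="asymptotic"
        )
        q0 = np.percentile(g0, [50, 25, 75])
        q1 = np.percentile(g1, [50, 25, 75])
        s0 = f"{q0[0]:.1f} ({q0[1]:.1f}-{q0[2]:.1f})"
        s1 = f"{q1[0]:.1f} ({q1[1]:.1f}-{q1[2]:.1f})"
        return s0, s1, float(stat), float(p)
    if kind == "categorical":
        tab = pd.crosstab(group, values)
        if tab.shape[1] < 2:
            # degenerate: a single observed level; report and skip the test
            lev = tab.columns[0]
            pos = 1 if lev in (1, True) else 0
            s0 = f"{pos * g0.size} ({100.0 * pos:.1f})"
            s1 = f"{pos * g1.size} ({100.0 * pos:.1f})"
            return s0, s1, np.nan, np.nan
        stat, p, _, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
        n0_pos = int(np.sum(np.asarray(g0) == 1))
        n1_pos = int(np.sum(np.asarray(g1) == 1))
        s0 = f"{n0_pos} ({100.0 * n0_pos / g0.size:.1f})"
        s1 = f"{n1_pos} ({100.0 * n1_pos / g1.size:.1f})"
        return s0, s1, float(stat), float(p)
    raise ConfigError(f"unknown variable kind {kind!r}")


def correlation_r2(x, y, method: str = "pearson") -> tuple[float, float]:
    """Squared Pearson or Spearman correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ConfigError("correlation needs matched samples, n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ConfigError("constant input to correlation")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ConfigError(f"method must be pearson|spearman, got {method!r}")
    return float(r**2), float(p)


@dataclass
class Table1Summary:
    """Survivor vs nonsurvivor baseline table."""

    table: pd.DataFrame
    n: int
    n_survivors: int
    n_nonsurvivors: int

    @property
    def mortality_pct(self) -> float:
        return round(100.0 * self.n_nonsurvivors / self.n, 1)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_text(self) -> str:
        head = (
            f"n = {self.n} ({self.n_survivors} survivors, "
            f"{self.n_nonsurvivors} nonsurvivors; mortality {self.mortality_pct}%)\n"
        )
        return head + self.table.to_string(index=False)


REQUIRED_COLUMNS = [
    "time", "event", "age", "male", "apache2", "sofa", "bmi", "hba1c", "known_dm",
    "mech_vent", "hemodialysis", "vasopressor", "lactate", "crp", "glucose", "hemoglobin",
]


def _check_schema(df: pd.DataFrame) -> None:
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"column '{col}' missing from cohort table")


def build_table1(cohort: pd.DataFrame) -> Table1Summary:
    """Baseline characteristics by survival, with the appropriate tests.

    The glucose-tolerance rows classify by HbA1c alone (the descriptive
    convention of the source table); the known-DM override belongs to the
    diagnostic classification, available via classify_glucose.
    Percentages are within-group and rounded to one decimal.
    """
    _check_schema(cohort)
    grp = cohort["event"].to_numpy(int)  # 1 = nonsurvivor
    rows = []
    for var, kind in TABLE1_VARIABLES:
        vals = cohort[var].to_numpy()
        try:
            s0, s1, stat, p = compare_groups(vals, grp, kind)
        except ConfigError as exc:
            s0 = s1 = "-"
            stat, p = np.nan, np.nan
            rows.append(
                {"variable": var, "kind": kind, "survivors": s0, "nonsurvivors": s1,
                 "statistic": stat, "p": p, "note": str(exc)}
            )
            continue
        rows.append(
            {"variable": var, "kind": kind, "survivors": s0, "nonsurvivors": s1,
             "statistic": stat, "p": p, "note": ""}
        )
    # glucose tolerance block: one omnibus chi-square, one row per category
    gcat = classify_glucose(cohort["hba1c"].to_numpy(), False)
    tab = pd.crosstab(grp, pd.Categorical(gcat, categories=GLUCOSE_CATEGORIES))
    if tab.shape[1] >= 2 and (tab.sum(axis=0) > 0).sum() >= 2:
        nz = tab.loc[:, tab.sum(axis=0) > 0]
        gstat, gp, _, _ = stats.chi2_contingency(nz.to_numpy(), correction=False)
    else:
        gstat, gp = np.nan, np.nan
    for i, cat in enumerate(GLUCOSE_CATEGORIES):
        c0 = int(tab.loc[0, cat]) if cat in tab.columns else 0
        c1 = int(tab.loc[1, cat]) if cat in tab.columns else 0
        n0, n1 = (grp == 0).sum(), (grp == 1).sum()
        rows.append(
            {
                "variable": f"glucose tolerance: {cat}",
                "kind": "categorical",
                "survivors": f"{c0} ({100.0 * c0 / n0:.1f})",
                "nonsurvivors": f"{c1} ({100.0 * c1 / n1:.1f})",
                "statistic": gstat if i == 0 else np.nan,
                "p": gp if i == 0 else np.nan,
                "note": "omnibus test on first row" if i == 0 else "",
            }
        )
    table = pd.DataFrame(rows)
    return Table1Summary(
        table=table,
        n=len(cohort),
        n_survivors=int((grp == 0).sum()),
        n_nonsurvivors=int((grp == 1).sum()),
    )


def glucose_breakdown(cohort: pd.DataFrame) -> dict:
    """Unrecognized dysglycemia among patients without known diabetes.

    Returns counts and within-subgroup percentages (one decimal) of
    prediabetes and HbA1c-defined diabetes among the no-known-DM
    patients, plus the no-known-DM share of the whole cohort.
    """
    _check_schema(cohort)
    no_dm = cohort.loc[~cohort["known_dm"].astype(bool)]
    n_no = len(no_dm)
    cat = classify_glucose(no_dm["hba1c"].to_numpy(), False)
    n_pre = int((cat == "prediabetes").sum())
    n_dm = int((cat == "diabetes").sum())
    return {
        "n": len(cohort),
        "n_no_known_dm": n_no,
        "no_known_dm_pct": round(100.0 * n_no / len(cohort), 1),
        "n_prediabetes": n_pre,
        "prediabetes_pct": round(100.0 * n_pre / n_no, 1) if n_no else np.nan,
        "n_unrecognized_dm": n_dm,
        "unrecognized_dm_pct": round(100.0 * n_dm / n_no, 1) if n_no else np.nan,
    }
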