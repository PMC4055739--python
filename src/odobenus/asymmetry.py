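"""Bilateral asymmetry: %DA, %AA, side regressions, and regional comparisons.

Directional asymmetry (%DA) is the signed right-minus-left difference as a
percentage of the bilateral mean; absolute asymmetry (%AA) is its unsigned
counterpart, so on every specimen %AA = |%DA|.  Whether a measure is
asymmetric at all is screened by regressing right on left and asking whether
the slope's standard-error band covers 1.  Regional differences in mean
asymmetry are tested with two-sample t-tests under a Bonferroni correction
for the family of bilateral measures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from odobenus.io import BILATERAL_CODES, DataError, MorphoDataset


@dataclass
class SideRegression:
    measure_code: str
    n_pairs: int
    slope: float
    slope_se: float
    intercept: float
    asymmetric: bool


@dataclass
class AsymmetryRow:
    measure_code: str
    region: str
    n: int
    mean_pct_da: float
    mean_pct_aa: float
    pct_da_values: list[float]
    pct_aa_values: list[float]


@dataclass
class AsymmetryComparison:
    measure_code: str
    statistic: float
    p_value: float
    significant_bonferroni: bool
    m_tests: int


def percent_da(right: float, left: float) -> float:
    """Signed directional asymmetry: (R - L) / mean(R, L) x 100."""
    if right <= 0 or left <= 0:
        raise DataError("percent_da requires positive measurements")
    return (right - left) / ((right + left) / 2.0) * 100.0


def percent_aa(right: float, left: float) -> float:
    """Absolute asymmetry: |R - L| / mean(R, L) x 100 (side-symmetric)."""
    if right <= 0 or left <= 0:
        raise DataError("percent_aa requires positive measurements")
    return abs(right - left) / ((right + left) / 2.0) * 100.0


def _paired_values(ds: MorphoDataset, measure_code: str) -> tuple[np.ndarray, np.ndarray]:
    lefts, rights = [], []
    for s in ds:
        l = s.get(measure_code, "L")
        r = s.get(measure_code, "R")
        if l is not None and r is not None:
            lefts.append(l)
            rights.append(r)
    return np.asarray(lefts, dtype=float), np.asarray(rights, dtype=float)


def regress_sides(
    ds: MorphoDataset, measure_code: str, se_multiplier: float = 1.0
) -> SideRegression:
    """OLS of right side on left; asymmetric if the slope's ±k·SE band excludes 1.

    ``se_multiplier`` is k (default 1, i.e. the raw standard error band).
    Requires at least 3 specimens with both sides and non-degenerate left values.
    """
    if measure_code not in BILATERAL_CODES:
        raise DataError(f"{measure_code} is not a bilateral measure")
    left, right = _paired_values(ds, measure_code)
    n = len(left)
    if n < 3:
        raise DataError(f"{measure_code}: need >= 3 complete pairs, have {n}")
    if np.ptp(left) == 0:
        raise DataError(f"{measure_code}: zero variance in left side")
    # closed-form OLS; slope SE is 0 (not nan) on exactly collinear data
    lc = left - left.mean()
    slope = float(lc @ (right - right.mean()) / (lc @ lc))
    intercept = float(right.mean() - slope * left.mean())
    resid = right - (intercept + slope * left)
    rss = float(resid @ resid)
    se = float(np.sqrt(max(rss, 0.0) / (n - 2) / (lc @ lc)))
    asymmetric = abs(slope - 1.0) > se_multiplier * se
    return SideRegression(measure_code, n, slope, se, intercept, asymmetric)


def select_side(ds: MorphoDataset, measure_code: str) -> str:
    """The side with more non-missing values; ties resolve to left."""
    if measure_code not in BILATERAL_CODES:
        raise DataError(f"{measure_code} is not a bilateral measure")
    n_l = sum(1 for s in ds if s.get(measure_code, "L") is not None)
    n_r = sum(1 for s in ds if s.get(measure_code, "R") is not None)
    if n_l == 0 and n_r == 0:
        raise DataError(f"{measure_code}: no data on either side")
    return "L" if n_l >= n_r else "R"


def asymmetry_table(
    ds: MorphoDataset, measures: list[str] | None = None
) -> list[AsymmetryRow]:
    """Per region x measure mean %DA and %AA over specimens with both sides.

    Region/measure combinations with no complete pair are omitted rather
    than fabricated.
    """
    measures = list(measures) if measures is not None else list(BILATERAL_CODES)
    rows: list[AsymmetryRow] = []
    for code in measures:
        if code not in BILATERAL_CODES:
            raise DataError(f"{code} is not a bilateral measure")
        for region in ds.regions:
            sub = ds.subset(region)
            left, right = _paired_values(sub, code)
            if len(left) == 0:
                continue
            da = [percent_da(r, l) for r, l in zip(right, left)]
            aa = [percent_aa(r, l) for r, l in zip(right, left)]
            rows.append(
                AsymmetryRow(
                    measure_code=code,
                    region=region,
                    n=len(da),
                    mean_pct_da=float(np.mean(da)),
                    mean_pct_aa=float(np.mean(aa)),
                    pct_da_values=da,
                    pct_aa_values=aa,
                )
            )
    return rows


def compare_asymmetry(
    values_a: list[float],
    values_b: list[float],
    *,
    measure_code: str = "",
    alpha: float = 0.05,
    m_tests: int = 1,
    welch: bool = False,
) -> AsymmetryComparison:
    """Two-sample t-test of per-specimen asymmetry between two regions.

    Pooled-variance Student's t by default; ``welch=True`` drops the
    equal-variance assumption.  Significance applies a Bonferroni threshold
    alpha / m_tests.  Two identical samples return t = 0, p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DataError("need >= 2 values per group")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t, p = np.inf * np.sign(a.mean() - b.mean()), 0.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
        t, p = float(t), float(p)
    return AsymmetryComparison(
        measure_code=measure_code,
        statistic=t,
        p_value=p,
        significant_bonferroni=p < alpha / m_tests,
        m_tests=m_tests,
    )


def bonferroni_flags(
    p_values: list[float], alpha: float = 0.05, m: int | None = None
) -> tuple[list[bool], int]:
    """Flag p_i < alpha / m; returns the flags and how many are True.

    ``m`` defaults to the number of p-values but may be larger when the
    family of tests exceeds the values supplied.
    """
    if m is None:
        m = len(p_values)
    if m < len(p_values):
        raise DataError("m must be at least the number of p-values")
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise DataError(f"p-value {p} outside [0, 1]")
    flags = [p < alpha / m for p in p_values]
    return flags, sum(flags)
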