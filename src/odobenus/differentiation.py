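"""Size standardization, univariate group tests, and DAPC with an isolation metric.

Raw skeletal measures confound region with age and sex, so every comparison
measure is first divided by a within-specimen reference that tracks age and
sex (cranial/mastoid width CW for skull and tusk measures, mandible width MW
for mandible measures), giving dimensionless ratios.  Each ratio is compared
between two regions with a test chosen from the data: a Welch two-sample
t-test when both groups pass Shapiro-Wilk normality and an F variance-ratio
test, otherwise a Wilcoxon rank-sum test.  Multivariately, complete cases
are decomposed by PCA and the component scores fed to a canonical
discriminant analysis (DAPC); group separation is summarised by whether the
groups' convex hulls on the first two discriminant axes intersect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from shapely.geometry import MultiPoint

from odobenus.asymmetry import select_side
from odobenus.io import (
    BILATERAL_CODES,
    MANDIBLE_CODES,
    SKULL_CODES,
    TUSK_CODES,
    DataError,
    MorphoDataset,
)

#: analysis blocks (standardizers CW and MW are never comparison measures)
BLOCKS = {
    "skull": tuple(SKULL_CODES),
    "tusk": tuple(TUSK_CODES),
    "mandible": tuple(MANDIBLE_CODES),
}


@dataclass
class StandardizedMatrix:
    """Specimens x dimensionless ratios, with region labels; NaN = missing."""

    data: pd.DataFrame  # index: specimen_id, columns: measure codes
    regions: pd.Series  # index: specimen_id

    def block(self, name: str) -> "StandardizedMatrix":
        codes = [c for c in BLOCKS[name] if c in self.data.columns]
        return StandardizedMatrix(self.data[codes], self.regions)


@dataclass
class UnivariateComparison:
    measure_code: str
    n_a: int
    n_b: int
    normality_p: tuple[float, float]
    variance_p: float
    chosen_test: str  # "welch_t" | "wilcoxon" | "untestable"
    statistic: float
    p_value: float
    significant: bool


@dataclass
class PCAResult:
    column_names: list[str]
    means: np.ndarray
    scales: np.ndarray  # 1s under covariance scaling
    loadings: np.ndarray  # columns are component loading vectors
    eigenvalues: np.ndarray
    proportions: np.ndarray
    scores: pd.DataFrame  # index: specimen_id of complete cases
    scaling: str


@dataclass
class DFAResult:
    eigenvalues: np.ndarray
    coefficients: np.ndarray  # columns are discriminant axes
    scores: pd.DataFrame  # all projected specimens
    groups: pd.Series
    centroids: pd.DataFrame  # groups used in scatter estimation
    n_components_used: int
    isolation: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# standardization


def rank_standardizers(
    ds: MorphoDataset, candidates: list[str]
) -> list[tuple[str, float, int]]:
    """Rank candidate reference measures by fit of measure ~ age + sex.

    Uses only specimens with known age and sex.  Returns (code, R^2, n)
    sorted by decreasing R^2; candidates with fewer than 3 usable specimens
    get R^2 = nan and sort last.
    """
    results: list[tuple[str, float, int]] = []
    for code in candidates:
        triples = [
            (s.get(code, "L" if code in BILATERAL_CODES else None), s.age_years, s.sex)
            for s in ds
            if s.age_years is not None and s.sex in ("M", "F")
        ]
        triples = [(v, a, sx) for v, a, sx in triples if v is not None]
        n = len(triples)
        if n < 3:
            results.append((code, float("nan"), n))
            continue
        y = np.array([v for v, _, _ in triples], dtype=float)
        X = np.column_stack(
            [
                np.ones(n),
                [a for _, a, _ in triples],
                [1.0 if sx == "M" else 0.0 for _, _, sx in triples],
            ]
        )
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        tss = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 if tss == 0 else 1.0 - float(resid @ resid) / tss
        # guard tiny negative round-off on perfect fits
        results.append((code, min(max(r2, 0.0), 1.0), n))
    if all(np.isnan(r) for _, r, _ in results):
        raise DataError("no eligible specimens (need known age and sex)")
    results.sort(key=lambda t: (np.isnan(t[1]), -(t[1] if not np.isnan(t[1]) else 0.0)))
    return results


def standardize(
    ds: MorphoDataset, skull_std: str = "CW", mandible_std: str = "MW"
) -> StandardizedMatrix:
    """Divide each comparison measure by its specimen's reference measure.

    Skull and tusk measures are divided by ``skull_std``, mandible measures
    by ``mandible_std``.  Bilateral measures contribute the side selected by
    :func:`odobenus.asymmetry.select_side` over the whole dataset.  A
    specimen lacking a reference has NaN for that block's ratios.
    """
    sides: dict[str, str] = {}
    for code in BILATERAL_CODES:
        try:
            sides[code] = select_side(ds, code)
        except DataError:
            sides[code] = "L"
    columns = [c for c in SKULL_CODES + TUSK_CODES + MANDIBLE_CODES
               if c not in (skull_std, mandible_std)]
    rows, ids, regions = [], [], []
    for s in ds:
        cw = s.get(skull_std)
        mw = s.get(mandible_std)
        for std_val, std_code in ((cw, skull_std), (mw, mandible_std)):
            if std_val is not None and std_val <= 0:
                raise DataError(f"{s.specimen_id}: non-positive standardizer {std_code}")
        row = {}
        for code in columns:
            side = sides.get(code) if code in BILATERAL_CODES else None
            value = s.get(code, side)
            std = mw if code in MANDIBLE_CODES else cw
            row[code] = float("nan") if value is None or std is None else value / std
        rows.append(row)
        ids.append(s.specimen_id)
        regions.append(s.region)
    data = pd.DataFrame(rows, index=ids, columns=columns)
    return StandardizedMatrix(data, pd.Series(regions, index=ids, name="region"))


# ---------------------------------------------------------------------------
# univariate comparisons


def _two_sided_f_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided variance-ratio (Fisher's F) test p-value."""
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        return 1.0
    if vb == 0 or va == 0:
        return 0.0
    f = va / vb
    dfa_, dfb = len(a) - 1, len(b) - 1
    p = 2.0 * min(stats.f.cdf(f, dfa_, dfb), stats.f.sf(f, dfa_, dfb))
    return float(min(p, 1.0))


def compare_two_samples(
    a: np.ndarray, b: np.ndarray, alpha: float = 0.05
) -> tuple[tuple[float, float], float, str, float, float]:
    """Test-selection core: returns (normality_p, variance_p, test, stat, p).

    Welch t when both samples look normal (Shapiro-Wilk) with equal
    variances (F test) at level ``alpha``; Wilcoxon rank-sum otherwise.
    """
    def _shapiro_p(x: np.ndarray) -> float:
        if np.ptp(x) == 0:
            return 0.0  # degenerate: treat as non-normal
        return float(stats.shapiro(x).pvalue)

    pn_a, pn_b = _shapiro_p(a), _shapiro_p(b)
    pv = _two_sided_f_test(a, b)
    if pn_a > alpha and pn_b > alpha and pv > alpha:
        statistic, p = stats.ttest_ind(a, b, equal_var=False)
        test = "welch_t"
    else:
        statistic, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        test = "wilcoxon"
    return (pn_a, pn_b), pv, test, float(statistic), float(p)


def compare_groups(
    mat: StandardizedMatrix, group_a: str, group_b: str, alpha: float = 0.05
) -> list[UnivariateComparison]:
    """Per-measure two-group comparison with pairwise deletion per measure."""
    out: list[UnivariateComparison] = []
    in_a = mat.regions == group_a
    in_b = mat.regions == group_b
    for code in mat.data.columns:
        col = mat.data[code]
        a = col[in_a].dropna().to_numpy()
        b = col[in_b].dropna().to_numpy()
        if len(a) < 3 or len(b) < 3:
            out.append(
                UnivariateComparison(
                    code, len(a), len(b), (float("nan"),) * 2, float("nan"),
                    "untestable", float("nan"), float("nan"), False,
                )
            )
            continue
        norm_p, var_p, test, statistic, p = compare_two_samples(a, b, alpha)
        out.append(
            UnivariateComparison(
                code, len(a), len(b), norm_p, var_p, test, statistic, p, p < alpha
            )
        )
    return out


# ---------------------------------------------------------------------------
# PCA


def pca(mat: StandardizedMatrix | pd.DataFrame, scaling: str = "correlation") -> PCAResult:
    """PCA of the complete-case submatrix under correlation or covariance scaling.

    Deterministic sign convention: within each loading vector the
    largest-magnitude entry is made positive.
    """
    if scaling not in ("correlation", "covariance"):
        raise DataError(f"unknown scaling {scaling!r}")
    df = mat.data if isinstance(mat, StandardizedMatrix) else mat
    complete = df.dropna(axis=0, how="any")
    if complete.shape[0] < 3 or complete.shape[1] < 2:
        raise DataError(
            f"need >= 3 complete cases and >= 2 columns, have {complete.shape}"
        )
    X = complete.to_numpy(dtype=float)
    means = X.mean(axis=0)
    Xc = X - means
    if scaling == "correlation":
        scales = X.std(axis=0, ddof=1)
        if np.any(scales == 0):
            zero = [c for c, sd in zip(complete.columns, scales) if sd == 0]
            raise DataError(f"zero-variance columns: {zero}")
        Xc = Xc / scales
    else:
        scales = np.ones(X.shape[1])
        if np.any(X.std(axis=0, ddof=1) == 0):
            zero = [c for c, sd in zip(complete.columns, X.std(axis=0, ddof=1)) if sd == 0]
            raise DataError(f"zero-variance columns: {zero}")
    cov = (Xc.T @ Xc) / (X.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    for j in range(eigvecs.shape[1]):
        k = int(np.argmax(np.abs(eigvecs[:, j])))
        if eigvecs[k, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    proportions = eigvals / eigvals.sum()
    scores = Xc @ eigvecs
    score_df = pd.DataFrame(
        scores,
        index=complete.index,
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
    return PCAResult(
        column_names=list(complete.columns),
        means=means,
        scales=scales,
        loadings=eigvecs,
        eigenvalues=eigvals,
        proportions=proportions,
        scores=score_df,
        scaling=scaling,
    )


# ---------------------------------------------------------------------------
# canonical discriminant analysis (DAPC)


def dfa(
    scores: pd.DataFrame,
    groups: pd.Series,
    n_components: int | float | None = 0.9,
    proportions: np.ndarray | None = None,
    min_group_size: int = 2,
) -> DFAResult:
    """Canonical discriminant analysis of PCA scores.

    Solves the generalized eigenproblem S_b v = lambda S_w v (between- vs
    within-group scatter).  ``n_components``: an int keeps that many leading
    PCs; a float in (0, 1] keeps the smallest set whose ``proportions``
    cumulate to at least that fraction of variance; None keeps all.  Groups
    with fewer than ``min_group_size`` members are projected onto the axes
    but excluded from scatter estimation.
    """
    groups = groups.loc[scores.index]
    if isinstance(n_components, float):
        if not 0 < n_components <= 1:
            raise DataError("variance threshold must be in (0, 1]")
        if proportions is None:
            raise DataError("variance threshold requires PCA proportions")
        k = int(np.searchsorted(np.cumsum(proportions), n_components - 1e-12) + 1)
    elif isinstance(n_components, int):
        k = n_components
    else:
        k = scores.shape[1]
    k = max(1, min(k, scores.shape[1]))
    X = scores.iloc[:, :k].to_numpy(dtype=float)

    sizes = groups.value_counts()
    used_groups = [g for g in sizes.index if sizes[g] >= min_group_size]
    if len(used_groups) < 2:
        raise DataError("need >= 2 groups with enough members")
    mask = groups.isin(used_groups).to_numpy()
    Xu, gu = X[mask], groups[mask]

    grand = Xu.mean(axis=0)
    d = Xu.shape[1]
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    means = {}
    for g in used_groups:
        Xg = Xu[(gu == g).to_numpy()]
        mg = Xg.mean(axis=0)
        means[g] = mg
        Dg = Xg - mg
        Sw += Dg.T @ Dg
        diff = (mg - grand)[:, None]
        Sb += len(Xg) * (diff @ diff.T)
    try:
        eigvals, eigvecs = linalg.eigh(Sb, Sw)
    except linalg.LinAlgError as exc:
        raise DataError(
            "singular within-group scatter; retain fewer components"
        ) from exc
    order = np.argsort(eigvals)[::-1]
    n_axes = min(len(used_groups) - 1, d)
    eigvals = np.clip(eigvals[order][:n_axes], 0.0, None)
    eigvecs = eigvecs[:, order][:, :n_axes]
    for j in range(eigvecs.shape[1]):
        i = int(np.argmax(np.abs(eigvecs[:, j])))
        if eigvecs[i, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    axis_names = [f"LD{i + 1}" for i in range(n_axes)]
    all_scores = pd.DataFrame((X - grand) @ eigvecs, index=scores.index, columns=axis_names)
    centroids = pd.DataFrame(
        {g: (means[g] - grand) @ eigvecs for g in used_groups}, index=axis_names
    ).T
    return DFAResult(
        eigenvalues=eigvals,
        coefficients=eigvecs,
        scores=all_scores,
        groups=groups,
        centroids=centroids,
        n_components_used=k,
    )


def assess_isolation(result: DFAResult, pair: tuple[str, str]) -> tuple[bool, float]:
    """Do two groups' convex hulls on the first two discriminant axes overlap?

    Returns (isolated, overlap measure).  Isolated means the hulls (or, when
    either group has < 3 points or only one axis exists, the axis-1
    intervals) do not intersect; the overlap measure is the intersection
    area in 2D or length in 1D (0 when isolated or touching at a point).
    """
    a, b = pair
    pts = {}
    for g in (a, b):
        sel = result.scores[(result.groups == g).to_numpy()]
        if sel.empty:
            raise DataError(f"group {g!r} has no scores")
        pts[g] = sel.to_numpy()
    two_d = result.scores.shape[1] >= 2 and all(len(p) >= 3 for p in pts.values())
    if two_d:
        hull_a = MultiPoint([tuple(p[:2]) for p in pts[a]]).convex_hull
        hull_b = MultiPoint([tuple(p[:2]) for p in pts[b]]).convex_hull
        inter = hull_a.intersection(hull_b)
        overlap = inter.area if inter.area > 0 else inter.length
        return bool(inter.is_empty), float(overlap)
    lo_a, hi_a = pts[a][:, 0].min(), pts[a][:, 0].max()
    lo_b, hi_b = pts[b][:, 0].min(), pts[b][:, 0].max()
    lo, hi = max(lo_a, lo_b), min(hi_a, hi_b)
    return bool(hi < lo), float(max(hi - lo, 0.0))
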