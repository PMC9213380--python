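"""Agreement and test statistics for feature-stability analysis.

Implements, directly from their defining formulas, the statistics the
stability pipeline consumes:

* ``icc_3_1`` — Shrout & Fleiss intraclass correlation ICC(3,1): two-way
  mixed model, single score, consistency form.
* ``lin_ccc`` — Lin's concordance correlation coefficient between two
  measurement series.
* ``occc`` — Barnhart's overall concordance correlation coefficient, the
  multi-rater generalization of Lin's CCC.
* ``kruskal_wallis`` — the Kruskal-Wallis omnibus rank test with mid-rank
  tie correction and the chi-square p-value approximation.
* ``bonferroni`` — Bonferroni multiplicity adjustment.
* ``pearson`` — Pearson correlation with the two-sided t-test.

Undefined statistics (zero variance everywhere) propagate as NaN rather
than raising; downstream acceptance thresholds treat NaN as a failure so
that degenerate, information-free features are never scored as stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "RatingMatrix",
    "TestResult",
    "icc_3_1",
    "lin_ccc",
    "occc",
    "kruskal_wallis",
    "bonferroni",
    "pearson",
]


@dataclass(frozen=True)
class RatingMatrix:
    """n_subjects x k_raters matrix of numeric scores.

    Rows are subjects (the objects being rated), columns are raters
    (the repeated measurement conditions). Missing values are rejected:
    the factorial design that feeds this type guarantees complete blocks.
    """

    values: np.ndarray
    subjects: tuple | None = None
    raters: tuple | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError(f"rating matrix must be 2-D, got shape {v.shape}")
        if v.shape[0] < 2 or v.shape[1] < 2:
            raise ValueError(
                f"need >= 2 subjects and >= 2 raters, got {v.shape[0]} x {v.shape[1]}"
            )
        if not np.isfinite(v).all():
            raise ValueError("rating matrix contains missing or non-finite entries")
        object.__setattr__(self, "values", v)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def k_raters(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class TestResult:
    """Statistic, p-value and bookkeeping for a hypothesis test."""

    statistic: float
    p_value: float
    df: float
    method: str

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _as_matrix(m) -> np.ndarray:
    if isinstance(m, RatingMatrix):
        return m.values
    return RatingMatrix(np.asarray(m, dtype=float)).values


def icc_3_1(m) -> float:
    """ICC(3,1): two-way mixed, single-score, consistency.

    ICC = (BMS - EMS) / (BMS + (k - 1) EMS) where BMS is the
    between-subjects mean square and EMS the residual mean square of the
    two-way subjects x raters layout. Invariant to adding a constant to
    any rater column (rater main effects are removed).

    Returns NaN when BMS + (k-1) EMS == 0, i.e. when the matrix carries
    no subject or residual variability at all.
    """
    v = _as_matrix(m)
    n, k = v.shape
    grand = v.mean()
    row_means = v.mean(axis=1)
    col_means = v.mean(axis=0)
    ss_total = ((v - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    bms = ss_rows / (n - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    denom = bms + (k - 1) * ems
    if denom <= 0 or not np.isfinite(denom) or np.isclose(denom, 0.0, atol=1e-30):
        return float("nan")
    return float((bms - ems) / denom)


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient between two series.

    CCC = 2 s_xy / (s_x^2 + s_y^2 + (mean x - mean y)^2) with biased
    (1/n) moment estimators. NaN if both series are constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("lin_ccc expects two 1-D vectors of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 paired observations")
    mx, my = x.mean(), y.mean()
    sx2 = ((x - mx) ** 2).mean()
    sy2 = ((y - my) ** 2).mean()
    sxy = ((x - mx) * (y - my)).mean()
    denom = sx2 + sy2 + (mx - my) ** 2
    if sx2 == 0 and sy2 == 0:
        return float("nan")  # two constant series carry no concordance signal
    return float(2.0 * sxy / denom)


def occc(m) -> float:
    """Barnhart's overall concordance correlation coefficient.

    For J raters,

        OCCC = sum_{j<l} 2 s_jl / sum_{j<l} [s_j^2 + s_l^2 + (mu_j - mu_l)^2]

    with 1/n (population) moments — a weighted average of the pairwise
    Lin CCCs with weights proportional to each pair's denominator. For
    J = 2 it reduces exactly to ``lin_ccc``. NaN if the total denominator
    is zero (all columns constant and identical in mean).
    """
    v = _as_matrix(m)
    n, k = v.shape
    mu = v.mean(axis=0)
    c = v - mu
    # population covariance matrix between rater columns
    cov = c.T @ c / n
    num = 0.0
    den = 0.0
    for j in range(k):
        for l in range(j + 1, k):
            num += 2.0 * cov[j, l]
            den += cov[j, j] + cov[l, l] + (mu[j] - mu[l]) ** 2
    if den == 0:
        return float("nan")
    return float(num / den)


def kruskal_wallis(groups, exact: bool = False, n_perm: int = 10000,
                   rng=None) -> TestResult:
    """Kruskal-Wallis omnibus test over >= 2 groups.

    H = [12 / (N (N+1))] * sum_i n_i Rbar_i^2 - 3 (N + 1), computed on
    mid-ranks, divided by the tie-correction factor
    1 - sum(t^3 - t) / (N^3 - N). The p-value uses the chi-square
    approximation with k - 1 degrees of freedom (standard even at small
    per-group n); ``exact=True`` replaces it with a permutation p-value
    for validation purposes.

    All pooled values identical -> tie correction factor is 0; the test
    is degenerate and returns H = 0, p = 1 by convention.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 1 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    sizes = np.array([g.size for g in groups])
    pooled = np.concatenate(groups)
    n_tot = pooled.size
    if n_tot < 3:
        raise ValueError("need at least 3 observations in total")
    df = len(groups) - 1

    def h_statistic(values: np.ndarray) -> float:
        ranks = sps.rankdata(values)  # mid-ranks
        _, counts = np.unique(values, return_counts=True)
        tie = 1.0 - (counts**3 - counts).sum() / (n_tot**3 - n_tot)
        if tie == 0.0:
            return float("nan")
        bounds = np.cumsum(sizes)
        h = 0.0
        start = 0
        for stop, ni in zip(bounds, sizes):
            rbar = ranks[start:stop].mean()
            h += ni * rbar**2
            start = stop
        h = 12.0 / (n_tot * (n_tot + 1)) * h - 3.0 * (n_tot + 1)
        return h / tie

    h = h_statistic(pooled)
    if np.isnan(h):  # all values tied everywhere
        return TestResult(0.0, 1.0, df, "kruskal-wallis (degenerate, all tied)")
    if exact:
        rng = np.random.default_rng(rng)
        count = 1
        for _ in range(n_perm):
            if h_statistic(rng.permutation(pooled)) >= h - 1e-12:
                count += 1
        return TestResult(float(h), count / (n_perm + 1), df,
                          "kruskal-wallis (permutation)")
    p = float(sps.chi2.sf(h, df))
    return TestResult(float(h), p, df, "kruskal-wallis (chi-square approx.)")


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, p * m).

    ``m`` defaults to the length of ``p_values``; it may be passed
    explicitly when the family is larger than the vector at hand.
    """
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return np.minimum(1.0, p * m)


def pearson(x, y) -> TestResult:
    """Pearson correlation r with its two-sided t-test.

    t = r sqrt((n - 2) / (1 - r^2)) on n - 2 degrees of freedom. Returns
    r = NaN, p = NaN if either input has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("pearson expects two 1-D vectors of equal length >= 3")
    n = x.size
    cx, cy = x - x.mean(), y - y.mean()
    ssx, ssy = (cx**2).sum(), (cy**2).sum()
    if ssx == 0 or ssy == 0:
        return TestResult(float("nan"), float("nan"), n - 2, "pearson (undefined)")
    r = float((cx * cy).sum() / np.sqrt(ssx * ssy))
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return TestResult(r, p, n - 2, "pearson")
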