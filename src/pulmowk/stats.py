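"""Small-sample cohort statistics: median/IQR, exact Mann-Whitney U and
exact Spearman rank correlation.

Sample sizes here are a handful of subjects per group, so the two-sided
p-values are exact: the Mann-Whitney null distribution is enumerated over
all C(n_x+n_y, n_x) group labelings and the Spearman null over all n!
pairings, falling back to the usual normal / Student-t approximations above
a configurable size threshold.  Ranks use midranks for ties.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from itertools import combinations, permutations
from math import comb, factorial

import numpy as np
from scipy.stats import norm as _norm
from scipy.stats import rankdata
from scipy.stats import t as _student_t

__all__ = [
    "SubjectRecord",
    "TestResult",
    "ComparisonRow",
    "median_iqr",
    "mann_whitney_u",
    "spearman",
    "group_compare",
    "METRICS",
    "SIGNIFICANCE_LEVEL",
]

SIGNIFICANCE_LEVEL = 0.050
_EPS = 1e-9


@dataclass
class SubjectRecord:
    """Per-subject biomechanical markers in clinical units."""

    subject_id: str
    group: str  # 'control' or 'PAH'
    e_kpa: float
    rac: float
    d_mm: float
    rt_mmhg_min_per_l: float
    ct_ml_per_mmhg: float
    tawss_mpa_pa: float
    tawss_all_pa: float
    regurgitant_ml: float

    def __post_init__(self) -> None:
        if self.group not in ("control", "PAH"):
            raise ValueError(f"group must be 'control' or 'PAH', got {self.group!r}")
        for name in (
            "e_kpa", "rac", "d_mm", "rt_mmhg_min_per_l", "ct_ml_per_mmhg",
            "tawss_mpa_pa", "tawss_all_pa", "regurgitant_ml",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SubjectRecord":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__})


# metric name -> SubjectRecord attribute
METRICS = {
    "E": "e_kpa",
    "RAC": "rac",
    "D": "d_mm",
    "R_T": "rt_mmhg_min_per_l",
    "C_T": "ct_ml_per_mmhg",
    "TAWSS_MPA": "tawss_mpa_pa",
    "TAWSS_all": "tawss_all_pa",
    "regurgitant_volume": "regurgitant_ml",
}


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str  # 'exact' or 'asymptotic'
    n: tuple

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value must lie in [0, 1]")


@dataclass(frozen=True)
class ComparisonRow:
    metric: str
    control_median: float
    control_iqr: float
    pah_median: float
    pah_iqr: float
    p_value: float
    method: str


def median_iqr(values) -> tuple[float, float]:
    """Median (midpoint convention) and IQR = Q3 − Q1.

    Quartiles use linear interpolation of order statistics, so e.g.
    {1,2,3,4,5} gives Q1 = 2, Q3 = 4 and IQR = 2.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    q1, q3 = np.percentile(v, [25.0, 75.0])
    return float(np.median(v)), float(q3 - q1)


def mann_whitney_u(x, y, exact_threshold: int = 14) -> TestResult:
    """Two-sided Mann-Whitney U test with midrank ties.

    For n_x + n_y ≤ ``exact_threshold`` the p-value is exact, defined as the
    doubled lower tail min(1, 2·P(U ≤ u_obs)) with u_obs = min(U_x, U_y)
    over all group labelings of the pooled sample; above the threshold a
    tie-corrected normal approximation with continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx == 0 or ny == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks
    base = nx * (nx + 1) / 2.0
    u_x = float(ranks[:nx].sum() - base)
    u_y = nx * ny - u_x
    u_obs = min(u_x, u_y)
    n = nx + ny

    if n <= exact_threshold:
        count = 0
        for idx in combinations(range(n), nx):
            u_c = ranks[list(idx)].sum() - base
            if u_c <= u_obs + _EPS:
                count += 1
        p = min(1.0, 2.0 * count / comb(n, nx))
        return TestResult(statistic=u_x, p_value=p, method="exact", n=(nx, ny))

    mu = nx * ny / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    if var <= 0:  # all values identical
        return TestResult(statistic=u_x, p_value=1.0, method="asymptotic", n=(nx, ny))
    z = (u_obs - mu + 0.5) / np.sqrt(var)  # continuity-corrected lower tail
    p = min(1.0, 2.0 * float(_norm.cdf(z)))
    return TestResult(statistic=u_x, p_value=p, method="asymptotic", n=(nx, ny))


def spearman(x, y, exact_threshold: int = 8) -> TestResult:
    """Spearman rank correlation with an exact two-sided permutation p-value.

    r is the Pearson correlation of midranks.  For n ≤ ``exact_threshold``
    the p-value enumerates all n! pairings, p = P(|r_perm| ≥ |r_obs|);
    larger samples use the Student-t approximation with n − 2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired samples of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input vector")
    rx = rankdata(x)
    ry = rankdata(y)
    r = float(np.corrcoef(rx, ry)[0, 1])

    if n <= exact_threshold:
        cx = rx - rx.mean()
        cy = ry - ry.mean()
        denom = np.sqrt((cx**2).sum() * (cy**2).sum())
        r_abs = abs(r)
        count = 0
        for perm in permutations(cy):
            r_p = abs(float(np.dot(cx, perm)) / denom)
            if r_p >= r_abs - _EPS:
                count += 1
        p = count / factorial(n)
        return TestResult(statistic=r, p_value=p, method="exact", n=(n,))

    denom = 1.0 - r * r
    if denom <= 0:
        p = 0.0
    else:
        t_stat = r * np.sqrt((n - 2) / denom)
        p = 2.0 * float(_student_t.sf(abs(t_stat), n - 2))
    return TestResult(statistic=r, p_value=min(1.0, p), method="asymptotic", n=(n,))


def group_compare(records, metric: str, exact_threshold: int = 14) -> ComparisonRow:
    """One comparison-table row: control vs PAH median/IQR and Mann-Whitney p."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(METRICS)}")
    attr = METRICS[metric]
    ctrl = [getattr(r, attr) for r in records if r.group == "control"]
    pah = [getattr(r, attr) for r in records if r.group == "PAH"]
    if not ctrl or not pah:
        raise ValueError("both groups must be non-empty")
    med_c, iqr_c = median_iqr(ctrl)
    med_p, iqr_p = median_iqr(pah)
    test = mann_whitney_u(ctrl, pah, exact_threshold=exact_threshold)
    return ComparisonRow(
        metric=metric,
        control_median=med_c,
        control_iqr=iqr_c,
        pah_median=med_p,
        pah_iqr=iqr_p,
        p_value=test.p_value,
        method=test.method,
    )
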