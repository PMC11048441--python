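"""Two-group statistics for VOT feature tables.

The analysis controls the number of planned pairwise comparisons by first
running family-level two-sample Hotelling's T² tests (NIRS variables of the
occlusion phase, NIRS variables of the hyperemia phase, DCS variables of
the hyperemia phase), then Bonferroni-adjusted pairwise comparisons within
each family.  The single occlusion-phase DCS variable (the rBF floor) gets
a lone Student's t-test.  Right-skewed variables are log-transformed before
the t-test; a variable that cannot be brought to normality falls back to
the Mann-Whitney U test.  Effect sizes are partial eta squared for the
multivariate tests and Cohen's d (pooled SD) for pairwise comparisons,
computed on the same scale as the test (i.e. after any log transform).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .vot_features import FEATURE_NAMES, FEATURE_UNITS

__all__ = [
    "GroupSample",
    "TestResult",
    "StatsError",
    "hotelling_t2",
    "cohens_d",
    "cohens_d_from_summary",
    "pairwise_compare",
    "bonferroni_adjust",
    "normality_check",
    "run_family_analysis",
    "FamilyReport",
    "FAMILIES",
    "DEFAULT_TRANSFORMS",
]


class StatsError(ValueError):
    pass


#: variable families for the multivariate tests and the Bonferroni scope
FAMILIES: dict[str, tuple[str, ...]] = {
    "oc_nirs": (
        "oc_d_o2hb_slope", "oc_d_hhb_slope", "oc_d_tsi_slope",
        "oc_d_o2hb_min", "oc_d_hhb_max", "oc_d_tsi_min",
        "oc_d_o2hb_tmin", "oc_d_hhb_tmax", "oc_d_tsi_tmin",
    ),
    "oc_dcs": ("oc_rbf_min",),
    "hy_nirs": (
        "hy_d_o2hb_max", "hy_d_hhb_min", "hy_d_tsi_max",
        "hy_d_o2hb_tmax", "hy_d_hhb_tmin", "hy_d_tsi_tmax",
        "hy_d_o2hb_slope", "hy_d_hhb_slope", "hy_d_tsi_slope",
        "hy_d_o2hb_htr", "hy_d_hhb_htr", "hy_d_tsi_htr",
    ),
    "hy_dcs": ("hy_rbf_max", "hy_rbf_tmax", "hy_rbf_slope", "hy_rbf_htr"),
    "baseline": ("ba_o2hb", "ba_hhb", "ba_tsi", "ba_bfi"),
}

#: families that get a Hotelling's T² main-effect test (the lone oc_dcs
#: variable gets a Student's t instead; baselines are descriptive)
HOTELLING_FAMILIES = ("oc_nirs", "hy_nirs", "hy_dcs")

#: per-variable transform policy: right-skewed magnitude variables are
#: log-transformed; the rBF half-time cannot be normalized and is ranked
DEFAULT_TRANSFORMS: dict[str, str] = {
    "oc_rbf_min": "log",
    "hy_rbf_max": "log",
    "hy_d_tsi_max": "log",
    "hy_rbf_slope": "log",
    "hy_rbf_htr": "mann_whitney",
}


@dataclass
class GroupSample:
    """Aligned subjects x variables matrix for one group."""

    group: str
    matrix: np.ndarray
    variable_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape[1] != len(self.variable_names):
            raise StatsError(
                f"matrix has {self.matrix.shape[1]} columns but "
                f"{len(self.variable_names)} variable names"
            )


@dataclass
class TestResult:
    statistic: float
    df: tuple[float, float]
    p_raw: float
    p_adj: float
    effect: float
    effect_kind: str
    transform: str = "none"
    test_kind: str = "t"
    n: tuple[int, int] = (0, 0)


def _drop_missing_rows(x: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    return x[np.isfinite(x).all(axis=1)]


def hotelling_t2(a: GroupSample | np.ndarray, b: GroupSample | np.ndarray) -> TestResult:
    """Two-sample Hotelling's T² with the exact F reference distribution.

    T² = (n1 n2 / (n1+n2)) (x̄1-x̄2)' S⁻¹ (x̄1-x̄2) with S the pooled
    covariance; F = T² (n1+n2-p-1) / (p (n1+n2-2)) on (p, n1+n2-p-1)
    degrees of freedom.  Effect size is partial eta squared
    T² / (T² + n1 + n2 - 2).  Subjects with any missing variable are
    dropped listwise.
    """
    X = _drop_missing_rows(a.matrix if isinstance(a, GroupSample) else a)
    Y = _drop_missing_rows(b.matrix if isinstance(b, GroupSample) else b)
    n1, p = X.shape
    n2 = Y.shape[0]
    if n1 < 2 or n2 < 2:
        raise StatsError("each group needs at least 2 complete subjects")
    if n1 + n2 - 2 <= p:
        raise StatsError(
            f"too few subjects for {p} variables (need n1+n2-2 > p, "
            f"got n1={n1}, n2={n2})"
        )
    d = X.mean(axis=0) - Y.mean(axis=0)
    S = ((n1 - 1) * np.cov(X, rowvar=False, ddof=1)
         + (n2 - 1) * np.cov(Y, rowvar=False, ddof=1)) / (n1 + n2 - 2)
    S = np.atleast_2d(S)
    try:
        sol = np.linalg.solve(S, d)
    except np.linalg.LinAlgError:
        raise StatsError("collinear variables: pooled covariance is singular")
    t2 = float(n1 * n2 / (n1 + n2) * d @ sol)
    df1 = float(p)
    df2 = float(n1 + n2 - p - 1)
    f_stat = t2 * df2 / (df1 * (n1 + n2 - 2))
    p_val = float(stats.f.sf(f_stat, df1, df2))
    eta2 = t2 / (t2 + n1 + n2 - 2)
    return TestResult(
        statistic=f_stat,
        df=(df1, df2),
        p_raw=p_val,
        p_adj=p_val,
        effect=eta2,
        effect_kind="partial_eta_squared",
        test_kind="hotelling",
        n=(n1, n2),
    )


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d with the pooled standard deviation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise StatsError("need at least 2 values per group")
    return cohens_d_from_summary(
        a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
    )


def cohens_d_from_summary(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> float:
    """Cohen's d from group summaries: (m_a - m_b) / s_pooled with
    s_pooled² = ((n_a-1)s_a² + (n_b-1)s_b²) / (n_a+n_b-2)."""
    s2 = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2)
    if s2 <= 0:
        raise StatsError("zero pooled standard deviation")
    return float((mean_a - mean_b) / math.sqrt(s2))


def _mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact when n1+n2 <= 20 and there are no
    ties, normal approximation with tie correction otherwise."""
    method = "exact" if (a.size + b.size <= 20) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def pairwise_compare(a: np.ndarray, b: np.ndarray, policy: str = "none") -> TestResult:
    """Single-variable two-group comparison under a transform policy.

    ``none``/``log``: pooled-variance Student's t on (transformed) values,
    with Cohen's d on the same scale.  ``mann_whitney``: U test, no d.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise StatsError("need at least 2 values per group")
    if policy == "mann_whitney":
        u, p = _mann_whitney(a, b)
        return TestResult(
            statistic=u, df=(a.size, b.size), p_raw=p, p_adj=p,
            effect=math.nan, effect_kind="none",
            transform="rank", test_kind="mann_whitney", n=(a.size, b.size),
        )
    if policy == "log":
        if (a <= 0).any() or (b <= 0).any():
            raise StatsError("log transform undefined for non-positive values")
        a, b = np.log(a), np.log(b)
    elif policy != "none":
        raise StatsError(f"unknown transform policy {policy!r}")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return TestResult(
        statistic=float(t),
        df=(1.0, float(a.size + b.size - 2)),
        p_raw=float(p),
        p_adj=float(p),
        effect=cohens_d(a, b),
        effect_kind="cohens_d",
        transform=policy,
        test_kind="t",
        n=(a.size, b.size),
    )


def bonferroni_adjust(p_values: list[float], m: int) -> list[float]:
    """p_adj = min(1, m * p_raw), order preserved."""
    if m < len(p_values):
        raise StatsError(
            f"family size m={m} smaller than number of p-values {len(p_values)}"
        )
    return [min(1.0, m * p) for p in p_values]


def normality_check(values: np.ndarray, alpha: float = 0.05) -> tuple[float, float, str]:
    """Shapiro-Wilk test; decision is 'non-normal' iff p < alpha."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if not 3 <= v.size <= 5000:
        raise StatsError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {v.size}")
    if v.max() == v.min():
        raise StatsError("normality undefined for a constant sample")
    w, p = stats.shapiro(v)
    return float(w), float(p), ("non-normal" if p < alpha else "normal")


# ---------------------------------------------------------------------------
# full analysis


@dataclass
class FamilyReport:
    """Family-level multivariate tests plus the per-variable table."""

    family_tests: dict[str, TestResult]
    table: pd.DataFrame
    notes: list[str] = field(default_factory=list)


def run_family_analysis(
    features: pd.DataFrame,
    *,
    transforms: dict[str, str] | None = None,
    groups: tuple[str, str] = ("climber", "nonclimber"),
    alpha: float = 0.05,
) -> FamilyReport:
    """The full statistical layer over a per-subject feature table.

    ``features`` needs a ``group`` column plus the feature columns.  Returns
    the three family Hotelling tests (plus the lone occlusion rBF t-test)
    and a per-variable table of group mean ± SD, transform, raw and
    Bonferroni-adjusted p (family-wise m), and Cohen's d.  A variable whose
    log transform is undefined on these data falls back to the rank test,
    with a note.
    """
    transforms = {**DEFAULT_TRANSFORMS, **(transforms or {})}
    g1 = features[features["group"] == groups[0]]
    g2 = features[features["group"] == groups[1]]
    if len(g1) < 3 or len(g2) < 3:
        raise StatsError(
            f"need at least 3 subjects per group, got {len(g1)}/{len(g2)}"
        )
    notes: list[str] = []

    family_tests: dict[str, TestResult] = {}
    for fam in HOTELLING_FAMILIES:
        cols = list(FAMILIES[fam])
        try:
            family_tests[fam] = hotelling_t2(
                g1[cols].to_numpy(float), g2[cols].to_numpy(float)
            )
        except StatsError as exc:
            notes.append(f"family {fam}: Hotelling test not computable ({exc})")
    try:
        family_tests["oc_dcs"] = pairwise_compare(
            g1["oc_rbf_min"].to_numpy(float),
            g2["oc_rbf_min"].to_numpy(float),
            transforms.get("oc_rbf_min", "none"),
        )
    except StatsError as exc:
        notes.append(f"oc_rbf_min lone test not computable ({exc})")

    rows = []
    for fam, cols in FAMILIES.items():
        m = len(cols)
        fam_rows = []
        for var in cols:
            a = g1[var].to_numpy(float)
            b = g2[var].to_numpy(float)
            policy = transforms.get(var, "none")
            try:
                res = pairwise_compare(a, b, policy)
            except StatsError as exc:
                if policy == "log":
                    notes.append(
                        f"{var}: log transform undefined on these data; "
                        "falling back to Mann-Whitney"
                    )
                    res = pairwise_compare(a, b, "mann_whitney")
                else:
                    notes.append(f"{var}: comparison not computable ({exc})")
                    res = None
            fam_rows.append((var, res))
        p_adj = bonferroni_adjust(
            [r.p_raw for _, r in fam_rows if r is not None], m
        )
        it = iter(p_adj)
        for var, res in fam_rows:
            if res is None:
                rows.append({"variable": var, "family": fam})
                continue
            a = g1[var].to_numpy(float)
            b = g2[var].to_numpy(float)
            a, b = a[np.isfinite(a)], b[np.isfinite(b)]
            adj = next(it)
            rows.append({
                "variable": var,
                "family": fam,
                "unit": FEATURE_UNITS.get(var, ""),
                f"mean_{groups[0]}": a.mean() if a.size else math.nan,
                f"sd_{groups[0]}": a.std(ddof=1) if a.size > 1 else math.nan,
                f"n_{groups[0]}": a.size,
                f"mean_{groups[1]}": b.mean() if b.size else math.nan,
                f"sd_{groups[1]}": b.std(ddof=1) if b.size > 1 else math.nan,
                f"n_{groups[1]}": b.size,
                "test": res.test_kind,
                "transform": res.transform,
                "p_raw": res.p_raw,
                "p_adj": adj,
                "d": res.effect if res.effect_kind == "cohens_d" else math.nan,
                "significant": adj <= alpha,
            })

    order = {v: i for i, v in enumerate(FEATURE_NAMES)}
    table = (
        pd.DataFrame(rows)
        .sort_values("variable", key=lambda s: s.map(order))
        .reset_index(drop=True)
    )
    return FamilyReport(family_tests=family_tests, table=table, notes=notes)
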