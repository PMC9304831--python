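"""Normality-gated correlation statistics and group comparisons.

Every pairwise correlation is gated by the Shapiro-Wilk test: Pearson
when both margins pass normality (p > alpha, default 0.05), Spearman
otherwise.  Partial correlations residualize both variables (and, for
Spearman, their midranks) on an intercept plus the covariates by least
squares and correlate the residuals; significance uses the t reference
with n - 2 - k degrees of freedom.

Group comparisons mirror a two-group clinical table: pooled-variance
two-sided t-tests for continuous variables (Welch available by flag)
and Yates-corrected 2x2 chi-square for categorical ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .quantify import SubjectPVSStats

__all__ = [
    "CohortRecord",
    "CorrelationResult",
    "shapiro_wilk",
    "gated_correlation",
    "partial_correlation",
    "t_from_summary",
    "chi2_yates",
    "group_tests",
]

GATE_ALPHA = 0.05


@dataclass
class CohortRecord:
    """One subject's clinical covariates, optionally joined to PVS measures.

    ``tleq_ce`` counts traumatic events experienced; ``tleq_oc`` counts
    events that elicited fear, helplessness, or horror.  ``brain_vol_mm3``
    is the brain segmentation volume without ventricles.  Optional
    fields are ``None`` when absent.
    """

    subject_id: str
    group: str
    age: float
    gender: str
    tleq_ce: float | None = None
    tleq_oc: float | None = None
    madrs: float | None = None
    brain_vol_mm3: float | None = None
    csf_vol_mm3: float | None = None
    stats: SubjectPVSStats | None = None

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError(f"subject {self.subject_id}: age must be > 0")
        for name in ("tleq_ce", "tleq_oc"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"subject {self.subject_id}: {name} must be >= 0")


@dataclass
class CorrelationResult:
    method: str  # "pearson" | "spearman"
    r: float
    p: float
    n: int
    covariates: tuple[str, ...] = ()
    normality_p_x: float | None = None
    normality_p_y: float | None = None
    ties_present: bool = False


def shapiro_wilk(x: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk W and p (Royston's AS R94 approximation), 3 <= n <= 5000."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D sample")
    if np.any(~np.isfinite(x)):
        raise ValueError("sample contains missing or non-finite values")
    n = x.size
    if not 3 <= n <= 5000:
        raise ValueError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate sample: zero variance")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def _has_ties(x: np.ndarray) -> bool:
    return np.unique(x).size < x.size


def gated_correlation(
    x: Sequence[float], y: Sequence[float], alpha: float = GATE_ALPHA
) -> CorrelationResult:
    """Pearson iff both margins pass Shapiro-Wilk normality, else Spearman.

    Spearman uses midranks under ties (flagged on the result); p-values
    are two-sided via the standard t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 4:
        raise ValueError("need n >= 4 for a gated correlation")
    _, px = shapiro_wilk(x)
    _, py = shapiro_wilk(y)
    if px > alpha and py > alpha:
        method = "pearson"
        r, p = sps.pearsonr(x, y)
    else:
        method = "spearman"
        r, p = sps.spearmanr(x, y)
    return CorrelationResult(
        method=method,
        r=float(r),
        p=float(p),
        n=x.size,
        normality_p_x=px,
        normality_p_y=py,
        ties_present=_has_ties(x) or _has_ties(y),
    )


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ coef


def partial_correlation(
    x: Sequence[float],
    y: Sequence[float],
    covariates: np.ndarray | pd.DataFrame | None = None,
    method: str | None = None,
    covariate_names: Sequence[str] | None = None,
    alpha: float = GATE_ALPHA,
) -> CorrelationResult:
    """Correlation between x and y with covariate effects removed.

    ``method=None`` applies the normality gate to the raw margins.
    Pearson: residualize x and y on [1, covariates]; Spearman: midrank
    x, y and every covariate first, then proceed identically.  The
    two-sided p uses t = r*sqrt(df/(1-r^2)) with df = n - 2 - k.
    Categorical covariates must be numerically encoded by the caller
    (see :func:`cohort_frame` for the 0/1 gender encoding).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if covariates is None:
        cov = np.empty((n, 0))
        names: tuple[str, ...] = ()
    else:
        if isinstance(covariates, pd.DataFrame):
            names = tuple(map(str, covariates.columns))
            cov = covariates.to_numpy(dtype=float)
        else:
            cov = np.asarray(covariates, dtype=float)
            if cov.ndim == 1:
                cov = cov[:, None]
            names = tuple(covariate_names) if covariate_names else tuple(
                f"c{i}" for i in range(cov.shape[1])
            )
        if cov.shape[0] != n:
            raise ValueError("covariate rows must match n")
    k = cov.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")

    px = py = None
    if method is None:
        _, px = shapiro_wilk(x)
        _, py = shapiro_wilk(y)
        method = "pearson" if (px > alpha and py > alpha) else "spearman"
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")

    if method == "spearman":
        xs = sps.rankdata(x)
        ys = sps.rankdata(y)
        cs = np.column_stack([sps.rankdata(cov[:, j]) for j in range(k)]) if k else cov
    else:
        xs, ys, cs = x, y, cov

    design = np.column_stack([np.ones(n), cs])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(f"rank-deficient covariates (collinear among {list(names)})")
    rx = _residualize(xs, design)
    ry = _residualize(ys, design)
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        raise ValueError("degenerate residuals: zero variance after residualization")
    r = float(rx @ ry) / denom
    df = n - 2 - k
    r_clamped = min(max(r, -1.0), 1.0)
    if abs(r_clamped) == 1.0:
        p = 0.0
    else:
        t = r_clamped * math.sqrt(df / (1.0 - r_clamped**2))
        p = 2.0 * sps.t.sf(abs(t), df)
    return CorrelationResult(
        method=method,
        r=r,
        p=float(p),
        n=n,
        covariates=names,
        normality_p_x=px,
        normality_p_y=py,
        ties_present=_has_ties(x) or _has_ties(y),
    )


def t_from_summary(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-sided two-sample t-test from summary statistics (pooled by default)."""
    t, p = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=equal_var)
    return float(t), float(p)


def chi2_yates(table: np.ndarray | Sequence[Sequence[int]]) -> tuple[float, float]:
    """Chi-square test on a contingency table, Yates-corrected when 2x2."""
    table = np.asarray(table)
    chi2, p, _, _ = sps.chi2_contingency(table, correction=(table.shape == (2, 2)))
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# Cohort-level reports
# ---------------------------------------------------------------------------

_CONTINUOUS = (
    ("age", lambda r: r.age),
    ("madrs", lambda r: r.madrs),
    ("tleq_ce", lambda r: r.tleq_ce),
    ("tleq_oc", lambda r: r.tleq_oc),
    ("pvs_count", lambda r: r.stats.pvs_count if r.stats else None),
    ("total_volume_mm3", lambda r: r.stats.total_volume_mm3 if r.stats else None),
    ("median_volume_mm3", lambda r: r.stats.median_volume_mm3 if r.stats else None),
    ("density_per_cm3", lambda r: r.stats.density_per_cm3 if r.stats else None),
    ("median_eq_diameter_mm", lambda r: r.stats.median_eq_diameter_mm if r.stats else None),
    ("median_long_axis_mm", lambda r: r.stats.median_long_axis_mm if r.stats else None),
    ("median_short_axis_mm", lambda r: r.stats.median_short_axis_mm if r.stats else None),
    ("wm_volume_mm3", lambda r: r.stats.wm_volume_mm3 if r.stats else None),
)


def cohort_frame(records: Sequence[CohortRecord]) -> pd.DataFrame:
    """Tabular view of a cohort; gender encoded 0 (female) / 1 (male)."""
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "group": r.group,
            "gender_male": 1.0 if str(r.gender).strip().lower() in ("m", "male", "1") else 0.0,
            "brain_vol_mm3": r.brain_vol_mm3,
            "csf_vol_mm3": r.csf_vol_mm3,
        }
        for name, get in _CONTINUOUS:
            row[name] = get(r)
        rows.append(row)
    return pd.DataFrame(rows)


def group_tests(
    records: Sequence[CohortRecord], equal_var: bool = True
) -> pd.DataFrame:
    """Two-group comparison table.

    Continuous variables: two-sided t-test (pooled variance by default);
    gender: Yates-corrected 2x2 chi-square on male counts.  Rows with a
    missing value are dropped per variable.
    """
    df = cohort_frame(records)
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, found {groups}")
    g1, g2 = groups
    out = []
    for name, _ in _CONTINUOUS:
        a = df.loc[(df["group"] == g1) & df[name].notna(), name].to_numpy(dtype=float)
        b = df.loc[(df["group"] == g2) & df[name].notna(), name].to_numpy(dtype=float)
        if a.size < 2 or b.size < 2:
            continue
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            t, p = 0.0, 1.0
        elif np.ptp(np.concatenate([a, b])) == 0:
            raise ValueError(f"{name}: zero pooled variance")
        else:
            t, p = t_from_summary(
                a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size, equal_var
            )
        out.append(
            {
                "variable": name,
                "test": "t_pooled" if equal_var else "t_welch",
                f"mean_{g1}": a.mean(),
                f"mean_{g2}": b.mean(),
                "statistic": t,
                "p": p,
            }
        )
    # gender: 2x2 male/female counts
    males = df.groupby("group")["gender_male"].sum()
    totals = df.groupby("group")["gender_male"].count()
    table = np.array(
        [
            [males[g1], totals[g1] - males[g1]],
            [males[g2], totals[g2] - males[g2]],
        ]
    )
    if (table.sum(axis=0) == 0).any():
        # single-gender cohort: no imbalance to test
        chi2, p = 0.0, 1.0
    else:
        chi2, p = chi2_yates(table)
    out.append(
        {
            "variable": "gender_male",
            "test": "chi2_yates",
            f"mean_{g1}": males[g1] / totals[g1],
            f"mean_{g2}": males[g2] / totals[g2],
            "statistic": chi2,
            "p": p,
        }
    )
    return pd.DataFrame(out)
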