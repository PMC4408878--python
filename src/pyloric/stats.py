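"""Comparison statistics implemented from their classical formulas.

Pearson correlation with its t-based p-value, paired and unpaired (pooled or
Welch) t tests, Mood's median test, and the two-way mixed ("split-plot")
ANOVA with one between-subjects factor (modulatory condition) and one
within-subjects factor (time).  The split-plot decomposition is the classical
univariate one with two error strata: subjects-within-groups for the
between-subjects factor, and its interaction with time for the within
effects.  Only the tail probabilities come from scipy's distribution
functions; every statistic is computed here from sums of squares.

Conventions: two-sided p-values throughout; no sphericity correction by
default (Greenhouse-Geisser available as an option); ties at the grand median
in Mood's test count in the "<= median" cell; no multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2
from scipy.stats import f as _f
from scipy.stats import t as _t

__all__ = [
    "StatResult",
    "MixedAnovaResult",
    "pearson_corr",
    "paired_t",
    "unpaired_t",
    "moods_median",
    "pearson_chi2_2x2",
    "mixed_anova",
    "mixed_anova_long",
]


@dataclass(frozen=True)
class StatResult:
    """One test: name, statistic, degrees of freedom, two-sided p, group sizes."""

    name: str
    statistic: float
    df: tuple[float, ...]
    p: float
    n: tuple[int, ...]

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p out of range: {self.p}")


@dataclass(frozen=True)
class MixedAnovaResult:
    """Split-plot ANOVA: three F tests plus the full SS/df/MS decomposition."""

    F_between: float
    p_between: float
    F_within: float
    p_within: float
    F_interaction: float
    p_interaction: float
    ss: dict[str, float] = field(repr=False)
    df: dict[str, float] = field(repr=False)
    ms: dict[str, float] = field(repr=False)
    n_per_group: dict = field(repr=False, default_factory=dict)


def _finite_pair(a, b, paired: bool):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired samples must have equal length")
        ok = np.isfinite(a) & np.isfinite(b)
        return a[ok], b[ok]
    return a[np.isfinite(a)], b[np.isfinite(b)]


def pearson_corr(x, y) -> StatResult:
    """Sample Pearson R with p from t = R sqrt((n-2)/(1-R^2)) on t(n-2)."""
    x, y = _finite_pair(x, y, paired=True)
    n = x.size
    if n < 3:
        raise ValueError("need >= 3 paired finite observations")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0 or syy == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(dx @ dy) / np.sqrt(sxx * syy)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        tstat = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * float(_t.sf(abs(tstat), n - 2))
    return StatResult("pearson_r", r, (float(n - 2),), min(p, 1.0), (n,))


def paired_t(a, b) -> StatResult:
    """Paired t test: t = mean(d) / (SD(d)/sqrt(n)), df = n - 1."""
    a, b = _finite_pair(a, b, paired=True)
    n = a.size
    if n < 2:
        raise ValueError("need >= 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return StatResult("paired_t", 0.0, (float(n - 1),), 1.0, (n, n))
        raise ValueError("zero variance of nonzero differences")
    tstat = float(d.mean() / (sd / np.sqrt(n)))
    p = 2.0 * float(_t.sf(abs(tstat), n - 1))
    return StatResult("paired_t", tstat, (float(n - 1),), min(p, 1.0), (n, n))


def unpaired_t(a, b, equal_var: bool = True) -> StatResult:
    """Two-sample t test; pooled-variance by default, Welch optional."""
    a, b = _finite_pair(a, b, paired=False)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 observations per group")
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if equal_var:
        if v1 == 0 and v2 == 0:
            raise ValueError("zero variance in both groups")
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = float(n1 + n2 - 2)
        name = "unpaired_t"
    else:
        if v1 == 0 and v2 == 0:
            raise ValueError("zero variance in both groups")
        se = np.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
        name = "welch_t"
    tstat = float(diff / se)
    p = 2.0 * float(_t.sf(abs(tstat), df))
    return StatResult(name, tstat, (df,), min(p, 1.0), (n1, n2))


def pearson_chi2_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) of a 2x2 table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    n = t.sum()
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("degenerate table: zero marginal")
    expected = np.outer(rows, cols) / n
    chi2 = float(((t - expected) ** 2 / expected).sum())
    p = float(_chi2.sf(chi2, 1))
    return chi2, p


def moods_median(a, b) -> StatResult:
    """Mood's median test for two groups of very different sizes/variances.

    Pools both groups, takes the grand median, cross-tabulates
    (> median) vs (<= median) by group (ties count as <= median), and applies
    the Pearson chi-square with 1 df, no continuity correction.
    """
    a, b = _finite_pair(a, b, paired=False)
    pooled = np.concatenate([a, b])
    if pooled.size == 0 or np.all(pooled == pooled[0]):
        raise ValueError("degenerate input: all values equal")
    med = float(np.median(pooled))
    table = np.array(
        [
            [(a > med).sum(), (a <= med).sum()],
            [(b > med).sum(), (b <= med).sum()],
        ],
        dtype=float,
    )
    chi2, p = pearson_chi2_2x2(table)
    return StatResult("moods_median_chi2", chi2, (1.0,), p, (a.size, b.size))


def _gg_epsilon(resid_by_subject: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the within-subject covariance matrix."""
    s = np.cov(resid_by_subject, rowvar=False, ddof=1)
    k = s.shape[0]
    mean_diag = np.trace(s) / k
    grand = s.mean()
    row = s.mean(axis=1)
    num = (k * (mean_diag - grand)) ** 2
    den = (k - 1) * (np.sum(s * s) - 2 * k * np.sum(row * row) + k * k * grand * grand)
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def mixed_anova(
    values: np.ndarray,
    groups,
    gg_correction: bool = False,
) -> MixedAnovaResult:
    """Two-way mixed (split-plot) ANOVA.

    ``values`` is an (n_subjects, k_levels) array, complete per subject
    (exclude incomplete subjects beforehand, see :func:`mixed_anova_long`);
    ``groups`` labels each row's between-subjects group.  Every group needs
    >= 2 subjects.

    Decomposition (two error strata): the between-groups effect is tested
    against subjects-within-groups; the within-subjects (time) effect and the
    group x time interaction are tested against time x subjects-within-groups.
    Because each subject contributes every level, cell counts are proportional
    to group sizes and the observation-weighted decomposition is exactly
    orthogonal, which is the classical solution for unequal group sizes.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 2:
        raise ValueError("values must be (n_subjects, k_levels)")
    if not np.all(np.isfinite(y)):
        raise ValueError("values must be finite and complete per subject")
    groups = np.asarray(groups)
    if groups.shape[0] != y.shape[0]:
        raise ValueError("groups must label each subject")
    n_subj, k = y.shape
    if k < 2:
        raise ValueError("need >= 2 within-subject levels")
    labels, ginv = np.unique(groups, return_inverse=True)
    G = labels.size
    n_g = np.bincount(ginv)
    if np.any(n_g < 2):
        raise ValueError("every group needs >= 2 subjects")

    grand = y.mean()
    subj_mean = y.mean(axis=1)
    time_mean = y.mean(axis=0)
    group_mean = np.array([subj_mean[ginv == g].mean() for g in range(G)])
    cell_mean = np.vstack([y[ginv == g].mean(axis=0) for g in range(G)])

    ss_total = float(((y - grand) ** 2).sum())
    ss_between_subj = float(k * ((subj_mean - grand) ** 2).sum())
    ss_group = float(k * (n_g * (group_mean - grand) ** 2).sum())
    ss_subj_within = ss_between_subj - ss_group
    ss_within_subj = ss_total - ss_between_subj
    ss_time = float(n_subj * ((time_mean - grand) ** 2).sum())
    inter = cell_mean - group_mean[:, None] - time_mean[None, :] + grand
    ss_inter = float((n_g[:, None] * inter**2).sum())
    ss_err2 = ss_within_subj - ss_time - ss_inter

    df_group = G - 1
    df_err1 = n_subj - G
    df_time = k - 1
    df_inter = (G - 1) * (k - 1)
    df_err2 = (n_subj - G) * (k - 1)
    if df_err1 <= 0 or df_err2 <= 0:
        raise ValueError("insufficient subjects for error degrees of freedom")

    ms = {
        "group": ss_group / df_group,
        "subjects_within_groups": ss_subj_within / df_err1,
        "time": ss_time / df_time,
        "interaction": ss_inter / df_inter,
        "time_x_subjects": ss_err2 / df_err2,
    }
    if ms["subjects_within_groups"] <= 0 or ms["time_x_subjects"] <= 0:
        raise ValueError("zero error mean square: F undefined")

    F_b = ms["group"] / ms["subjects_within_groups"]
    F_w = ms["time"] / ms["time_x_subjects"]
    F_i = ms["interaction"] / ms["time_x_subjects"]

    # GG epsilon estimated from subject-centred data
    eps = _gg_epsilon(y - subj_mean[:, None]) if gg_correction else 1.0
    p_b = float(_f.sf(F_b, df_group, df_err1))
    p_w = float(_f.sf(F_w, eps * df_time, eps * df_err2))
    p_i = float(_f.sf(F_i, eps * df_inter, eps * df_err2))

    ss = {
        "group": ss_group,
        "subjects_within_groups": ss_subj_within,
        "time": ss_time,
        "interaction": ss_inter,
        "time_x_subjects": ss_err2,
        "total": ss_total,
    }
    df = {
        "group": float(df_group),
        "subjects_within_groups": float(df_err1),
        "time": float(df_time),
        "interaction": float(df_inter),
        "time_x_subjects": float(df_err2),
    }
    return MixedAnovaResult(
        F_between=float(F_b),
        p_between=p_b,
        F_within=float(F_w),
        p_within=p_w,
        F_interaction=float(F_i),
        p_interaction=p_i,
        ss=ss,
        df=df,
        ms=ms,
        n_per_group={str(lab): int(c) for lab, c in zip(labels, n_g)},
    )


def mixed_anova_long(
    df: pd.DataFrame,
    dv: str,
    subject: str,
    within: str,
    between: str,
    gg_correction: bool = False,
) -> tuple[MixedAnovaResult, list]:
    """Long-format front end for :func:`mixed_anova`.

    Subjects missing any within-level (or with a non-finite value) are
    excluded; their ids are returned alongside the result.
    """
    wide = df.pivot_table(index=[subject, between], columns=within, values=dv)
    complete = wide.notna().all(axis=1)
    excluded = [idx[0] for idx, ok in complete.items() if not ok]
    wide = wide[complete]
    groups = [idx[1] for idx in wide.index]
    res = mixed_anova(wide.to_numpy(), groups, gg_correction=gg_correction)
    return res, excluded
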