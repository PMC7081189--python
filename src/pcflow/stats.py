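"""Cohort precision statistics.

The battery a paired before/after-correction cohort analysis needs:
exact McNemar on paired classifications, variance-homogeneity tests
(F-test for normal data, rank-based Levene otherwise), a Kolmogorov-Smirnov
normality gate routing parametric vs rank tests, absolute-agreement
intra-class correlation for observer variability, median-dichotomized
covariate screens with Bonferroni control, and 2x2 reclassification
summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import PCFlowError


class DegenerateDataError(PCFlowError):
    """The data carry no information for the requested statistic."""


# ---------------------------------------------------------------------------
# paired classification


@dataclass
class PairedClassification:
    """2x2 before/after counts: a normal->normal, b pathological->normal,
    c normal->pathological, d pathological->pathological."""

    a: int
    b: int
    c: int
    d: int

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class ReclassificationSummary:
    counts: PairedClassification
    pct_pathological_before: int  # rounded integer percent
    pct_pathological_after: int
    normalized_fraction: float | None  # b / (b + d); None if none pathological
    pct_normalized: int | None
    mcnemar_p: float


def mcnemar_exact(b: int, c: int) -> float:
    """Exact two-sided McNemar p-value on the discordant pair counts.

    p = min(1, 2 * P(X <= min(b, c))) with X ~ Binomial(b + c, 1/2);
    p = 1 when there are no discordant pairs.
    """
    if b < 0 or c < 0:
        raise ValueError("counts must be non-negative")
    n = b + c
    if n == 0:
        return 1.0
    return float(min(1.0, 2.0 * sps.binom.cdf(min(b, c), n, 0.5)))


def reclassification_summary(before, after) -> ReclassificationSummary:
    """Summarize paired classifications before/after correction.

    ``before`` and ``after`` are equal-length label sequences; any label
    other than "normal" counts as pathological (outside the normal Qp/Qs
    range). Percentages are rounded to integers as clinical papers print
    them; the normalized fraction is the share of initially pathological
    subjects whose corrected value is normal.
    """
    before = list(before)
    after = list(after)
    if len(before) != len(after):
        raise ValueError("before/after label vectors differ in length")
    if not before:
        raise ValueError("empty label vectors")
    path_b = np.array([lab != "normal" for lab in before])
    path_a = np.array([lab != "normal" for lab in after])
    counts = PairedClassification(
        a=int((~path_b & ~path_a).sum()),
        b=int((path_b & ~path_a).sum()),
        c=int((~path_b & path_a).sum()),
        d=int((path_b & path_a).sum()),
    )
    n = counts.n
    n_path_before = counts.b + counts.d
    if n_path_before > 0:
        frac = counts.b / n_path_before
        pct_norm = round(100.0 * frac)
    else:
        frac = None
        pct_norm = None
    return ReclassificationSummary(
        counts=counts,
        pct_pathological_before=round(100.0 * n_path_before / n),
        pct_pathological_after=round(100.0 * (counts.c + counts.d) / n),
        normalized_fraction=frac,
        pct_normalized=pct_norm,
        mcnemar_p=mcnemar_exact(counts.b, counts.c),
    )


# ---------------------------------------------------------------------------
# variability (precision) tests


def f_test_variance(x, y) -> float:
    """Two-sided F-test of equal variances, F = s_x^2 / s_y^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 or vy == 0:
        raise DegenerateDataError("zero variance: F-test undefined")
    f = vx / vy
    dist = sps.f(x.size - 1, y.size - 1)
    return float(min(1.0, 2.0 * min(dist.cdf(f), dist.sf(f))))


def levene_rank(x, y) -> float:
    """Rank-based (non-parametric) Levene test of scale.

    The pooled data are rank-transformed, then the median-centered Levene
    (Brown-Forsythe) statistic is computed on the ranks and referred to
    F(1, n - 2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("each sample needs n >= 3")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        raise DegenerateDataError("all observations tied: rank Levene undefined")
    ranks = sps.rankdata(pooled)
    rx, ry = ranks[: x.size], ranks[x.size :]
    try:
        _, p = sps.levene(rx, ry, center="median")
    except ValueError as err:  # e.g. zero spread within both groups
        raise DegenerateDataError(str(err)) from err
    return float(p)


def icc_absolute_single(ratings) -> float:
    """Two-way mixed-effects, absolute-agreement, single-measure ICC.

    ``ratings`` is an (n_subjects, 2) matrix (two readings per subject).
    From the two-way ANOVA mean squares (MSR between subjects, MSC between
    readings, MSE residual):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k/n (MSC - MSE)),  k = 2.

    Negative values are returned unclamped (systematic anti-agreement).
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2 or m.shape[1] != 2:
        raise ValueError("ratings must be an (n_subjects, 2) matrix")
    n, k = m.shape
    if n < 3:
        raise ValueError("need >= 3 subjects")
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((m - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    if np.isclose(denom, 0.0, atol=1e-300):
        raise DegenerateDataError("no variance anywhere: ICC undefined")
    return float((msr - mse) / denom)


# ---------------------------------------------------------------------------
# normality gate and location tests

NORMAL = "normal"
NON_NORMAL = "non-normal"


def ks_normality_gate(x, alpha: float = 0.05) -> str:
    """One-sample Kolmogorov-Smirnov normality gate.

    Tests against a normal distribution with the sample's own mean and SD
    (as clinical statistics software does; conservative). Returns "normal"
    iff p >= alpha. A constant sample is "non-normal" by definition.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise ValueError("need n >= 5 for the normality gate")
    sd = x.std(ddof=1)
    if sd == 0:
        return NON_NORMAL
    _, p = sps.kstest(x, "norm", args=(x.mean(), sd))
    return NORMAL if p >= alpha else NON_NORMAL


def location_tests(x, y, paired: bool, gate: str) -> float:
    """Two-sided location comparison dispatched on the normality gate.

    normal -> paired/unpaired t-test; non-normal -> Wilcoxon signed-rank
    (paired) or Mann-Whitney U (unpaired). Identical paired samples (all
    differences zero) return p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired and x.size != y.size:
        raise ValueError("paired samples must have equal length")
    if x.size < 2 or y.size < 2:
        raise ValueError("samples too small")
    if gate not in (NORMAL, NON_NORMAL):
        raise ValueError(f"unknown gate result {gate!r}")
    if paired and np.all(x == y):
        return 1.0
    if gate == NORMAL:
        res = sps.ttest_rel(x, y) if paired else sps.ttest_ind(x, y)
    else:
        if paired:
            res = sps.wilcoxon(x, y, zero_method="wilcox")
        else:
            res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# covariate screen

BONFERRONI_M = 20
ALPHA = 0.05


def covariate_precision_screen(
    table: pd.DataFrame,
    covariates: list[str],
    value_col: str,
    m: int = BONFERRONI_M,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Test whether any covariate is associated with Qp/Qs variability.

    Each covariate is dichotomized at its median (ties assigned to the low
    group; binary covariates split by value), and the spread of
    ``value_col`` is compared between groups with the gated variance test:
    F-test if both groups pass the KS normality gate, rank Levene otherwise.
    Significance is Bonferroni-controlled at alpha/m (0.05/20 = 0.0025 at
    the defaults). Covariates leaving < 3 subjects in a group are skipped
    with a warning.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    threshold = alpha / m
    rows = []
    values = table[value_col].to_numpy(dtype=float)
    for cov in covariates:
        v = table[cov].to_numpy(dtype=float)
        uniq = np.unique(v)
        if uniq.size <= 2:
            low = v == uniq[0]
        else:
            low = v <= np.median(v)
        high = ~low
        row = {
            "covariate": cov,
            "n_low": int(low.sum()),
            "n_high": int(high.sum()),
            "test": None,
            "p_value": np.nan,
            "significant": False,
            "alpha_adjusted": threshold,
            "skipped": False,
        }
        if low.sum() < 3 or high.sum() < 3:
            warnings.warn(
                f"covariate {cov!r}: degenerate median split "
                f"({int(low.sum())} vs {int(high.sum())}); skipped",
                stacklevel=2,
            )
            row["skipped"] = True
            rows.append(row)
            continue
        g_lo, g_hi = values[low], values[high]
        gates_normal = (
            ks_normality_gate(g_lo) == NORMAL and ks_normality_gate(g_hi) == NORMAL
            if min(low.sum(), high.sum()) >= 5
            else False
        )
        try:
            if gates_normal:
                row["test"] = "F-test"
                row["p_value"] = f_test_variance(g_lo, g_hi)
            else:
                row["test"] = "rank-Levene"
                row["p_value"] = levene_rank(g_lo, g_hi)
        except DegenerateDataError as err:
            warnings.warn(f"covariate {cov!r}: {err}; skipped", stacklevel=2)
            row["skipped"] = True
            rows.append(row)
            continue
        row["significant"] = bool(row["p_value"] < threshold)
        rows.append(row)
    return pd.DataFrame(rows)
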