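"""Rater-agreement and validation statistics.

Implements the battery used to validate an instrumented facial grading
method against clinician scales: Spearman rank correlation, Bland–Altman
agreement (bias, SD of the bias, 95 % limits of agreement), intraclass
correlation from a two-way (subjects × measurements) ANOVA — absolute
agreement and consistency, single and average measures — Cronbach α, the
conventional interpretation bins, and a Shapiro–Wilk-gated paired change
test (paired t vs Wilcoxon signed-rank).

The base significance tests (Shapiro–Wilk, paired t, Wilcoxon, Spearman)
are delegated to :mod:`scipy.stats`; the ICC/α decomposition and the gating
and reporting logic are implemented here.

ICC forms, from the two-way mean squares MSR (rows/subjects), MSC
(columns/measurements), MSE (residual) with n subjects and k measurements::

    consistency, single   (MSR - MSE) / (MSR + (k-1) MSE)
    consistency, average  (MSR - MSE) / MSR                    == Cronbach α
    absolute,    single   (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    absolute,    average  (MSR - MSE) / (MSR + (MSC - MSE) / n)
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


class AgreementError(ValueError):
    pass


#: Conventional 95 % limits-of-agreement multiplier.
LOA_MULTIPLIER = 1.96


class ICCType(str, enum.Enum):
    ABSOLUTE_AGREEMENT = "absolute_agreement"
    CONSISTENCY = "consistency"


class ICCUnit(str, enum.Enum):
    SINGLE = "single"
    AVERAGE = "average"


@dataclass
class RaterTable:
    """Complete n subjects × k measurements matrix (raters or repeats)."""

    values: np.ndarray
    subject_ids: list[str] = field(default_factory=list)
    measurement_labels: list[str] = field(default_factory=list)
    scale: str | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise AgreementError("rater table must be 2-dimensional")
        n, k = arr.shape
        if n < 2 or k < 2:
            raise AgreementError("need at least 2 subjects and 2 measurements")
        if np.isnan(arr).any():
            raise AgreementError(
                "rater table has missing cells; apply listwise deletion upstream"
            )
        self.values = arr
        if not self.subject_ids:
            self.subject_ids = [f"s{i + 1}" for i in range(n)]
        if not self.measurement_labels:
            self.measurement_labels = [f"m{j + 1}" for j in range(k)]
        if len(self.subject_ids) != n or len(self.measurement_labels) != k:
            raise AgreementError("id/label lengths do not match the matrix")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, scale: str | None = None) -> "RaterTable":
        """Build from a DataFrame whose index is subjects and columns are
        measurements; rows with any missing cell are dropped (listwise)."""
        complete = df.dropna(axis=0, how="any")
        if len(complete) < len(df):
            dropped = len(df) - len(complete)
            import logging

            logging.getLogger(__name__).info(
                "listwise deletion dropped %d incomplete subject(s)", dropped
            )
        return cls(
            values=complete.to_numpy(dtype=float),
            subject_ids=[str(i) for i in complete.index],
            measurement_labels=[str(c) for c in complete.columns],
            scale=scale,
        )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class BlandAltmanReport:
    bias: float
    sd_bias: float
    loa_low: float
    loa_high: float
    n_outside: int
    n: int

    def __str__(self) -> str:
        return (
            f"bias {self.bias:.2f}, SD {self.sd_bias:.2f}, "
            f"LoA [{self.loa_low:.2f}, {self.loa_high:.2f}], "
            f"{self.n_outside}/{self.n} outside"
        )


@dataclass(frozen=True)
class ICCReport:
    icc_value: float
    model: str
    type: ICCType
    unit: ICCUnit
    label: str
    cronbach_alpha: float
    alpha_label: str
    p_value: float
    significant: bool
    degenerate: bool = False


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (mid-ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise AgreementError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise AgreementError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AgreementError("zero rank variance: a vector is constant")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def bland_altman(
    method_a: Sequence[float],
    method_b: Sequence[float],
    *,
    loa_multiplier: float = LOA_MULTIPLIER,
) -> BlandAltmanReport:
    """Bland–Altman agreement of two paired measurement methods.

    Differences are ``method_a − method_b``; with the instrumented score as
    method A, a positive bias means it reads systematically higher (more
    optimistic) than the comparator.
    """
    a = np.asarray(method_a, dtype=float)
    b = np.asarray(method_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise AgreementError("paired vectors must have equal length")
    if len(a) < 2:
        raise AgreementError("need at least 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    lo = bias - loa_multiplier * sd
    hi = bias + loa_multiplier * sd
    outside = int(np.sum((d < lo) | (d > hi)))
    return BlandAltmanReport(
        bias=bias, sd_bias=sd, loa_low=lo, loa_high=hi, n_outside=outside, n=len(a)
    )


def bland_altman_plot(
    method_a: Sequence[float],
    method_b: Sequence[float],
    *,
    ax=None,
    label_a: str = "A",
    label_b: str = "B",
):
    """Differences-vs-means agreement plot with bias and LoA lines."""
    import matplotlib.pyplot as plt

    report = bland_altman(method_a, method_b)
    a = np.asarray(method_a, dtype=float)
    b = np.asarray(method_b, dtype=float)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((a + b) / 2.0, a - b, s=18, alpha=0.7)
    ax.axhline(report.bias, color="k", lw=1.2, label=f"bias {report.bias:.2f}")
    for y in (report.loa_low, report.loa_high):
        ax.axhline(y, color="r", ls="--", lw=1.0)
    ax.set_xlabel(f"mean of {label_a} and {label_b}")
    ax.set_ylabel(f"{label_a} − {label_b}")
    ax.legend(loc="best", frameon=False)
    return ax, report


def _two_way_mean_squares(values: np.ndarray) -> tuple[float, float, float]:
    """MSR, MSC, MSE of the subjects × measurements two-way decomposition."""
    n, k = values.shape
    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_total = float(np.sum((values - grand) ** 2))
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_two_way(
    table: RaterTable,
    type: ICCType | str = ICCType.ABSOLUTE_AGREEMENT,
    unit: ICCUnit | str = ICCUnit.AVERAGE,
    *,
    alpha: float = 0.05,
) -> ICCReport:
    """Two-way mixed-model intraclass correlation with F-test p-value,
    Cronbach α, and interpretation labels."""
    type = ICCType(type)
    unit = ICCUnit(unit)
    vals = table.values
    n, k = vals.shape
    msr, msc, mse = _two_way_mean_squares(vals)

    degenerate = msr <= mse or math.isclose(msr, 0.0, abs_tol=1e-30)
    if math.isclose(float(np.var(vals.mean(axis=1))), 0.0, abs_tol=1e-24):
        # no between-subject variance at all
        icc = 0.0
        degenerate = True
    elif type == ICCType.CONSISTENCY and unit == ICCUnit.SINGLE:
        icc = (msr - mse) / (msr + (k - 1) * mse)
    elif type == ICCType.CONSISTENCY and unit == ICCUnit.AVERAGE:
        icc = (msr - mse) / msr
    elif type == ICCType.ABSOLUTE_AGREEMENT and unit == ICCUnit.SINGLE:
        icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    else:
        icc = (msr - mse) / (msr + (msc - mse) / n)

    if mse <= 0:
        # perfect-fit table (e.g. identical raters): F is infinite, p -> 0
        p = 0.0 if msr > 0 else 1.0
    else:
        f_stat = msr / mse
        p = float(stats.f.sf(f_stat, n - 1, (n - 1) * (k - 1)))

    try:
        ca = cronbach_alpha(table)
        ca_label = classify_alpha(ca)
    except AgreementError:
        ca, ca_label = float("nan"), "undefined"
    return ICCReport(
        icc_value=float(icc),
        model="two-way mixed",
        type=type,
        unit=unit,
        label=classify_icc(icc),
        cronbach_alpha=ca,
        alpha_label=ca_label,
        p_value=p,
        significant=p < alpha,
        degenerate=degenerate and icc <= 0,
    )


def cronbach_alpha(table: RaterTable) -> float:
    """Cronbach α = k/(k−1) × (1 − Σ column variances / variance of row sums).

    Algebraically identical to the consistency / average-measures ICC.
    """
    vals = table.values
    n, k = vals.shape
    item_vars = vals.var(axis=0, ddof=1)
    total_var = vals.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise AgreementError("zero total variance: Cronbach alpha undefined")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def classify_icc(icc: float) -> str:
    """Cicchetti interpretation bins for ICC."""
    if not math.isfinite(icc):
        raise AgreementError("ICC must be finite")
    if icc >= 0.75:
        return "excellent"
    if icc >= 0.6:
        return "good"
    if icc >= 0.4:
        return "fair"
    return "unacceptable"


def classify_alpha(alpha: float) -> str:
    """Interpretation bins for Cronbach α."""
    if not math.isfinite(alpha):
        raise AgreementError("alpha must be finite")
    if alpha >= 0.9:
        return "excellent"
    if alpha >= 0.8:
        return "good"
    if alpha >= 0.7:
        return "fair"
    return "unacceptable"


def paired_change_test(
    pre: Sequence[float],
    post: Sequence[float],
    *,
    normality_alpha: float = 0.05,
) -> dict:
    """Pre/post comparison with a normality-gated test choice.

    Shapiro–Wilk on the paired differences decides the test: normal
    (p ≥ ``normality_alpha``) → paired t test, otherwise Wilcoxon
    matched-pairs signed-rank.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise AgreementError("pre and post must be equal-length vectors")
    if len(pre) < 3:
        raise AgreementError("need at least 3 pairs")
    d = post - pre
    if np.all(d == 0):
        raise AgreementError("degenerate differences: all pre/post pairs identical")
    sw_stat, sw_p = stats.shapiro(d)
    if sw_p >= normality_alpha:
        res = stats.ttest_rel(post, pre)
        test_used = "paired t"
    else:
        res = stats.wilcoxon(post, pre)
        test_used = "Wilcoxon signed-rank"
    return {
        "test_used": test_used,
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "shapiro_w": float(sw_stat),
        "shapiro_p": float(sw_p),
        "n": int(len(pre)),
    }
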