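"""Diagnostic and agreement statistics for the response analysis.

Confusion-table metrics (reported as integer percentages with retained
fractions), single-operating-point AUC for binary criteria, empirical ROC
with Youden-index cutoff and DeLong confidence intervals, paired DeLong AUC
comparison, two-way mixed absolute-agreement ICC (McGraw–Wong A,1) with
F-based confidence interval, weighted kappa, Shapiro–Wilk-gated two-group
tests, and Kaplan–Meier curves with the log-rank test.

The empirical AUC equals the Mann–Whitney U statistic normalized by the
product of class sizes, ties counted with half weight. The Youden cutoff is
the midpoint between adjacent sorted unique scores maximizing
sensitivity + specificity − 1; ties break toward higher specificity. Marker
direction is declared, not auto-detected: percent ADC increases are
"greater-positive", energy decreases are "less-positive".
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats
from sklearn.metrics import cohen_kappa_score

from .errors import DomainError

__all__ = [
    "ConfusionTable",
    "GroupComparison",
    "ICCResult",
    "KMGroup",
    "KMResult",
    "ROCResult",
    "binary_marker_auc",
    "confusion_metrics",
    "delong_compare",
    "empirical_roc",
    "group_compare",
    "icc_two_way_mixed_absolute",
    "km_logrank",
    "weighted_kappa",
]


# ---------------------------------------------------------------------------
# confusion arithmetic
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionTable:
    """TP/FP/TN/FN counts; positive = major pathological response."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise DomainError("confusion counts must be non-negative")
        if self.total == 0:
            raise DomainError("confusion table must be non-empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_labels(cls, predicted, truth) -> "ConfusionTable":
        p = np.asarray(predicted, dtype=bool)
        t = np.asarray(truth, dtype=bool)
        return cls(
            tp=int((p & t).sum()),
            fp=int((p & ~t).sum()),
            tn=int((~p & ~t).sum()),
            fn=int((~p & t).sum()),
        )


@dataclass(frozen=True)
class MetricValue:
    """A ratio metric keeping its printed fraction form."""

    numerator: int
    denominator: int

    @property
    def fraction(self) -> float | None:
        if self.denominator == 0:
            return None
        return self.numerator / self.denominator

    @property
    def percent(self) -> int | None:
        """Integer percent, rounded half-up (report parity)."""
        if self.denominator == 0:
            return None
        return int(math.floor(100.0 * self.numerator / self.denominator + 0.5))

    def __str__(self) -> str:
        if self.denominator == 0:
            return "undefined"
        return f"{self.percent} ({self.numerator}/{self.denominator})"


def confusion_metrics(ct: ConfusionTable) -> dict[str, MetricValue]:
    """Sensitivity, specificity, PPV, NPV and accuracy with retained fractions."""
    return {
        "sensitivity": MetricValue(ct.tp, ct.tp + ct.fn),
        "specificity": MetricValue(ct.tn, ct.tn + ct.fp),
        "ppv": MetricValue(ct.tp, ct.tp + ct.fp),
        "npv": MetricValue(ct.tn, ct.tn + ct.fn),
        "accuracy": MetricValue(ct.tp + ct.tn, ct.total),
    }


def binary_marker_auc(ct: ConfusionTable) -> float:
    """Trapezoidal AUC of a single-operating-point ROC: (sens + spec) / 2."""
    if ct.tp + ct.fn == 0 or ct.tn + ct.fp == 0:
        raise DomainError("both classes must be present")
    sens = ct.tp / (ct.tp + ct.fn)
    spec = ct.tn / (ct.tn + ct.fp)
    return 0.5 * (sens + spec)


# ---------------------------------------------------------------------------
# empirical ROC / DeLong
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ROCResult:
    auc: float
    ci95: tuple[float, float]
    youden_cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float
    direction: str  # "greater-positive" | "less-positive"


def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    ranks = np.empty(n, dtype=float)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n, dtype=float)
    out[order] = ranks
    return out


def _delong_structures(scores: np.ndarray, labels: np.ndarray):
    """AUC and DeLong structural components (V10 per positive, V01 per negative)."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise DomainError("both classes must be present")
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return float(auc), v10, v01


def _auc_variance(v10: np.ndarray, v01: np.ndarray) -> float:
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def empirical_roc(
    scores: Sequence[float],
    labels: Sequence[bool],
    direction: str = "greater-positive",
) -> ROCResult:
    """Empirical ROC with DeLong CI and exhaustive Youden-cutoff scan."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if direction not in ("greater-positive", "less-positive"):
        raise DomainError("direction must be 'greater-positive' or 'less-positive'")
    if len(np.unique(s)) < 2:
        raise DomainError("at least two distinct scores are required")
    flip = direction == "less-positive"
    work = -s if flip else s
    auc, v10, v01 = _delong_structures(work, y)
    se = math.sqrt(max(_auc_variance(v10, v01), 0.0))
    ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))

    u = np.unique(work)
    cands = 0.5 * (u[:-1] + u[1:])
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    best = None
    for t in cands:
        pred = work > t
        sens = (pred & y).sum() / n_pos
        spec = (~pred & ~y).sum() / n_neg
        j = sens + spec - 1.0
        key = (j, spec, t)  # ties -> higher specificity, then higher threshold
        if best is None or key > best[0]:
            best = (key, t, sens, spec)
    _, cutoff, sens, spec = best
    if flip:
        cutoff = -cutoff
    return ROCResult(auc, ci, float(cutoff), float(sens), float(spec), direction)


def delong_compare(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[bool],
) -> float:
    """Two-sided DeLong test p-value for a paired AUC difference."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if a.shape != b.shape or a.shape != y.shape:
        raise DomainError("paired scores must share the lesion set")
    auc_a, v10a, v01a = _delong_structures(a, y)
    auc_b, v10b, v01b = _delong_structures(b, y)
    diff = auc_a - auc_b
    if diff == 0.0:
        return 1.0
    m, n = len(v10a), len(v01a)
    s10 = np.cov(v10a, v10b, ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01a, v01b, ddof=1) if n > 1 else np.zeros((2, 2))
    var = (
        s10[0, 0] / m + s10[1, 1] / m - 2 * s10[0, 1] / m
        + s01[0, 0] / n + s01[1, 1] / n - 2 * s01[0, 1] / n
    )
    if var <= 0 or not np.isfinite(var):
        warnings.warn("degenerate DeLong variance; p-value undefined", stacklevel=2)
        return float("nan")
    z = diff / math.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# agreement
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ICCResult:
    value: float
    ci95: tuple[float, float]
    defined: bool = True


def icc_two_way_mixed_absolute(ratings: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """Single-measure absolute-agreement ICC (McGraw–Wong A,1) for n items x k raters.

    Computed from the two-way ANOVA mean squares with an F-distribution
    confidence interval. Zero between-item variance makes the coefficient
    undefined; it is reported as 0 and flagged.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise DomainError("ratings must be an (n >= 3) x (k >= 2) matrix")
    if not np.all(np.isfinite(x)):
        raise DomainError("ratings must not contain missing cells")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or not np.isfinite(denom):
        warnings.warn("zero between-item variance; ICC undefined (0 by convention)",
                      stacklevel=2)
        return ICCResult(0.0, (float("nan"), float("nan")), defined=False)
    icc = (msr - mse) / denom

    # McGraw & Wong F-based bounds with Satterthwaite degrees of freedom
    r = icc
    if mse <= 0:
        return ICCResult(float(icc), (float(icc), float(icc)))
    a = (k * r) / (n * (1.0 - r)) if r < 1 else np.inf
    b = 1.0 + (k * r * (n - 1.0)) / (n * (1.0 - r)) if r < 1 else np.inf
    if not np.isfinite(a) or not np.isfinite(b):
        return ICCResult(float(icc), (float(icc), 1.0))
    num_v = (a * msc + b * mse) ** 2
    den_v = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num_v / den_v if den_v > 0 else (n - 1) * (k - 1)
    f_low = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_up = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_low * mse) / (
        f_low * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_up * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_up * msr
    )
    return ICCResult(float(icc), (float(lower), float(upper)))


def weighted_kappa(
    cat_reader1: Sequence,
    cat_reader2: Sequence,
    categories: Sequence | None = None,
    weights: str = "linear",
) -> float:
    """Weighted kappa over an ordered category set (linear weights by default)."""
    if weights not in ("linear", "quadratic"):
        raise DomainError("weights must be 'linear' or 'quadratic'")
    a = list(cat_reader1)
    b = list(cat_reader2)
    if len(a) != len(b) or len(a) < 2:
        raise DomainError("two ratings per item and n >= 2 are required")
    if categories is None:
        categories = sorted(set(a) | set(b))
    if len(set(a) | set(b)) < 2:
        warnings.warn("single observed category; kappa undefined", stacklevel=2)
        return float("nan")
    return float(
        cohen_kappa_score(a, b, labels=list(categories), weights=weights)
    )


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KMGroup:
    label: str
    n: int
    n_events: int
    median_months: float
    milestone_rates: Mapping[float, float]
    curve: pd.DataFrame = field(repr=False)


@dataclass(frozen=True)
class KMResult:
    groups: Mapping[str, KMGroup]
    logrank_p: float
    logrank_stat: float


def km_logrank(
    times: Sequence[float],
    events: Sequence[bool],
    groups: Sequence[str] | None = None,
    milestones: Sequence[float] = (12.0, 36.0, 60.0),
) -> KMResult:
    """Kaplan–Meier estimates per group with a two-group log-rank test.

    The median is the first time at which survival drops to 0.5 or below
    (infinite when never reached). With no groups, a single "all" stratum is
    fitted and the log-rank fields are NaN.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0 or np.any(t < 0):
        raise DomainError("times must be non-negative and non-empty")
    if groups is None:
        groups = ["all"] * t.size
    g = np.asarray(groups)
    out: dict[str, KMGroup] = {}
    for label in pd.unique(g):
        sel = g == label
        kmf = KaplanMeierFitter()
        kmf.fit(t[sel], e[sel])
        rates = {
            float(ms): float(np.asarray(kmf.predict(ms)))
            for ms in milestones
        }
        curve = kmf.survival_function_.reset_index()
        curve.columns = ["time_months", "survival"]
        out[str(label)] = KMGroup(
            label=str(label),
            n=int(sel.sum()),
            n_events=int(e[sel].sum()),
            median_months=float(kmf.median_survival_time_),
            milestone_rates=rates,
            curve=curve,
        )
    labels = list(out)
    if len(labels) == 2 and e.sum() > 0:
        sel = g == labels[0]
        res = _lifelines_logrank(t[sel], t[~sel], e[sel], e[~sel])
        p, stat = float(res.p_value), float(res.test_statistic)
    else:
        p, stat = float("nan"), float("nan")
    return KMResult(out, p, stat)


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupComparison:
    p_value: float
    test: str
    summary_pos: str
    summary_neg: str
    mean_pos: float
    mean_neg: float
    median_pos: float
    median_neg: float


def _is_normal(x: np.ndarray, alpha: float) -> bool:
    if x.size < 3 or np.ptp(x) == 0:
        return False
    return bool(stats.shapiro(x).pvalue >= alpha)


def _fmt(x: np.ndarray, normal: bool) -> str:
    if normal:
        return f"{x.mean():.4g} ± {x.std(ddof=1):.4g}"
    q25, med, q75 = np.percentile(x, [25, 50, 75])
    return f"{med:.4g} ({q25:.4g}–{q75:.4g})"


def group_compare(
    values: Sequence[float], labels: Sequence[bool], alpha: float = 0.05
) -> GroupComparison:
    """MPR-vs-non-MPR style comparison with a Shapiro–Wilk-gated test.

    Both groups normal (Shapiro–Wilk p >= alpha, n >= 3 each): Student's
    t-test; otherwise Mann–Whitney U.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    pos, neg = v[y], v[~y]
    if pos.size == 0 or neg.size == 0:
        raise DomainError("both groups must be non-empty")
    pos_norm, neg_norm = _is_normal(pos, alpha), _is_normal(neg, alpha)
    if pos_norm and neg_norm:
        test = "Student t"
        p = float(stats.ttest_ind(pos, neg, equal_var=True).pvalue)
    else:
        test = "Mann–Whitney U"
        p = float(stats.mannwhitneyu(pos, neg, alternative="two-sided").pvalue)
    return GroupComparison(
        p_value=p,
        test=test,
        summary_pos=_fmt(pos, pos_norm),
        summary_neg=_fmt(neg, neg_norm),
        mean_pos=float(pos.mean()),
        mean_neg=float(neg.mean()),
        median_pos=float(np.median(pos)),
        median_neg=float(np.median(neg)),
    )
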