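"""First-order whole-tumor histogram features of an ADC map.

Eighteen intensity statistics computed over the multiset of in-mask voxel
values: mean, median, 10th/90th percentiles, min, max, interquartile range,
range, variance (population, denominator N), mean absolute deviation (MAD),
robust MAD (restricted to values within [p10, p90]), root mean square,
energy (sum of squares), total energy (energy x voxel volume in mm^3),
entropy (bits) and uniformity over a fixed-bin-width histogram anchored at
the in-mask minimum, Fisher–Pearson skewness, and non-excess kurtosis
(normal = 3; the non-excess convention matches clinical ADC reporting,
where kurtosis values cluster near 3 rather than 0).

Percentiles use linear interpolation between order statistics. A degenerate
(single-voxel or zero-variance) mask yields variance 0 and, by convention,
skewness and kurtosis 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError
from .synthgen import ADCVolume

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "extract_first_order",
    "summarize_pre_post",
]

FEATURE_NAMES = (
    "mean",
    "median",
    "p10",
    "p90",
    "min",
    "max",
    "iqr",
    "range",
    "variance",
    "mad",
    "rmad",
    "rms",
    "energy",
    "total_energy",
    "entropy",
    "skewness",
    "kurtosis",
    "uniformity",
)

DEFAULT_BIN_WIDTH = 25.0  # 1e-6 mm^2/s; conventional fixed bin width for ADC maps


@dataclass(frozen=True)
class FeatureVector:
    mean: float
    median: float
    p10: float
    p90: float
    min: float
    max: float
    iqr: float
    range: float
    variance: float
    mad: float
    rmad: float
    rms: float
    energy: float
    total_energy: float
    entropy: float
    skewness: float
    kurtosis: float
    uniformity: float
    n_voxels: int = 0

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def _histogram_probs(x: np.ndarray, bin_width: float) -> np.ndarray:
    # fixed-width bins anchored at the in-mask minimum; the maximum falls in
    # its own (last) bin
    idx = np.floor((x - x.min()) / bin_width).astype(np.int64)
    counts = np.bincount(idx)
    p = counts[counts > 0] / x.size
    return p


def extract_first_order(
    volume: ADCVolume, mask: np.ndarray, bin_width: float = DEFAULT_BIN_WIDTH
) -> FeatureVector:
    """Compute the 18 first-order histogram features over in-mask voxels."""
    if bin_width <= 0:
        raise DomainError("bin_width must be positive")
    if mask.shape != volume.voxels.shape:
        raise DomainError("mask shape must equal volume shape")
    x = volume.voxels[mask.astype(bool)]
    if x.size == 0:
        raise DomainError("mask must be non-empty")
    n = x.size
    mean = float(x.mean())
    p10, q25, med, q75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    var = float(x.var(ddof=0))
    mad = float(np.mean(np.abs(x - mean)))
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.mean(np.abs(robust - robust.mean()))) if robust.size else 0.0
    energy = float(np.sum(x.astype(float) ** 2))
    rms = float(np.sqrt(energy / n))
    if var > 0:
        m2 = var
        m3 = float(np.mean((x - mean) ** 3))
        m4 = float(np.mean((x - mean) ** 4))
        skew = m3 / m2**1.5
        kurt = m4 / m2**2
    else:  # degenerate convention
        skew, kurt = 0.0, 0.0
    p = _histogram_probs(x, bin_width)
    entropy = float(-np.sum(p * np.log2(p)))
    uniformity = float(np.sum(p**2))
    return FeatureVector(
        mean=mean,
        median=float(med),
        p10=float(p10),
        p90=float(p90),
        min=float(x.min()),
        max=float(x.max()),
        iqr=float(q75 - q25),
        range=float(x.max() - x.min()),
        variance=var,
        mad=mad,
        rmad=rmad,
        rms=rms,
        energy=energy,
        total_energy=volume.voxel_volume_mm3 * energy,
        entropy=entropy,
        skewness=float(skew),
        kurtosis=float(kurt),
        uniformity=uniformity,
        n_voxels=int(n),
    )


def _normal(values: np.ndarray, alpha: float) -> bool:
    if values.size < 3 or np.ptp(values) == 0:
        return False
    return bool(stats.shapiro(values).pvalue >= alpha)


def _summary(values: np.ndarray, normal: bool) -> str:
    if normal:
        return f"{values.mean():.4g} ± {values.std(ddof=1):.4g}"
    q25, med, q75 = np.percentile(values, [25, 50, 75])
    return f"{med:.4g} ({q25:.4g}–{q75:.4g})"


def summarize_pre_post(
    features_pre: pd.DataFrame,
    features_post: pd.DataFrame,
    parameters: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired pre/post comparison table, one row per parameter.

    Rows are paired by position (equal cohort sizes required). The paired
    test is Shapiro–Wilk gated on the paired differences: normal differences
    use the paired t-test, otherwise the paired Wilcoxon signed-rank test;
    cohorts of fewer than three lesions skip normality testing and default
    to Wilcoxon. Each phase is summarized as mean ± SD when its marginal
    distribution passes Shapiro–Wilk at ``alpha``, else median (IQR).
    """
    if len(features_pre) != len(features_post):
        raise DomainError("pre and post cohorts must be paired (equal sizes)")
    if parameters is None:
        parameters = [c for c in features_pre.columns if c in features_post.columns]
    rows = []
    n = len(features_pre)
    for param in parameters:
        pre = np.asarray(features_pre[param], dtype=float)
        post = np.asarray(features_post[param], dtype=float)
        diffs = post - pre
        if np.all(diffs == 0):
            test, p_value = "none (identical)", 1.0
        elif n >= 3 and _normal(diffs, alpha):
            test = "paired t"
            p_value = float(stats.ttest_rel(post, pre).pvalue)
        else:
            test = "paired Wilcoxon"
            p_value = float(stats.wilcoxon(post, pre, zero_method="wilcox").pvalue)
        rows.append(
            {
                "parameter": param,
                "pre_summary": _summary(pre, _normal(pre, alpha)),
                "post_summary": _summary(post, _normal(post, alpha)),
                "pre_mean": pre.mean(),
                "post_mean": post.mean(),
                "pre_median": float(np.median(pre)),
                "post_median": float(np.median(post)),
                "test": test,
                "p_value": p_value,
            }
        )
    return pd.DataFrame(rows)
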