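"""Percent-change response statistics and categorical response criteria.

Δ-parameter% = (post − pre) / pre × 100 per lesion, for every ADC parameter.

mRECIST categories score the single longest diameter (SLD) of the enhancing
viable portion: CR when it vanishes, PR at ≥ 30% decrease, PD at ≥ 20%
increase, SD otherwise. LR-TR (nonviable / equivocal / viable) is carried as
a label — it is read from enhancement patterns on multiphase MRI, which is
out of scope here. The composite "LR-ADC CR" criterion upgrades LR-TR with
the ADC change: a lesion is LR-ADC CR when it is LR-TR nonviable, or LR-TR
equivocal with Δ-ADC% strictly above the cutoff (+46 for the circular-ROI
scheme, +33 for the single-slice scheme, as fixed operating points).

Pathology labels: major pathological response (MPR) at ≤ 10% viable tumor
cells, pathologic complete response (pCR) at exactly 0%.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np

from .errors import DomainError, UndefinedDeltaError

__all__ = [
    "MRECIST_CATEGORIES",
    "classify_lr_adc",
    "classify_lr_adc_cohort",
    "classify_mrecist",
    "delta_vector",
    "label_pathology",
    "patient_level_response",
    "percent_change",
    "worst_mrecist",
]

MRECIST_CATEGORIES = ("CR", "PR", "SD", "PD")  # best to worst

# fixed operating points of the composite criteria
LR_ADC_ROI_CUTOFF_PCT = 46.0
LR_ADC_SLICE_CUTOFF_PCT = 33.0


def percent_change(pre: float, post: float) -> float:
    """(post − pre) / pre × 100; undefined when pre is zero."""
    if pre == 0:
        raise UndefinedDeltaError("percent change undefined for pre-treatment value 0")
    return (post - pre) / pre * 100.0


def delta_vector(
    pre: Mapping[str, float], post: Mapping[str, float]
) -> dict[str, float]:
    """Per-parameter percent change; parameters with pre == 0 are NaN-flagged."""
    out: dict[str, float] = {}
    for key, pre_val in pre.items():
        if key not in post:
            continue
        try:
            out[key] = percent_change(float(pre_val), float(post[key]))
        except UndefinedDeltaError:
            out[key] = float("nan")
    return out


def classify_mrecist(sld_pre_mm: float, sld_post_mm: float) -> str:
    """mRECIST category from viable-tumor longest diameters."""
    if sld_pre_mm <= 0 or sld_post_mm < 0:
        raise DomainError("SLD values must be non-negative with positive baseline")
    if sld_post_mm == 0:
        return "CR"
    change = (sld_post_mm - sld_pre_mm) / sld_pre_mm
    if change <= -0.30:
        return "PR"
    if change >= 0.20:
        return "PD"
    return "SD"


def classify_lr_adc(lrtr: str, delta_pct: float, cutoff: float) -> bool:
    """Composite criterion: LR-TR nonviable, or equivocal with Δ% > cutoff.

    The inequality is strict; LR-TR viable is never a composite CR, whatever
    the ADC change.
    """
    if lrtr == "nonviable":
        return True
    if lrtr == "equivocal":
        return bool(delta_pct > cutoff)
    if lrtr == "viable":
        return False
    raise DomainError(f"unknown LR-TR category {lrtr!r}")


def label_pathology(viable_fraction: float) -> tuple[bool, bool]:
    """(is_mpr, is_pcr) from the post-treatment viable-cell fraction."""
    if not 0.0 <= viable_fraction <= 1.0:
        raise DomainError("viable fraction must be in [0, 1]")
    return viable_fraction <= 0.10, viable_fraction == 0.0


def patient_level_response(lesion_responses: Iterable[bool]) -> bool:
    """Worst-lesion rule: a patient responds iff every lesion responds."""
    responses = list(lesion_responses)
    if not responses:
        raise DomainError("at least one lesion response is required")
    return all(bool(r) for r in responses)


def worst_mrecist(categories: Iterable[str]) -> str:
    """Patient-level mRECIST: the worst category under CR < PR < SD < PD."""
    cats = list(categories)
    if not cats:
        raise DomainError("at least one lesion category is required")
    for c in cats:
        if c not in MRECIST_CATEGORIES:
            raise DomainError(f"unknown mRECIST category {c!r}")
    return max(cats, key=MRECIST_CATEGORIES.index)


def classify_lr_adc_cohort(delta_pcts: np.ndarray, lrtr: np.ndarray, cutoff: float) -> np.ndarray:
    """Vectorized composite calls for a cohort (convenience for tables)."""
    return np.array(
        [classify_lr_adc(c, d, cutoff) for c, d in zip(lrtr, delta_pcts)], dtype=bool
    )
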