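"""Three ADC measurement strategies for a segmented lesion.

1. Size-dependent circular ROIs placed in the most diffusion-restricted
   areas (operationalized as the fully-in-mask disc of minimal mean ADC on
   the largest consecutive axial slices) — recorded as ``adc_roi``.
2. The single largest cross-sectional slice trace — ``adc_slice``.
3. Whole-tumor volume extraction is handled by :mod:`adcresponse.features`.

Lesion diameter decides the number of discs: one for lesions < 2 cm, two for
2–4 cm (boundaries inclusive), three for > 4 cm, on the run of consecutive
slices maximizing total in-mask area. A voxel belongs to a disc when its
center lies within the radius in physical mm. Values from two readers are
combined by their arithmetic mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DomainError, ROIPlacementError
from .synthgen import ADCVolume

__all__ = [
    "CircularROISpec",
    "ROIMeasurement",
    "average_readers",
    "measure_adc_roi",
    "measure_adc_slice",
    "measure_case",
    "n_rois_for_size",
    "place_circular_rois",
]

DEFAULT_ROI_RADIUS_MM = 5.0


@dataclass(frozen=True)
class CircularROISpec:
    """One circular ROI: axial slice index, in-plane voxel center, radius."""

    slice_index: int
    center: tuple[int, int]
    radius_mm: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise DomainError("ROI radius must be positive")


@dataclass(frozen=True)
class ROIMeasurement:
    adc_roi: float
    adc_slice: float
    roi_specs: tuple[CircularROISpec, ...]
    largest_slice_index: int


def n_rois_for_size(diameter_cm: float) -> int:
    """Number of circular ROIs mandated by lesion size (cm)."""
    if not np.isfinite(diameter_cm) or diameter_cm <= 0:
        raise DomainError("lesion diameter must be a positive length")
    if diameter_cm < 2.0:
        return 1
    if diameter_cm <= 4.0:
        return 2
    return 3


def _disc_footprint(radius_mm: float, spacing: tuple[float, float]) -> np.ndarray:
    rx = int(np.floor(radius_mm / spacing[0]))
    ry = int(np.floor(radius_mm / spacing[1]))
    ox = np.arange(-rx, rx + 1)[:, None] * spacing[0]
    oy = np.arange(-ry, ry + 1)[None, :] * spacing[1]
    return ox**2 + oy**2 <= radius_mm**2


def _best_run(areas: np.ndarray, n: int) -> list[int]:
    """Run of n consecutive nonempty slices with maximal total area."""
    best_start, best_total = None, -1.0
    for s in range(len(areas) - n + 1):
        window = areas[s : s + n]
        if np.any(window == 0):
            continue
        total = float(window.sum())
        if total > best_total:  # strict: ties go to the lowest starting index
            best_start, best_total = s, total
    if best_start is None:
        raise ROIPlacementError(f"no run of {n} consecutive non-empty slices")
    return list(range(best_start, best_start + n))


def place_circular_rois(
    volume: ADCVolume,
    mask: np.ndarray,
    diameter_cm: float,
    radius_mm: float = DEFAULT_ROI_RADIUS_MM,
) -> list[CircularROISpec]:
    """Place size-dependent minimal-mean-ADC discs on the largest slices.

    On each of the n largest consecutive mask slices the fully-in-mask disc
    with minimal mean ADC is found by exhaustive grid search over in-mask
    centers; ties break to the smallest (slice, row, column). If no disc of
    the requested radius fits, the radius is halved once before giving up.
    """
    if not mask.any():
        raise DomainError("mask must be non-empty")
    if mask.shape != volume.voxels.shape:
        raise DomainError("mask shape must equal volume shape")
    n = n_rois_for_size(diameter_cm)
    areas = mask.sum(axis=(0, 1))
    slices = _best_run(areas, n)
    in_plane = (volume.spacing_mm[0], volume.spacing_mm[1])

    for attempt_radius in (radius_mm, radius_mm / 2.0):
        foot = _disc_footprint(attempt_radius, in_plane)
        size = int(foot.sum())
        specs: list[CircularROISpec] = []
        for s in slices:
            msk = mask[:, :, s]
            counts = ndimage.correlate(
                msk.astype(np.int64), foot.astype(np.int64), mode="constant", cval=0
            )
            valid = (counts == size) & msk
            if not valid.any():
                specs = []
                break
            sums = ndimage.correlate(
                volume.voxels[:, :, s], foot.astype(float), mode="constant", cval=0.0
            )
            means = np.where(valid, sums / size, np.inf)
            best = means.min()
            rows, cols = np.nonzero(means == best)
            specs.append(
                CircularROISpec(int(s), (int(rows[0]), int(cols[0])), attempt_radius)
            )
        if specs:
            return specs
    raise ROIPlacementError(
        f"no disc of radius {radius_mm} mm (or half) fits on slices {slices}"
    )


def _disc_values(volume: ADCVolume, spec: CircularROISpec) -> np.ndarray:
    foot = _disc_footprint(spec.radius_mm, (volume.spacing_mm[0], volume.spacing_mm[1]))
    rx, ry = (foot.shape[0] - 1) // 2, (foot.shape[1] - 1) // 2
    r, c = spec.center
    sl = volume.voxels[:, :, spec.slice_index]
    if r - rx < 0 or c - ry < 0 or r + rx >= sl.shape[0] or c + ry >= sl.shape[1]:
        raise DomainError("disc extends outside the image")
    patch = sl[r - rx : r + rx + 1, c - ry : c + ry + 1]
    return patch[foot]


def measure_adc_roi(volume: ADCVolume, specs: list[CircularROISpec]) -> float:
    """Mean over discs of per-disc mean ADC (unweighted across discs)."""
    if not specs:
        raise DomainError("at least one ROI spec is required")
    return float(np.mean([_disc_values(volume, s).mean() for s in specs]))


def measure_adc_slice(volume: ADCVolume, mask: np.ndarray) -> tuple[float, int]:
    """Mean ADC over the axial slice of maximal in-mask area (ties: lowest index)."""
    if not mask.any():
        raise DomainError("mask must be non-empty")
    areas = mask.sum(axis=(0, 1))
    s = int(np.argmax(areas))  # argmax returns the first maximum
    value = float(volume.voxels[:, :, s][mask[:, :, s]].mean())
    return value, s


def average_readers(value_reader1: float, value_reader2: float) -> float:
    if not (np.isfinite(value_reader1) and np.isfinite(value_reader2)):
        raise DomainError("reader values must be finite")
    return 0.5 * (float(value_reader1) + float(value_reader2))


def measure_case(case, radius_mm: float = DEFAULT_ROI_RADIUS_MM) -> dict:
    """Two-reader ROI and largest-slice measurements for one lesion case.

    Returns a flat record with per-reader and reader-averaged ``adc_roi`` and
    ``adc_slice`` for both phases, suitable for a measurements table.
    """
    gt = case.ground_truth
    d_cm = gt.diameter_mm / 10.0
    out: dict = {"lesion_id": gt.lesion_id, "patient_id": gt.patient_id}
    phases = {
        "pre": (case.pre_volume, case.pre_mask, case.reader2_pre_mask),
        "post": (case.post_volume, case.post_mask, case.reader2_post_mask),
    }
    for phase, (vol, mask1, mask2) in phases.items():
        per_reader_roi, per_reader_slice = [], []
        for reader, msk in ((1, mask1), (2, mask2)):
            specs = place_circular_rois(vol, msk, d_cm, radius_mm)
            roi_val = measure_adc_roi(vol, specs)
            slice_val, slice_idx = measure_adc_slice(vol, msk)
            per_reader_roi.append(roi_val)
            per_reader_slice.append(slice_val)
            out[f"{phase}_adc_roi_reader{reader}"] = roi_val
            out[f"{phase}_adc_slice_reader{reader}"] = slice_val
            if reader == 1:
                out[f"{phase}_largest_slice_index"] = slice_idx
                out[f"{phase}_n_rois"] = len(specs)
        out[f"{phase}_adc_roi"] = average_readers(*per_reader_roi)
        out[f"{phase}_adc_slice"] = average_readers(*per_reader_slice)
    return out
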