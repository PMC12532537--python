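"""Seeded synthetic cohorts of paired pre-/post-radiotherapy lesion ADC volumes.

The generator emulates the measurable structure of a preoperative-radiotherapy
HCC cohort: lesion-level apparent diffusion coefficient (ADC) distributions
that shift upward after irradiation, a positive-to-neutral skewness shift, a
larger percent ADC change in lesions with major pathological response (MPR,
<= 10% viable tumor cells), LI-RADS treatment-response (LR-TR) categories
statistically linked to viable fraction, mRECIST-style viable-diameter
changes, and piecewise-exponential recurrence-free survival.

ADC is stored internally in 1e-6 mm^2/s (the native scale of clinical ADC
maps); reporting layers divide by 1000 when a x1e-3 mm^2/s convention is
wanted.

Geometry is deliberately simple — axis-aligned ellipsoids with mild per-axis
anisotropy — because every downstream operation (disc search, slice trace,
whole-volume histogram) only needs a plausible 3D mask, not realistic lesion
shape. Each lesion carries a small low-ADC "core" cylinder representing the
most diffusion-restricted tissue; the circular-ROI search localizes there, so
the rendered core level is the ground truth for the ROI measurement scheme.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy.stats import skewnorm

from .errors import ConfigurationError, GeometryError

__all__ = [
    "ADCVolume",
    "CohortConfig",
    "LesionCase",
    "LesionGroundTruth",
    "SurvivalRecord",
    "TextureParams",
    "DEFAULT_RFS_MILESTONES",
    "LRTR_CATEGORIES",
    "generate_cohort",
    "perturb_reader_mask",
    "render_lesion_volume",
    "simulate_survival",
    "solve_milestone_hazards",
]

LRTR_CATEGORIES = ("nonviable", "equivocal", "viable")

#: (time in months, recurrence-free survival probability) milestones used to
#: calibrate the default piecewise-exponential hazard.
DEFAULT_RFS_MILESTONES = ((12.0, 0.743), (36.0, 0.543), (60.0, 0.367))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ADCVolume:
    """3D scalar ADC image (1e-6 mm^2/s) with voxel spacing in mm.

    Axial slices run along the third array axis; indices are 0-based.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels, dtype=float)
        if v.ndim != 3:
            raise ConfigurationError("ADC volume must be 3D")
        if not np.all(np.isfinite(v)):
            raise ConfigurationError("ADC volume contains non-finite voxels")
        if v.min() < 0:
            raise ConfigurationError("ADC values must be non-negative")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ConfigurationError("voxel spacing must be three positive lengths")
        object.__setattr__(self, "voxels", v)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass(frozen=True)
class LesionGroundTruth:
    """Latent truth for one lesion, shared by both imaging phases."""

    lesion_id: str
    patient_id: str
    diameter_mm: float
    viable_fraction_post: float
    is_mpr: bool
    is_pcr: bool
    true_delta_adc_pct: float
    lrtr_category: str
    sld_pre_mm: float
    sld_post_mm: float
    # per-lesion ADC anchors for the most-restricted (core) tissue
    pre_adc_roi: float
    post_adc_roi: float
    # post-treatment overall lesion diameter (tumors shrink after RT; the
    # shrinkage drives the energy / total-energy decrease)
    post_diameter_mm: float = float("nan")
    # second-reader label variants
    lrtr_category_reader2: str = ""
    sld_pre_reader2_mm: float = float("nan")
    sld_post_reader2_mm: float = float("nan")

    def __post_init__(self) -> None:
        if not 0.0 <= self.viable_fraction_post <= 1.0:
            raise ConfigurationError("viable_fraction_post must be in [0, 1]")
        if self.is_mpr != (self.viable_fraction_post <= 0.10):
            raise ConfigurationError("is_mpr must equal (viable_fraction_post <= 0.10)")
        if self.is_pcr != (self.viable_fraction_post == 0.0):
            raise ConfigurationError("is_pcr must equal (viable_fraction_post == 0)")
        if self.lrtr_category not in LRTR_CATEGORIES:
            raise ConfigurationError(f"unknown LR-TR category {self.lrtr_category!r}")
        if self.sld_pre_mm < 0 or self.sld_post_mm < 0:
            raise ConfigurationError("viable-diameter (SLD) values must be >= 0")
        if self.diameter_mm <= 0:
            raise ConfigurationError("lesion diameter must be positive")

    def diameter_for_phase(self, phase: str) -> float:
        if phase == "post" and np.isfinite(self.post_diameter_mm):
            return self.post_diameter_mm
        return self.diameter_mm

    def semiaxes_mm(self, phase: str = "pre") -> tuple[float, float, float]:
        d = self.diameter_for_phase(phase)
        return (0.50 * d, 0.45 * d, 0.40 * d)


@dataclass(frozen=True)
class LesionCase:
    """Paired pre/post volumes, masks and second-reader masks for one lesion."""

    ground_truth: LesionGroundTruth
    pre_volume: ADCVolume
    post_volume: ADCVolume
    pre_mask: np.ndarray
    post_mask: np.ndarray
    reader2_pre_mask: np.ndarray
    reader2_post_mask: np.ndarray

    def __post_init__(self) -> None:
        for mask, vol in (
            (self.pre_mask, self.pre_volume),
            (self.post_mask, self.post_volume),
            (self.reader2_pre_mask, self.pre_volume),
            (self.reader2_post_mask, self.post_volume),
        ):
            if mask.shape != vol.voxels.shape:
                raise ConfigurationError("mask shape must equal volume shape")
            if not mask.any():
                raise ConfigurationError("mask must be non-empty")


@dataclass(frozen=True)
class SurvivalRecord:
    """Time-to-recurrence (months from surgery) with censoring flag."""

    patient_id: str
    time_months: float
    event: bool
    groups: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time_months < 0:
            raise ConfigurationError("time_months must be >= 0")


@dataclass(frozen=True)
class TextureParams:
    """Voxel-level appearance of rendered lesions (all ADC offsets in 1e-6 mm^2/s).

    ``pre_bulk_offset``/``pre_bulk_scale`` control the skewed heterogeneity of
    the untreated tumor bulk above the restricted core; ``viable_offset`` and
    ``nonviable_offset`` set the two post-treatment compartments relative to
    the core level. Setting everything to zero yields piecewise-constant
    lesions (useful for degenerate/no-noise checks).
    """

    background_adc: float = 1150.0
    background_sd: float = 40.0
    core_radius_mm: float = 6.5
    core_half_height_mm: float = 8.0
    pre_bulk_offset: float = 130.0
    pre_bulk_scale: float = 220.0
    viable_offset: float = 60.0
    nonviable_offset: float = 100.0
    post_bulk_scale: float = 140.0
    margin_mm: float = 9.0


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the reference clinical cohort this package models:
    35 patients with 38 lesions, MPR prevalence 12/38 (half of MPR lesions in
    pathologic complete response), post-RT core ADC 1.45 +/- 0.28 x1e-3
    mm^2/s, per-group percent ADC change 64.3 +/- 34.1 (MPR) vs 27.6 +/- 20.3
    (non-MPR), LR-TR frequencies 5/6/27 (nonviable/equivocal/viable) and
    mRECIST frequencies 5/14/19 (CR/PR/SD), and recurrence-free survival with
    1/3/5-year rates 74.3/54.3/36.7%.
    """

    n_patients: int = 35
    n_lesions: int | None = 38
    lesion_size_range_mm: tuple[float, float] = (30.0, 70.0)
    mpr_prevalence: float = 12 / 38
    pcr_fraction_of_mpr: float = 0.5
    pre_adc_mean_loc: float = 1070.0
    pre_adc_skewness: float = 0.48
    post_adc_roi_loc: float = 1450.0
    post_adc_roi_scale: float = 280.0
    delta_params_by_group: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"mpr": (64.3, 34.1), "non_mpr": (27.6, 20.3)}
    )
    # P(nonviable, equivocal, viable) conditional on pathology stratum
    lrtr_confusion: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "mpr": (5 / 12, 5 / 12, 2 / 12),
            "non_mpr": (0.0, 1 / 26, 25 / 26),
        }
    )
    # P(PR, SD) for lesions that are not LR-TR nonviable (nonviable -> CR)
    mrecist_probs: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"mpr": (6 / 7, 1 / 7), "non_mpr": (8 / 26, 18 / 26)}
    )
    voxel_spacing_mm: tuple[float, float, float] = (1.5, 1.5, 5.0)
    noise_sd: float = 50.0
    reader_perturbation_sd: float = 1.2  # mm of boundary jitter
    reader_sld_cv: float = 0.10
    lrtr_reader_flip_prob: float = 0.20
    survival_hazards: Mapping[str, Sequence[float]] | None = None
    survival_group_multipliers: Mapping[str, float] = field(
        default_factory=lambda: {"responder": 0.45, "non_responder": 1.40}
    )
    censor_range_months: tuple[float, float] = (36.0, 84.0)
    moment_match: bool = True
    texture: TextureParams = field(default_factory=TextureParams)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        n_lesions = self.n_lesions if self.n_lesions is not None else self.n_patients
        if n_lesions < self.n_patients:
            raise ConfigurationError("n_lesions must be >= n_patients")
        lo, hi = self.lesion_size_range_mm
        if lo <= 0 or hi <= 0 or hi < lo:
            raise ConfigurationError("lesion_size_range_mm must be positive and ordered")
        if not 0.0 <= self.mpr_prevalence <= 1.0:
            raise ConfigurationError("mpr_prevalence must be in [0, 1]")
        if not 0.0 <= self.pcr_fraction_of_mpr <= 1.0:
            raise ConfigurationError("pcr_fraction_of_mpr must be in [0, 1]")
        for grp, (loc, scale) in self.delta_params_by_group.items():
            if scale <= 0:
                raise ConfigurationError(f"delta scale for group {grp!r} must be > 0")
        if self.post_adc_roi_scale <= 0 or self.post_adc_roi_loc <= 0:
            raise ConfigurationError("post-RT core ADC location/scale must be > 0")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ConfigurationError("voxel spacing must be positive")
        if self.noise_sd < 0 or self.reader_perturbation_sd < 0:
            raise ConfigurationError("noise and perturbation SDs must be >= 0")
        if self.survival_hazards is not None:
            for grp, rates in self.survival_hazards.items():
                if any(r < 0 for r in rates):
                    raise ConfigurationError(f"hazard rates for {grp!r} must be >= 0")


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------


def _substream(seed: int, key: str, stream: int) -> np.random.Generator:
    """Per-lesion/per-purpose RNG derived by stable hashing of the string key.

    Cohort membership changes therefore do not shuffle the randomness of
    other lesions.
    """
    entropy = [int(seed) & 0x7FFFFFFF, zlib.crc32(key.encode("utf-8")), int(stream)]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _skewnorm_shape(target_skewness: float) -> float:
    """Invert the skew-normal skewness formula for the shape parameter."""
    g = min(abs(float(target_skewness)), 0.99)
    if g == 0.0:
        return 0.0
    g23 = g ** (2.0 / 3.0)
    c = ((4.0 - np.pi) / 2.0) ** (2.0 / 3.0)
    delta2 = (np.pi / 2.0) * g23 / (g23 + c)
    delta = np.sqrt(delta2)
    a = delta / np.sqrt(1.0 - delta2)
    return float(np.copysign(a, target_skewness))


# ---------------------------------------------------------------------------
# lesion rendering
# ---------------------------------------------------------------------------


def render_lesion_volume(
    ground_truth: LesionGroundTruth,
    phase: str,
    spacing_mm: tuple[float, float, float] = (1.5, 1.5, 5.0),
    noise_sd: float = 50.0,
    texture: TextureParams | None = None,
    pre_bulk_skewness: float = 0.48,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[ADCVolume, np.ndarray]:
    """Render one phase of a lesion as an ellipsoid in liver-like background.

    Pre-RT lesions are a positively skewed heterogeneous bulk above a low-ADC
    core cylinder pinned at ``ground_truth.pre_adc_roi``. Post-RT lesions are
    a two-compartment mixture — a viable (low-ADC) inner ellipsoid whose
    volume fraction equals ``viable_fraction_post`` and a nonviable (high-ADC)
    remainder — again with the core pinned at ``post_adc_roi``. Additive
    Gaussian noise of ``noise_sd`` is applied to the whole map.
    """
    if phase not in ("pre", "post"):
        raise ConfigurationError("phase must be 'pre' or 'post'")
    tex = texture if texture is not None else TextureParams()
    if rng is None:
        rng = np.random.default_rng(seed)
    sp = np.asarray(spacing_mm, dtype=float)
    semi = np.asarray(ground_truth.semiaxes_mm(phase), dtype=float)
    if np.any(2.0 * semi < 3.0 * sp):
        raise GeometryError(
            f"lesion {ground_truth.lesion_id}: diameter must span >= 3 voxels per axis"
        )
    shape = np.ceil((2.0 * semi + 2.0 * tex.margin_mm) / sp).astype(int)
    center = shape * sp / 2.0

    axes = [(np.arange(shape[i]) + 0.5) * sp[i] - center[i] for i in range(3)]
    dx = axes[0][:, None, None]
    dy = axes[1][None, :, None]
    dz = axes[2][None, None, :]
    mask = (dx / semi[0]) ** 2 + (dy / semi[1]) ** 2 + (dz / semi[2]) ** 2 <= 1.0
    if not mask.any():
        raise GeometryError("lesion mask is empty at this spacing")

    core = (
        (dx**2 + dy**2 <= tex.core_radius_mm**2)
        & (np.abs(dz) <= tex.core_half_height_mm)
        & mask
    )
    if not core.any():
        core = mask  # tiny lesion: the whole lesion is "core"

    vol = tex.background_adc + tex.background_sd * rng.standard_normal(mask.shape)

    if phase == "pre":
        level = ground_truth.pre_adc_roi
        # the bulk target sits above the lesion-level target because the
        # low-ADC core lump dilutes the sample skewness of the whole lesion
        shape_a = _skewnorm_shape(min(1.6 * pre_bulk_skewness, 0.95))
        if tex.pre_bulk_scale > 0:
            bulk = level + tex.pre_bulk_offset + skewnorm.rvs(
                shape_a,
                scale=tex.pre_bulk_scale,
                size=int(mask.sum()),
                random_state=rng,
            )
        else:
            bulk = np.full(int(mask.sum()), level + tex.pre_bulk_offset)
        vol[mask] = bulk
        vol[core] = level
    else:
        level = ground_truth.post_adc_roi
        f = ground_truth.viable_fraction_post
        inner_scale = f ** (1.0 / 3.0) if f > 0 else 0.0
        if inner_scale > 0:
            viable = (
                (dx / (inner_scale * semi[0])) ** 2
                + (dy / (inner_scale * semi[1])) ** 2
                + (dz / (inner_scale * semi[2])) ** 2
            ) <= 1.0
            viable &= mask
        else:
            viable = np.zeros_like(mask)
        # draw both compartments for every lesion voxel so that increasing the
        # viable fraction only re-labels voxels (monotone coupling)
        n_in = int(mask.sum())
        nonviable_vals = level + tex.nonviable_offset + tex.post_bulk_scale * rng.standard_normal(n_in)
        viable_vals = level + tex.viable_offset + 0.5 * tex.post_bulk_scale * rng.standard_normal(n_in)
        lesion_vals = np.where(viable[mask], viable_vals, nonviable_vals)
        vol[mask] = lesion_vals
        vol[core] = level

    if noise_sd > 0:
        vol = vol + noise_sd * rng.standard_normal(mask.shape)
    vol = np.clip(vol, 0.0, None)
    return ADCVolume(vol, tuple(sp)), mask


def perturb_reader_mask(
    mask: np.ndarray,
    perturbation_sd: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    spacing_mm: tuple[float, float, float] = (1.5, 1.5, 5.0),
) -> np.ndarray:
    """Morphological boundary jitter emulating a second reader's segmentation.

    The signed Euclidean distance to the boundary (mm) is perturbed by a
    smooth Gaussian random field scaled to ``perturbation_sd`` mm and
    re-thresholded; the largest connected component is kept. A zero SD
    returns an identical copy.
    """
    if not mask.any():
        raise ConfigurationError("mask must be non-empty")
    if perturbation_sd < 0:
        raise ConfigurationError("perturbation_sd must be >= 0")
    if perturbation_sd == 0:
        return mask.copy()
    if rng is None:
        rng = np.random.default_rng(seed)
    noise = rng.standard_normal(mask.shape)
    smooth = ndimage.gaussian_filter(noise, sigma=(2.0, 2.0, 0.8))
    sd = smooth.std()
    if sd == 0:
        return mask.copy()
    smooth /= sd
    inside = ndimage.distance_transform_edt(mask, sampling=spacing_mm)
    outside = ndimage.distance_transform_edt(~mask, sampling=spacing_mm)
    signed = inside - outside
    new = signed + perturbation_sd * smooth > 0.0
    labels, n = ndimage.label(new)
    if n == 0:
        return mask.copy()
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    new = labels == (1 + int(np.argmax(sizes)))
    return new


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


def solve_milestone_hazards(
    milestones: Sequence[tuple[float, float]] = DEFAULT_RFS_MILESTONES,
) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Piecewise-constant hazards matching survival probabilities at milestones.

    Returns ``(edges, rates)`` where ``edges`` are the interval start times
    (first is 0) and ``rates`` the per-month hazard on each interval; the last
    rate extends beyond the final milestone.
    """
    times = [t for t, _ in milestones]
    surv = [s for _, s in milestones]
    if any(t <= 0 for t in times) or times != sorted(times):
        raise ConfigurationError("milestone times must be positive and increasing")
    if any(not 0 < s <= 1 for s in surv) or surv != sorted(surv, reverse=True):
        raise ConfigurationError("milestone survival must be in (0, 1] and decreasing")
    edges = [0.0] + times[:-1]
    rates = []
    prev_t, prev_logs = 0.0, 0.0
    for t, s in milestones:
        logs = np.log(s)
        rates.append((prev_logs - logs) / (t - prev_t))
        prev_t, prev_logs = t, logs
    return tuple(edges), tuple(rates)


def _sample_piecewise_time(u: float, edges: Sequence[float], rates: Sequence[float]) -> float:
    """Invert the piecewise-exponential CDF for a uniform draw ``u``."""
    target = -np.log(u)  # exponential(1) cumulative-hazard target
    cum = 0.0
    for i, (start, rate) in enumerate(zip(edges, rates)):
        end = edges[i + 1] if i + 1 < len(edges) else np.inf
        width = end - start
        seg = rate * width
        if cum + seg >= target or (i + 1 == len(edges) and rate > 0):
            if rate == 0:
                continue
            return start + (target - cum) / rate
        cum += seg
    return np.inf  # zero hazard tail: the event never occurs


def simulate_survival(
    response_groups: Sequence[str],
    hazards: Mapping[str, Sequence[float]] | Sequence[float],
    censor_time_months: float | Sequence[float] | None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    edges: Sequence[float] = (0.0, 12.0, 36.0),
    patient_ids: Sequence[str] | None = None,
    group_key: str = "response",
) -> list[SurvivalRecord]:
    """Piecewise-exponential event times with administrative censoring.

    ``hazards`` maps each group label to per-interval rates over ``edges``
    (a plain sequence applies to every group). ``censor_time_months`` may be
    a scalar, a per-subject sequence, or None for no censoring; if the hazard
    is identically zero a subject is censored at the last interval edge.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n = len(response_groups)
    if not isinstance(hazards, Mapping):
        hazards = {g: hazards for g in set(response_groups)}
    for g, rates in hazards.items():
        if len(rates) != len(edges):
            raise ConfigurationError("one hazard rate per interval is required")
        if any(r < 0 for r in rates):
            raise ConfigurationError(f"negative hazard for group {g!r}")
    if patient_ids is None:
        patient_ids = [f"S{i:04d}" for i in range(n)]
    if censor_time_months is None:
        censor = np.full(n, np.inf)
    else:
        censor = np.broadcast_to(np.asarray(censor_time_months, dtype=float), (n,))
    records = []
    u = rng.uniform(size=n)
    for i, g in enumerate(response_groups):
        t_event = _sample_piecewise_time(u[i], edges, hazards[g])
        if t_event <= censor[i]:
            t, event = t_event, True
        else:
            t, event = censor[i], False
        if not np.isfinite(t):
            t, event = float(edges[-1]), False
        records.append(
            SurvivalRecord(patient_ids[i], float(t), bool(event), {group_key: g})
        )
    return records


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _moment_match(z: np.ndarray) -> np.ndarray:
    """Standardize draws to exact mean 0 / SD 1 (cohort-level calibration)."""
    if z.size < 2:
        return np.zeros_like(z)
    sd = z.std(ddof=0)
    if sd == 0:
        return np.zeros_like(z)
    return (z - z.mean()) / sd


def _draw_lrtr(rng: np.random.Generator, probs: Sequence[float]) -> str:
    return LRTR_CATEGORIES[int(rng.choice(3, p=np.asarray(probs) / np.sum(probs)))]


def _flip_adjacent(rng: np.random.Generator, category: str, prob: float) -> str:
    """Second-reader category: adjacent-category disagreement with given prob."""
    if rng.uniform() >= prob:
        return category
    i = LRTR_CATEGORIES.index(category)
    if i == 0:
        return LRTR_CATEGORIES[1]
    if i == 2:
        return LRTR_CATEGORIES[1]
    return LRTR_CATEGORIES[0] if rng.uniform() < 0.5 else LRTR_CATEGORIES[2]


def _sld_factor(category: str, viable_fraction: float, rng: np.random.Generator) -> float:
    """Post/pre viable-diameter ratio consistent with an mRECIST category.

    The ratio grows with the cube root of the viable fraction so that the
    residual enhancing diameter tracks the viable compartment extent.
    """
    c = viable_fraction ** (1.0 / 3.0)
    if category == "CR":
        return 0.0
    if category == "PR":
        return 0.15 + 0.55 * c + rng.uniform(-0.04, 0.04)
    # SD: change bounded away from the -30% / +20% thresholds
    return np.clip(0.78 + 0.36 * c + rng.uniform(-0.03, 0.03), 0.72, 1.17)


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[LesionCase], list[SurvivalRecord]]:
    """Generate a full synthetic cohort (lesion cases + survival records).

    Deterministic for a fixed config and seed. The number of MPR lesions is
    the nearest-integer realization of ``mpr_prevalence``; per-lesion percent
    ADC change and post-RT core level are drawn from the configured group
    distributions (cohort-level moment matched when ``moment_match`` is set,
    so the generated cohort realizes the configured summary statistics
    exactly and downstream calibration checks measure pipeline fidelity
    rather than draw noise).
    """
    config.validate()
    n_lesions = config.n_lesions if config.n_lesions is not None else config.n_patients
    seed = config.seed

    master = _substream(seed, "__cohort__", 0)
    patient_ids = [f"P{i:03d}" for i in range(config.n_patients)]
    lesion_patients = list(range(config.n_patients))
    extra = n_lesions - config.n_patients
    if extra > 0:
        lesion_patients += list(master.choice(config.n_patients, size=extra, replace=False))

    n_mpr = int(round(n_lesions * config.mpr_prevalence))
    order = master.permutation(n_lesions)
    mpr_set = set(order[:n_mpr].tolist())
    n_pcr = int(round(n_mpr * config.pcr_fraction_of_mpr))
    pcr_set = set(order[:n_pcr].tolist())

    lesion_ids = [f"L{i:03d}" for i in range(n_lesions)]

    # per-lesion latent draws from independent substreams
    z_delta = np.empty(n_lesions)
    z_post = np.empty(n_lesions)
    raw: list[dict] = []
    for i, lid in enumerate(lesion_ids):
        r = _substream(seed, lid, 1)
        diameter = r.uniform(*config.lesion_size_range_mm)
        z_delta[i] = r.standard_normal()
        z_post[i] = r.standard_normal()
        if i in pcr_set:
            vf = 0.0
        elif i in mpr_set:
            vf = r.uniform(0.01, 0.10)
        else:
            vf = r.uniform(0.15, 0.95)
        stratum = "mpr" if i in mpr_set else "non_mpr"
        lrtr = _draw_lrtr(r, config.lrtr_confusion[stratum])
        lrtr2 = _flip_adjacent(r, lrtr, config.lrtr_reader_flip_prob)
        if lrtr == "nonviable":
            mrecist = "CR"
        else:
            p_pr, p_sd = config.mrecist_probs[stratum]
            mrecist = "PR" if r.uniform() < p_pr / (p_pr + p_sd) else "SD"
        sld_pre = 0.9 * diameter
        sld_post = sld_pre * _sld_factor(mrecist, vf, r)
        # whole-lesion shrinkage after RT: strong for pathological responders
        shrink = float(np.clip(0.45 + 0.55 * vf ** (1.0 / 3.0), 0.65, 1.0))
        sld_cv = config.reader_sld_cv
        sld_pre2 = max(0.0, sld_pre * (1.0 + sld_cv * r.standard_normal()))
        sld_post2 = max(0.0, sld_post * (1.0 + sld_cv * r.standard_normal())) if sld_post > 0 else 0.0
        raw.append(
            dict(
                lesion_id=lid,
                patient_id=patient_ids[lesion_patients[i]],
                diameter_mm=diameter,
                post_diameter_mm=diameter * shrink,
                viable_fraction_post=vf,
                stratum=stratum,
                lrtr=lrtr,
                lrtr2=lrtr2,
                sld_pre=sld_pre,
                sld_post=sld_post,
                sld_pre2=sld_pre2,
                sld_post2=sld_post2,
            )
        )

    # group-calibrated percent change and post-RT core level
    delta = np.empty(n_lesions)
    for stratum, (loc, scale) in config.delta_params_by_group.items():
        idx = np.array([i for i, d in enumerate(raw) if d["stratum"] == stratum], dtype=int)
        if idx.size == 0:
            continue
        z = z_delta[idx]
        if config.moment_match:
            z = _moment_match(z)
        delta[idx] = loc + scale * z
    zp = _moment_match(z_post) if config.moment_match else z_post
    post_roi = config.post_adc_roi_loc + config.post_adc_roi_scale * zp
    post_roi = np.clip(post_roi, 500.0, 3500.0)
    delta = np.clip(delta, -85.0, 400.0)
    pre_roi = np.clip(post_roi / (1.0 + delta / 100.0), 300.0, 3500.0)

    cases: list[LesionCase] = []
    for i, d in enumerate(raw):
        gt = LesionGroundTruth(
            lesion_id=d["lesion_id"],
            patient_id=d["patient_id"],
            diameter_mm=d["diameter_mm"],
            post_diameter_mm=d["post_diameter_mm"],
            viable_fraction_post=d["viable_fraction_post"],
            is_mpr=d["viable_fraction_post"] <= 0.10,
            is_pcr=d["viable_fraction_post"] == 0.0,
            true_delta_adc_pct=float(delta[i]),
            lrtr_category=d["lrtr"],
            sld_pre_mm=d["sld_pre"],
            sld_post_mm=d["sld_post"],
            pre_adc_roi=float(pre_roi[i]),
            post_adc_roi=float(post_roi[i]),
            lrtr_category_reader2=d["lrtr2"],
            sld_pre_reader2_mm=d["sld_pre2"],
            sld_post_reader2_mm=d["sld_post2"],
        )
        pre_vol, pre_mask = render_lesion_volume(
            gt,
            "pre",
            spacing_mm=config.voxel_spacing_mm,
            noise_sd=config.noise_sd,
            texture=config.texture,
            pre_bulk_skewness=config.pre_adc_skewness,
            rng=_substream(seed, gt.lesion_id, 2),
        )
        post_vol, post_mask = render_lesion_volume(
            gt,
            "post",
            spacing_mm=config.voxel_spacing_mm,
            noise_sd=config.noise_sd,
            texture=config.texture,
            pre_bulk_skewness=config.pre_adc_skewness,
            rng=_substream(seed, gt.lesion_id, 3),
        )
        r2_pre = perturb_reader_mask(
            pre_mask,
            config.reader_perturbation_sd,
            rng=_substream(seed, gt.lesion_id, 4),
            spacing_mm=config.voxel_spacing_mm,
        )
        r2_post = perturb_reader_mask(
            post_mask,
            config.reader_perturbation_sd,
            rng=_substream(seed, gt.lesion_id, 5),
            spacing_mm=config.voxel_spacing_mm,
        )
        cases.append(
            LesionCase(gt, pre_vol, post_vol, pre_mask, post_mask, r2_pre, r2_post)
        )

    # patient-level survival: responder = every lesion in MPR
    if config.survival_hazards is not None:
        hazards = {g: tuple(r) for g, r in config.survival_hazards.items()}
        edges: Sequence[float] = (0.0, 12.0, 36.0)
    else:
        edges, base = solve_milestone_hazards(DEFAULT_RFS_MILESTONES)
        hazards = {
            g: tuple(m * r for r in base)
            for g, m in config.survival_group_multipliers.items()
        }
    mpr_by_patient: dict[str, bool] = {}
    for c in cases:
        pid = c.ground_truth.patient_id
        mpr_by_patient[pid] = mpr_by_patient.get(pid, True) and c.ground_truth.is_mpr
    groups = [
        "responder" if mpr_by_patient.get(pid, False) else "non_responder"
        for pid in patient_ids
    ]
    censor_rng = _substream(seed, "__censor__", 6)
    censor = censor_rng.uniform(*config.censor_range_months, size=config.n_patients)
    records = simulate_survival(
        groups,
        hazards,
        censor_time_months=censor,
        rng=_substream(seed, "__survival__", 7),
        edges=edges,
        patient_ids=patient_ids,
        group_key="pathology_mpr",
    )
    return cases, records
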