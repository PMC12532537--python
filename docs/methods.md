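# Methods

This note documents the models, conventions and design choices behind
`adcresponse`: what the synthetic cohorts emulate, how the measurement and
evaluation layers are defined, and what the passing tests do and do not show
about real clinical data.

## Units and conventions

ADC is stored internally in 10⁻⁶ mm²/s, the native scale of clinical ADC
maps; the reporting layer divides ADC-scale location parameters (ADC_roi,
ADC_slice, mean, median, P10, P90, min, max, IQR, range) by 1000 so tables
read in the conventional ×10⁻³ mm²/s. Working on the native scale avoids
rounding artifacts in fixed-width histogram bins. Volumes are 3D arrays with
axial slices along the third axis, 0-based indices, and voxel spacing in mm
(default 1.5 × 1.5 × 5 mm, typical axial liver DWI).

## Synthetic cohort model

The generator's defaults are the study conditions of the reference clinical
cohort the package models: 35 patients / 38 lesions, MPR prevalence 12/38
with half of MPR lesions in pathologic complete response, lesion diameters
uniform on 30–70 mm (median 50 mm), LR-TR frequencies 5/6/27
(nonviable/equivocal/viable) and mRECIST frequencies 5/14/19 (CR/PR/SD)
arising from category-assignment probabilities conditioned on the pathology
stratum, per-group percent ADC change 64.3 ± 34.1 (MPR) vs 27.6 ± 20.3
(non-MPR), post-RT ADC_roi level 1450 ± 280 (10⁻⁶ mm²/s), and
recurrence-free survival hitting 74.3/54.3/36.7% at 1/3/5 years.

**Anchoring.** The published pre-RT level (1.07), post-RT level (1.45,
×10⁻³ mm²/s) and group Δ% means (lesion-weighted 39.2%) are mutually
inconsistent if pre-RT level and Δ% were independent (1.07 × 1.392 ≈ 1.49).
Real cohorts resolve this through a negative correlation between baseline
ADC and percent change (a smaller denominator inflates Δ%). The generator
therefore anchors the *post*-RT core level per lesion,
`post ~ N(1450, 280)`, draws Δ% from the pathology-group distribution, and
derives `pre = post / (1 + Δ/100)`. Both the post-RT level and the group Δ%
means are then simultaneously recoverable; the implied pre-RT cohort mean
(≈ 1.04 ×10⁻³) sits slightly below the published 1.07, which is the price of
consistency.

**Cohort-level moment matching.** Per-lesion draws come from independent
substreams keyed by a stable hash of the lesion id (so adding or removing a
lesion does not reshuffle others). The standard-normal draws behind Δ% and
the post-RT level are affinely standardized within each pathology group so
the generated cohort realizes the configured means and SDs exactly. This is
a variance-reduction choice: downstream calibration checks then measure
pipeline fidelity (rendering + ROI search + reader averaging) rather than
raw RNG luck. Geometry, noise, labels and survival keep fully independent
substreams.

**Lesion rendering.** Lesions are axis-aligned ellipsoids (semi-axes
0.50/0.45/0.40 of the diameter — mild anisotropy; real lesions are
irregular, but every tested property only needs a plausible 3D mask) in a
liver-like background (1150 ± 40). Each lesion carries a "core" cylinder
(radius 6.5 mm, half-height 8 mm) representing its most diffusion-restricted
tissue, pinned at the lesion's pre- or post-RT anchor level; the circular-ROI
search localizes there by construction, which is what makes the ROI scheme's
ground truth well defined. Pre-RT bulk voxels add a positively skewed
skew-normal heterogeneity (+130 offset, scale 220) above the core — whole-
lesion sample skewness lands near +0.4 for a 4 cm lesion. Post-RT lesions
are a two-compartment mixture: a viable (low-ADC, core + 60) inner ellipsoid
whose volume fraction equals the pathological viable fraction, and a
nonviable remainder (core + 100, scale 140); increasing the viable fraction
lowers the whole-lesion mean (mixture monotonicity). Post-RT lesions also
shrink (diameter factor 0.45 + 0.55·f^⅓, floored at 0.65 so the smallest
default lesions remain renderable at 5 mm slice spacing); shrinkage is what
drives the energy / total-energy decrease in responders. Additive Gaussian
noise (default SD 50) is applied to the whole map; no Rician/DWI signal
physics is modeled. The skewness *direction* after RT (decrease) is
reproduced, but not the full published magnitude (0.48 → ~0.04): with the
core pinned for measurement calibration, shrunken lesions retain a mildly
positive sample skewness (~+0.3).

**Readers.** The second reader is emulated by a smooth boundary jitter of the
segmentation (signed-distance perturbation by a Gaussian random field scaled
to 1.2 mm, largest connected component kept; Dice ≳ 0.9 for a 4 cm lesion),
a 10% CV perturbation of viable-tumor diameters, and a 20% adjacent-category
flip of LR-TR. Because both synthetic readers find the same pinned core, the
resulting ICCs (≈ 0.999) are far higher than clinical inter-observer values
(0.77–0.89): subjective ROI placement is not modeled, and passing agreement
tests says nothing about human-reader variability.

**Survival.** Event times are piecewise-exponential with hazard changes at
12 and 36 months; `solve_milestone_hazards` inverts the published milestone
survival exactly (rates ≈ 0.0248, 0.0131, 0.0163 per month). In generated
cohorts, patients whose lesions all reach MPR get a 0.45× hazard multiplier
and the rest 1.40×; administrative censoring is uniform on 36–84 months.

## Measurement layer

The ROI count rule is 1/2/3 discs for < 2 cm, 2–4 cm (both boundaries in the
2-disc class), > 4 cm, placed on the run of consecutive slices maximizing
total in-mask area (ties to the lowest starting index). "Most restricted
diffusion" is operationalized as the fully-in-mask disc (voxel centers
within the radius in physical mm; default radius 5 mm, configurable) with
minimal mean ADC, found by exhaustive convolution-based search over in-mask
centers; ties break to the smallest (slice, row, column). If no disc fits,
the radius is halved once before erroring. T2 shine-through/blackout
exclusion is not implementable without T2 images and is a documented
simplification. Readers are averaged after per-reader aggregation across
discs (order is immaterial for arithmetic means).

Feature conventions: population variance (N), linear-interpolation
percentiles, robust MAD over values within [P10, P90] about the mean of that
restricted set, energy without intensity offset, total energy = energy ×
voxel volume in mm³, entropy/uniformity over fixed-width bins (default
25 × 10⁻⁶ mm²/s — a conventional first-order bin width for ADC-scale maps;
the reference analysis does not state one) anchored at the in-mask minimum,
Fisher–Pearson skewness, and *non-excess* kurtosis (published values cluster
near 3, which identifies the convention). Degenerate single-voxel or
zero-variance masks report variance 0 and skewness/kurtosis 0.

## Response and evaluation layer

Δ% is undefined for a zero pre-RT value; such lesions are flagged (NaN) and
excluded from that parameter's analysis. mRECIST uses plain ±30%/+20%
thresholds on the viable diameter with no absolute-mm floor. LR-ADC uses a
strict `>` at the cutoff, matching the published "+46"/"+33" wording; a
nonviable lesion is composite-CR regardless of its Δ% (implemented as
defined). LR-TR itself is carried as a label: reading enhancement patterns
from multiphase MRI is out of scope, so the generator's confusion model
supplies the category.

Statistics: empirical AUC equals the normalized Mann–Whitney statistic with
half-weight ties; the Youden cutoff scans midpoints of adjacent sorted
unique scores, breaking ties toward higher specificity (fewer false
positives for a surgery-gating decision) and then the higher threshold.
Marker direction is declared per marker (Δ-energy%/Δ-total-energy% are
"less-positive"), never auto-detected. AUC confidence intervals and paired
AUC comparisons use DeLong's structural components; identical markers return
p = 1 and degenerate variance is flagged rather than silently zeroed. The
ICC is the single-measure absolute-agreement form from two-way mean squares
with McGraw–Wong F-based bounds (Satterthwaite degrees of freedom); zero
between-item variance reports 0 with a flag. Weighted κ defaults to linear
weights (quadratic available). Normality gates (Shapiro–Wilk at α = 0.05)
choose paired t vs Wilcoxon, and Student's t vs Mann–Whitney; groups smaller
than 3 skip normality testing and use the rank test. Reported percentages
round half-up to integers and AUCs to 3 decimals, with the underlying
fractions retained so printed values round-trip.

## Problem sizes in the checks

The reference-table check is exact arithmetic at the study scale (38
lesions). Calibration recovery renders and measures 500 lesions through the
actual ROI pipeline (≈ 10 s); recovered group means sit within one standard
error of 64.3/27.6 and the post-RT cohort mean within one SE of 1.45 ×10⁻³
mm²/s. Survival calibration uses 2000 uncensored subjects (two binomial SEs
at the 12-month milestone). Method-correctness properties use
definition-transcription oracles (features, 10⁻⁹ relative), exhaustive pair
counting and cutoff scans (n ≤ 50), brute-force disc search on small
lesions, 1000-replicate DeLong null calibration, and 2000 label permutations
for log-rank p uniformity.

## Known limitations

- Ellipsoidal geometry, pinned cores and pre-aligned pre/post volumes: no
  registration errors, irregular margins, or infiltrative growth.
- No DWI acquisition physics (b-value fitting, Rician noise, perfusion
  contamination); noise is additive Gaussian on the map.
- Inter-observer variability is mask-jitter only; synthetic ICCs are
  near-perfect and not representative of human readers.
- LR-TR and mRECIST categories are label-model outputs, not image reads.
- The published per-lesion data are unavailable, so real-data ROC values
  (e.g. continuous-marker AUCs 0.830/0.824), ICCs, κ and DeLong p-values are
  not reproduction targets; the package claims method-level correctness plus
  calibration to the published summary statistics.
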