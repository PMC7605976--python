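# Methods

## Muscle quality classification

The core computation classifies every pixel of the total abdominal muscle
area (TAMA) on an axial L3-level CT slice by its Hounsfield-unit value into
normal-attenuation muscle (NAMA, +30…+150 HU), low-attenuation muscle
(LAMA, −29…+29 HU) and inter/intramuscular adipose tissue (IMAT,
−190…−30 HU). These ranges are the thresholds conventional in CT
body-composition work for gross fat, intramyocellular-lipid-depressed
muscle and healthy muscle; they assume portal-venous-phase contrast CT and
are applied as-is to any input (the contrast-phase label from the DICOM
header is carried into the report so users can stratify).

**Rounding rule.** The ranges have inclusive *integer* endpoints and say
nothing about fractional HU (which arise with non-integer rescale slopes or
after resampling). We round half-away-from-zero to the nearest integer
before binning, which preserves the endpoints verbatim and makes the three
classes an exact partition of [−190.5, +150.5): −29.5 → −30 → IMAT,
+29.4 → +29 → LAMA. This is an implementation choice — half-open float
intervals would differ only on a measure-zero set of exact half-integers —
but it is fixed and documented so results are bit-reproducible.

**The "other" class.** TAMA pixels outside [−190, +150] (dense calcification,
metal, extreme artifacts) go to an explicit `other` class. They count inside
the TAMA area but inside none of the three components, so
NAMA + LAMA + IMAT + other = TAMA holds exactly and nothing is silently
dropped. Derived indices: SMA = NAMA + LAMA, myosteatosis = LAMA + IMAT.

**Quantification.** Area(class) = pixel count × row spacing × column
spacing / 100, in cm². Mean TAMA density averages *all* TAMA pixels
(including IMAT and other); mean SMA density averages NAMA ∪ LAMA only —
these are the two distinct density covariates used in the correlation
analysis. When SMA is empty its mean density is reported as undefined
(`null`), never as zero. The TAMA HU histogram defaults to 1 HU bins
(native HU resolution) aligned so integer HU fall at bin centers, covering
the full data range so counts always sum to the TAMA pixel count.

## I/O contracts

DICOM slices are converted raw → HU exactly once via
HU = raw × RescaleSlope + RescaleIntercept; the slice object records the
applied calibration and a guard flag. Only single-frame axial CT is
accepted; MONOCHROME1 data are inverted about the raw maximum on read.
The DICOM writer stores int16 raw values with slope 1 / intercept −1024,
quantizing HU to the nearest integer (as a scanner would); read-back is
exact for integer-valued HU. All UIDs are content-addressed (SHA-256 of the
pixel buffer), so identical slices give byte-identical files — file-level
determinism is a test target. The mask dialect is fixed:
{0 background, 1 TAMA, 2 VFA, 3 SFA}; one documented convention beats
auto-detection, and unknown codes are reported by value.

## Segmentation

Deep-learning compartment segmentation is out of scope; externally produced
masks are first-class input and are only *validated*: an empty TAMA is a
hard error (the map is undefined), and heuristic plausibility checks (>50%
of muscle pixels below −190 HU; mean muscle density outside [−50, 120] HU)
emit warnings that are never silently swallowed. The thresholds stand in
for a radiologist's visual review and are flagged as heuristic in the
warning text.

The fallback segmenter targets the phantom geometry: body = hole-filled
largest connected component above −500 HU; fat candidates = body pixels in
[−190, −30] HU; subcutaneous fat = fat components touching a 3-pixel body
rim band (the smallest band robust to one-pixel boundary noise); the muscle
ring = muscle-range ([−29, 150] HU) components on the outer edge of the
remaining core, with enclosed non-cavity pockets reclaimed as intramuscular
fat; visceral fat = the remaining interior fat. Components use 8-neighbor
connectivity, hole filling 4-neighbor — fixed for determinism. Dice overlap
(2|A∩B|/(|A|+|B|), empty-vs-empty defined as 1.0) is provided for
evaluation. This segmenter is explicitly phantom-grade: real paraspinal
anatomy, fascia and bowel contents violate its ring assumptions.

## Phantom generator

The phantom emulates what the pipeline actually consumes at L3: an
elliptical body (semi-axes 160 × 110 mm) on air, an 18 mm subcutaneous fat
layer, a 14 mm muscle ring (≈ 97 cm² muscle area, a realistic adult
cross-section at 1.5 mm × 1.5 mm spacing on a 256² grid), a 6 mm
visceral-fat lining inside the ring (mimicking the retroperitoneal fat
plane, and guaranteeing the cavity never touches muscle), and a cavity
with fat blobs (35% fill) plus organ-density background. LAMA and IMAT are
placed as compact random clusters strictly interior to the ring — fat
infiltration appears as streaks, not salt-and-pepper — at default fractions
12% / 2% of ring pixels (a healthy young-adult profile).

Per-role HU values are drawn from truncated normals confined to the role's
class bin: NAMA 55 ± 6 HU (contrast-enhanced healthy muscle, conditionally
≥ +30), LAMA 0 ± 8, IMAT −85 ± 15, subcutaneous fat −100 ± 8, visceral fat
−90 ± 8, cavity background +40 ± 15, air −1000 ± 5. Truncation makes the
noiseless ground truth *exact* — every generated pixel classifies as its
generated role — so partition tests are separated cleanly from
noise-robustness tests; class boundary leakage enters only through the
optional additive Gaussian noise (ground truth is recorded before noise).
The roles model distinct tissue states, so their within-role spreads are
tighter than the overall muscle HU spread, which is the mixture of the
three. A single seed drives geometry, HU sampling and noise through split
seed sequences, so changing the noise level does not move the geometry.

What the phantom does **not** model: real organ anatomy, partial-volume
mixing at boundaries, beam hardening, metal artifacts, non-elliptical body
habitus. Passing phantom tests therefore demonstrates the correctness of
the classification/quantification machinery and the internal consistency of
the pipeline — not clinical segmentation performance on patients.

## Cohort simulator

The cohort simulator reproduces the *design shape* of an age-stratified
body-composition study: two sexes × six age decades (20–79), with
per-cell generative means/SDs for NAMA, LAMA, IMAT, VFA and SFA. The
default muscle-component parameters follow a published healthy-cohort
profile (NAMA declining with age, LAMA and IMAT rising); the VFA/SFA
parameters are synthetic but age-plausible, since per-cell fat-area moments
were not available. Marginals are gamma distributions moment-matched to the
requested mean/SD — areas are positive and right-skewed, and the matching
keeps generative means exact where a zero-clipped normal would bias small
IMAT means upward. Dependence comes from a Gaussian copula with one shared
per-subject "adiposity" factor (default loadings: LAMA 0.6, IMAT 0.5, VFA
0.6, SFA 0.4, NAMA −0.3), which induces the positive fat–fat and negative
fat–muscle correlations seen in such data. Mean densities are derived from
the drawn composition as the pixel-count-weighted mean of representative
class HU values (55 / 0 / −85, per-subject jitter SD 2 HU) plus 1 HU
measurement noise — so the negative myosteatosis-vs-density correlation is
a structural consequence of composition, as it is in real data, not an
injected target.

## Statistics

One-way fixed-effects ANOVA is computed from the classical sum-of-squares
decomposition with the upper-tail F p-value; α defaults to .05. Degenerate
inputs are explicit: zero between- and within-group variance → F undefined
(NaN, reported as such); zero within-group variance with an effect →
F = ∞, p = 0. Pearson correlations use the t-transform for two-sided
p-values and are labelled with the magnitude bands conventional in this
literature (|r| < 0.1 negligible, 0.1–0.4 weak, 0.4–0.7 moderate, 0.7–0.9
strong, 0.9–1 very strong). The published band ranges overlap at their
endpoints; we assign ties to the *higher* band (|r| = 0.4 → moderate),
deterministically. Bands are computed from |r|; the sign is reported
separately. No multiple-testing correction is applied — matching standard
practice in these feasibility analyses — and the report notes that
p-values are nominal.

## Problem sizes and numerical choices

Phantoms are 256 × 256 at 1.5 mm spacing; robustness checks use 20 noise
seeds at 10 HU noise; statistical calibration uses 10,000 null ANOVA
simulations (4 groups × 10) and 200 simulated cohorts of 40 subjects per
decade. These sizes give stable estimates (binomial SE of the type-I rate
≈ 0.002) while keeping the full suite fast. Report serialization writes
floats at shortest round-tripping precision, so JSON/CSV round trips are
lossless. All randomness flows from explicit integer seeds via NumPy seed
sequences.

## Known limitations

- Thresholds are not recalibrated for non-contrast or dual-energy CT.
- Single-slice only: no volumetric extension, no L3 auto-selection.
- The fallback segmenter fails on anatomy that breaks its ring geometry;
  it exists to exercise the pipeline, not to replace a trained model.
- The cohort simulator's correlation structure is a one-factor model; real
  body-composition covariance is richer.
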