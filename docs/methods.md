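# Methods

This note records the models, conventions and numerical choices behind
`arterymorph`, in the order the pipeline runs.

## Phantom generator (synthgen)

Phantoms are 8-bit rasters rendered at a configurable scale (default
1 μm/px — chosen so pixel arithmetic matches the 0–255 thresholding range
used throughout). A vessel is a set of nested level-set boundaries at the
radii implied by `inner_radius_um` and the (intima, media, adventitia)
thicknesses. Eccentricity `e ≥ 0` maps each boundary of radius `r` to an
ellipse with semi-axes `r(1+e)` and `r/(1+e)`. This stretch preserves area,
so the area-equivalent radius of every boundary — and hence the ground-truth
ring thickness — is independent of `e`, while perimeters grow; hydraulic and
circle-formula diameters then disagree measurably, which is what the
geometry stage's sensitivity outputs are for.

Intensity model: fluorescence background is Gaussian with mean 40 and a
configurable SD (default 8), specific signal has mean 180 — a
signal-to-background ratio of 4.5. The nonzero background mean is
deliberate: it makes negative-control calibration a real subtraction, not a
comparison against zero. VVG brightfield uses wall 200, elastin 60, nuclei
45, lumen 10, perivascular 255; the lumen-black / outside-white fills match
the editing conventions the mask stage assumes. These levels keep each
class ≥ 3 noise SDs from its neighbours at the default noise, so flood
fill, wall recovery and dark-pixel thresholding have well-defined operating
points without being trivial.

Painted stain sets are exact: `GroundTruth.fractions` are painted-pixel
counts over wall-pixel counts, and noise perturbs intensities only, never
mask membership. Fluorescence constituents are random wall-pixel subsets of
exactly `round(f·N_wall)` pixels. Elastin is painted as contiguous
structures — whole lamellar rings first (evenly spaced through the media,
~1 px wide, `n_lamellae` of them), then random thin circumferential arcs,
the last one truncated in angular order so the count is exact. Scattered
single-pixel elastin would be indistinguishable from nuclei during blob
removal; fibers are both more realistic and the only fair test of the
size+compactness rule. Elastic fibers also keep a 1-px gap from nuclei
blobs so that the two classes are separable in principle, as they are on
real sections at working resolution.

Nuclei are disks of radius 2 px placed by random sequential adsorption with
a minimum centre gap of 2r+2 px, which guarantees pairwise disjoint blobs
even under 8-connectivity; the count is `round(density × wall area)`.
If the requested density exceeds the jamming limit an overlap-budget error
is raised rather than silently placing fewer.

Dose–response ground truth uses a four-parameter logistic in log10 molar
dose (resting and maximal diameter, EC50, Hill slope). The logistic lives
only in the generator: the analysis stage never fits curves, it only
normalizes and summarizes.

Default presets for the three arterial beds (wall class, lamellae count,
composition fractions 0.479/0.258/0.128 etc., nuclei densities 0.000127,
0.00378 and 0.005497 cells/μm²) mirror the normotensive values reported for
porcine proximal aorta, left anterior descending and middle cerebral
arteries; cohort presets for hypertensive groups apply the reported
media-thickening contrast (1.56×). Phantom radii are desk-scale (tens of
μm, frames ≈ 200–450 px) rather than the millimetre scale of a real aorta:
recovery accuracy is resolution-limited, not size-limited, and these sizes
keep the full validation suite fast. The sparse aortic nuclei density is
the one exception — it is exercised on a larger frame (inner radius 300 μm
at 2 μm/px) so the expected count is large enough for a 5% recovery check
to be meaningful.

What the phantoms do *not* emulate: out-of-focus light, uneven
illumination, stain bleed-through, touching nuclei, tissue folds and
autofluorescence structure beyond a constant-mean background. Passing
recovery tests therefore demonstrates the correctness of the measurement
logic at realistic contrast, not robustness to every acquisition artifact.

## Masks

The lumen is a seeded flood fill with an intensity tolerance and
4-connectivity — a reproducible re-specification of interactive magic-wand
selection, whose original tool parameters are unknowable. Tolerance is
configurable (default 10); a region exceeding a configurable fraction of
the frame (default 0.5) raises a leak error, the symptom of seeding on
tissue. Perivascular cropping takes a closed polygon contour (annotations
are a documented manual hand-off; phantom ground truth plays that role in
tests). Region refinement is threshold + median filter; the median radius
defaults to 1 px (no kernel size is standard; 1 px removes single-pixel
particles while preserving 2-px structures). Media/adventitia annotations
must be disjoint subsets of the wall; the intima is defined by subtraction,
making layer areas additive by construction.

## Geometry

Three radius definitions are computed: area-equivalent (primary),
perimeter-based, and hydraulic. When they disagree (non-circular vessels)
the area-based value is used for thickness, and the others are always
reported so the disagreement is visible; this is a deliberate design choice
where the original workflow's tie-break is unknown. Raster perimeters use
the Crofton estimator with 4 directions (bias ≲ 0.5% on smooth convex
shapes at the sizes used; the plain marching estimator is several percent
high on circles). The strip-route thickness on whole rings divides wall
area by the mid-wall circumference (mean of luminal and outer perimeters);
for a perfect annulus this equals `r_out − r_in` analytically. On strips,
`Σnᵢ/m` and area/width are the same integer sum — the code asserts the
identity. Negative intima from independently measured layers is clipped to
0 with a warning inside one pixel of tolerance and raises beyond it.

## Stain quantification

Threshold calibration compares 256-bin histograms of sample and control
wall pixels after normalizing both to unit mass (sample and control walls
differ in pixel count, so raw "total intensity" subtraction is not
comparable). The cut-off is the minimum intensity of the highest-intensity
contiguous run of positive difference — the intensity band occupied by
specific signal and absent from background. Two guards make this usable on
arbitrary histograms: runs carrying < 0.1% of sample mass are ignored (a
handful of outlier pixels cannot masquerade as the signal band), and if no
qualifying run exists a sentinel threshold of 256 is returned, meaning
"nothing positive", which area_fraction maps to 0. The rule is
translation-sound: shifting sample and control by a common offset shifts
the threshold by the same offset.

Elastin blob removal deletes connected dark components with area below
`min_blob_size` *and* circularity `4πA/P² ≥ 0.5`; the compactness test
protects thin elastic fragments that happen to be small. With 13-px nuclei
blobs the working value is `min_blob_size = 16` — just above the nucleus
area. The PSR region of interest is red-dominance (red exceeds green and
blue by a 20-level margin, configurable); collagen is the ROI ∩ wall pixels
whose polarized intensity exceeds the black threshold (default 30).

## Nuclei

Components above the intensity threshold with at least `min_size` pixels
become nuclei; centroids are intensity-weighted means. Components whose
centroids fall within `min_separation` are merged single-link, with the
merged centroid weighted by component intensity mass. Wall position is
`d_L/(d_L + d_A)` with distances to the nearest inner-border and
outer-border wall pixels (borders: wall pixels 8-adjacent to lumen /
background). Distances use exact nearest-neighbour queries (KD-tree), so
they equal a brute-force search to float precision; a point on a border
pixel gets position exactly 0 or 1, and the degenerate both-zero case
(single-pixel wall) maps to 0.5. Grid bins are half-open `[k/25, (k+1)/25)`
with the last bin closed, a partition without double counting.
Normalization divides by the largest bin count (global mode, default) so
the densest transmural location maps to 1; per-column normalization is
available because the prose definition of this normalization admits both
readings.

## Arteriolar function

The dilation baseline is the pre-agonist resting (toned) diameter and the
ceiling is the sodium-nitroprusside diameter; basal tone is per-vessel
`100·d_rest/d_max` (clamped at 100 against float round-off), and group
tone is the mean of per-vessel ratios, not the ratio of mean diameters.
Groups are (condition, treatment); mismatched dose grids within a group
raise rather than interpolate. A single-vessel group reports SEM 0 with a
flag, keeping batch summaries total. No EC50 or Hill fitting is offered as
an analysis output.

## Statistics and reporting

Two-way ANOVA uses an OLS cell-means fit; unbalanced designs use type-II
sums of squares (the cohorts this serves are unbalanced, and type II does
not depend on factor order). The repeated-measures variant adds the vessel
as an additive blocking factor — the classical randomized-block treatment
of a between×within design. Zero-variance fixtures report F = 0, p = 1 by
convention instead of 0/0. Pairwise comparisons are Welch t-tests over all
cell pairs, Bonferroni-adjusted (`min(1, p·k)`) over that family; the
family definition (per panel vs per figure) is a configuration choice.
Star codes use open intervals — a p exactly at a threshold maps to the
weaker code. `build_report` joins stage tables on (condition, week,
animal), raises on duplicate keys, flags missing sections, and can drop
designated conditions (mirroring the exclusion of inconsistent sham
controls from reporting).

## Problem sizes in the validation suite

Recovery studies use 20 seeds per stain preset, phantoms of roughly
200–450 px, cohorts of 5 animals per group, and 200 replicates for the
ANOVA power study at the 1.56× media contrast with 10% between-animal
coefficient of variation and n = 7 per group. These sizes give stable
means (Monte-Carlo SE well below the tolerances tested) while the whole
suite runs in well under a minute.

## Known limitations

- Media/adventitia borders come from annotations; no automatic boundary
  learning is attempted.
- The calibration rule assumes the specific-signal band is separated from
  background at the histogram level; heavily overlapping distributions
  return conservative (high) thresholds.
- Touching or overlapping nuclei beyond the merge rule are not segmented.
- The strip thickness formula assumes the wall crosses the image
  vertically; rotated strips must be rectified first.
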