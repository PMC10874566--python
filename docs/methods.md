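# Methods

## The problem and the pipeline

Rodents lack an extreme capsule, so no anatomical border separates the
claustrum from the insula; demarcation must rely on labelling. The strategy
implemented here combines three signals on coronal slices: a retrograde
tracer channel marking claustrum projection neurons, claustrum-enriched
markers (Nurr1, Nr2f2) that co-express with most of them, and the
claustrum-devoid cortical marker Tle4 whose labelling surrounds but avoids
the claustrum. The pipeline quantifies (i) cell-level colocalization
between channels as Venn counts, (ii) the spatial footprint of the enriched
and devoid zones as polygons registered across animals, (iii) dual-axis
fluorescence-intensity profiles around the claustrum, and (iv) group
statistics. Because no imaging data are distributed, every stage is
validated on a synthetic generator with an exact ground truth.

## Synthetic slice model (`synthgen`)

**Geometry.** The claustrum is modelled as a rotated ellipse (default
semi-axes 220 × 90 µm, orientation 30° standing in for the external-capsule
direction, centred in a 1024 µm frame). Tle4⁺ tissue is an elliptical ring
of width 80 µm starting 15 µm outside the ellipse (the devoid margin), on
top of a sparse background. Cohort slices receive per-slice anatomical
jitter: centre ±40 µm, orientation ±5°, isotropic scale 0.9–1.1.

**Point process.** Cell counts per (zone, channel) are Poisson at the
configured density × zone area; positions are uniform in the zone. Default
densities (cells/mm²): enriched zone — retro 1600, independent Nurr1 500,
Nr2f2 400, c-Fos 150; ring — Tle4 1500, Nurr1 300, Nr2f2 250, c-Fos 200;
background — Tle4 350, Nurr1 120, Nr2f2 120, c-Fos 150. This yields on the
order of 100 retro cells per slice (adult counts are a few tens per slice)
with marker totals exceeding the retro count and Tle4 absent from the
claustrum interior.

**Co-expression.** Channel memberships are augmented pairwise and in
configuration order: for each configured pair (A, B), every current member
of A gains membership of B by an independent Bernoulli draw with
probability f(A, B). Defaults follow the reported adult fractions:
f(retro, Nurr1) = 0.87, f(retro, Nr2f2) = 0.81, f(retro, Tle4) = 0.01,
f(Nurr1, Tle4) = 0.015, f(Nr2f2, Tle4) = 0.004; baseline c-Fos
f(Nurr1, c-Fos) = 0.10 and f(Tle4, c-Fos) = 0.03, with the open-field
condition modelled by raising them to 0.256 and 0.057 (a +15.6 and +2.7
percentage-point activation). The realized |A∩B|/|A| is binomial, which is
what the recovery tests check.

**Rendering.** Stacks are 11 planes at 2 µm over a 20 µm volume,
1024 × 1024 px at 1 µm/px. The pixel size is a declared convention — the
source imaging protocol does not state µm/px — and is configurable; all
mm↔px conversions go through it. Each member cell is an isotropic Gaussian
spot: the lateral sigma combines the cell radius (σ = r/2, r = 5 µm) with
the PSF sigma (1 µm) in closed form rather than via a separate blur pass;
axial weights are a Gaussian around the cell's true z (σ = r/2) normalized
to unit mass over the planes, so every cell deposits identical integrated
intensity regardless of depth — this keeps the equal-mass rendering test
exact and detection amplitude nearly depth-independent. Poisson noise
(gain 1) is applied to the signal, then additive Gaussian noise (SD 2),
then quantization to uint16; both noise levels default low so that
oracle-based tests are tight.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: soma morphology and size variation, uneven
illumination and bleed-through, antibody penetration gradients, anisotropic
PSFs, tissue deformation, and any correlation between co-expression and
position beyond zone membership. Detection and zone parameters tuned here
are calibrated to this idealization, not to real micrographs.

## Detection (`detect`)

The original counting was operator-assisted; this package fixes the
simplest fully specified automation: Gaussian smoothing (σ = 1 µm), global
Otsu threshold (parameter-free and invariant to uniform intensity
rescaling; a fixed threshold is available), connected components, watershed
splitting at local maxima separated by ≥ 6 µm, an area filter
(10–1000 µm²), and intensity-weighted centroids for sub-pixel accuracy. On
zero-noise, well-separated synthetic cells this attains recall and
precision ≥ 0.99 with centroid error ≤ 1 px; at the default claustrum
densities a few percent of cells merge, which is the expected behaviour of
any threshold-based counter at ~12 µm nearest-neighbour distances.

## Colocalization (`coloc`)

The original analysis judged colocalization visually; a metric criterion is
required for reproducibility. Two cells are colocalized when their
centroids are within 5 µm (≈ one soma radius). Matching is greedy
globally-nearest (closest remaining cross-channel pair first, ties broken
by id order): at biological densities it is near-identical to optimal
assignment — the tests verify equality of match counts against an
exhaustive `linear_sum_assignment` oracle on small instances — and runs in
O(n log n). Venn counts conserve cells (n_A = matched + unmatched_A) and
the A-fraction is undefined (absent) when n_A = 0.

Note a property of any proximity criterion: if the partner channel has
independent cells at density ρ near the A cells, chance matches inflate the
recovered fraction by ≈ (1−f)(1−exp(−ρπr²)). At the default independent
Nurr1 density this bias is well under the binomial 3-SE band; the recovery
tests additionally use the retro/Tle4 pair, where the partner has no
independent cells inside the enriched zone and the estimator is cleanly
binomial.

Bregma subdivisions are assigned with intervals closed on their anterior
edge: anterior (+0.70, +1.80], middle (−0.20, +0.70], posterior
[−1.00, −0.20]; the boundary convention is not specified by the source and
is fixed here for determinism. Aggregation always averages slices within a
mouse first and mice second.

## Zone polygons (`zones`)

The operator's hand-drawn perimeter of the zone containing > 90 % of
labelled cells is replaced by a kernel-density superlevel set: centroids
are binned to a grid (8 µm) anchored at multiples of the grid spacing and
smoothed with a Gaussian kernel (bandwidth 25 µm); the polygon is the outer
contour of the largest connected region above the highest density level
whose simplified contour still contains ≥ 90 % of the cells by an exact
point-in-polygon test. Scanning candidate levels (the density values at the
cells, descending) guarantees the returned polygon meets the containment
rule whenever any level does; cells scattered into several distant blobs
have no enriched zone and raise an error. The boundary's smoothness is a
bandwidth choice — the > 90 % rule constrains containment, not shape.
Contours are simplified with tolerance grid/2 (doubling until ≤ 200
vertices), moving the boundary by at most half a grid cell. Grid anchoring
makes delineation exactly translation-equivariant for shifts that are
multiples of the grid spacing and equivariant to within one cell otherwise.

The devoid zone inverts the construction: the connected component of
{density ≤ 0.25 × median density at the Tle4 cells} containing the anchor
(the retro-zone centroid in the pipeline). The devoid boundary sits
≈ 0.67 bandwidths inside the ring's inner edge, so the devoid margin should
exceed the bandwidth for the polygon to reach the true interior boundary;
a uniform field has no sub-threshold region and raises an error.

Polygon centroids are the unweighted mean of the vertex coordinates — not
the area centroid; the two differ when one edge carries more vertices, and
a dedicated test documents the difference. Overlays translate each mouse's
polygon pair by minus the reference (retro) vertex centroid — alignment is
translation only, no rotation or scaling — and count per-grid-point
occupancy across mice. One slice per mouse per subdivision (the first)
enters the overlay.

## Intensity profiles (`profiles`)

Axis 1 is parallel to the external capsule (the configured orientation);
axis 2 is perpendicular; both are anchored at the retro enriched-zone
vertex centroid — an operator-free stand-in for the anatomical placement.
The profile value in each bin is the exact mean of the pixels whose
projection onto the axis falls in the bin and whose perpendicular offset is
≤ half the strip width; this pixel-binning definition is what the
brute-force loop oracle computes, and the two agree to 1e-6. The 0.1 mm
"section" is interpreted as the strip width, with the bin length a separate
parameter (default 20 µm); the alternative reading (0.1 mm bins) is
obtainable by setting `bin_um=100`. Empty bins are marked absent.
Z-scoring uses the population (n) SD over present bins — immaterial at
these bin counts but fixed for bit-reproducibility — and a constant profile
maps to zeros with a degeneracy flag. No smoothing precedes peak detection;
the strip averaging already regularizes. Peak ties break toward the bin
nearest the origin. Realignment shifts all of a slice's channels by the
same amount so the retro peak sits at 0; averaging covers bins present in
at least half the slices to avoid edge artifacts from differing shifts. On
the default geometry the aligned Tle4 mean profile has its trough at the
retro peak; because the devoid interior is nearly signal-free the trough is
a plateau, and the alignment test allows a 0.05-z plateau tolerance when
locating the minimum.

## Statistics (`stats`)

Two-group comparisons use the pooled-variance Student t-test: the printed
df of 13 for 5 vs 10 mice identifies the pooled form (Welch would give a
fractional df). ANOVA post hoc pairwise tests use the pooled within-group
mean square with df_within (classical protected Bonferroni), with raw
p-values multiplied by m = k(k−1)/2 and capped at 1; the source states
"ANOVA followed by Bonferroni" without further detail, and this is the
standard reading. Degenerate zero-variance inputs return t = 0, p = 1 when
means agree and are an error otherwise. The statistical unit is the mouse:
slice values are averaged per mouse before testing. Type-I error of the
t-test is verified at 5 % ± 0.6 % over 10 000 null replicates.

## Pipeline and reproducibility

Per-mouse seeds are `crc32(master_seed:mouse_id)`, so adding mice never
perturbs existing mice's data; reruns with the same config are
bit-identical for all tables. The effective config (with a SHA-1 digest of
the generator settings) is written into every run directory, and each
output row carries (mouse, slice, subdivision). The default cohort layout
is 6 slices per mouse — 2 per anteroposterior subdivision with the bregma
coordinate drawn uniformly inside the subdivision's range.

## Problem sizes used in tests and the reproduction script

Unit and pipeline tests run on quarter-scale frames (256 µm) with densities
raised to preserve per-zone counts. The reproduction script and the
acceptance-style tests use full-scale defaults: 20 slices for the
enrichment-containment figure, pooled cohorts of ≥ 2000 retro cells for
fraction recovery, and a 12-slice jittered cohort for profile alignment —
sizes chosen so the whole suite completes in a few minutes on one CPU while
keeping binomial confidence intervals tight.

## Known limitations

- Pairwise co-expression is sampled independently per pair; no three-way
  constraints are modelled (only pairwise Venn counts are quantified).
- The devoid-zone boundary depends on the KDE bandwidth relative to the
  devoid margin (see above); very tight geometries under-cover the true
  interior.
- No curved (claustrum-following) profile axes, no rotation/scaling in
  overlay registration, no atlas mapping, no 3-D segmentation — the
  quantification operates on maximum-intensity projections throughout.
- Detection merges touching somata by design of the separation rule;
  counts at high densities are conservative.
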