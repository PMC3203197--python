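# Methods

## Data model

An atlas is one species' averaged blastoderm: `n_cells` nuclei with 3D
positions (µm) for each of `T` temporal cohorts, a surface neighbor graph
(the triangulation edges, stored once per undirected edge), and for every
(cell, gene, timepoint) the mean, standard deviation and count of
expression across the registered replicate embryos. Cell ids are dense
integers from 0. A (gene, timepoint) slice in which every cell has
replicate count 0 is *missing* (e.g. *cad* absent from one species, *bcd*
unmeasured at late cohorts); missing entries are dropped from distances and
tests, shrinking the Bonferroni family accordingly. Files are plain TSV
(atlas table, neighbor table) plus a `key: value` metadata sidecar.

## Normalization

Distance scoring requires each (gene, timepoint) slice scaled so its
maximum mean is 1 (`scope="per_timepoint"`, the default); standard
deviations are divided by the same factor, so subsequent t-tests are
invariant to per-slice gains. A second convention, `scope="per_gene"`,
scales each gene by its maximum over the whole time course (the peak
timepoint takes the value 1) and is the natural display normalization for
expression time traces. All-zero slices are left untouched and logged.
Normalization is idempotent and gain-invariant (property-tested).

## Expression distance and matching

`d_ij` is the squared Euclidean distance between normalized G×T profiles
over a gene subset (default: all genes except the maternal gradients *bcd*
and *cad*). Squared rather than plain distance keeps the score additive
over genes and timepoints.

Spatial candidates are found after scaling each atlas isotropically to
unit AP extent and centering on the nuclear center of mass. The kNN search
(k = 30) uses one cohort's positions — configurable, defaulting to the
last cohort, since cell identity is constant across cohort rows and the
choice only anchors the spatial window. All ordering is deterministic:
candidates sort by (distance, cell id), the best match is the argmin of
d_ij with ties to the lowest id.

The displacement endpoint is the weighted mean position of the m = 10
smallest-distance candidates with weights 1/d_ij. The weighting is
undefined at d = 0, so candidates with d < 1e-12 share equal weight and
all others get zero — with the side effect that a perfect match pins the
endpoint to it exactly. Displacements are reported in scaled units and in
µm of the query embryo.

Match tallies count, per target cell, appearances in any query's top-10
list; their sum is m × n_query by construction, and the fraction of target
cells with a nonzero tally summarizes how completely the target is covered
without one-to-one matching.

## Significance testing

Each tested profile entry gets a Welch two-sample t statistic from the
stored summaries, t = (m₁−m₂)/√(s₁²/n₁ + s₂²/n₂), with Welch–Satterthwaite
degrees of freedom and a two-sided p. If both variances vanish, p is 1
(equal means) or 0 (unequal) by convention, logged. Per cell pair, an entry
is significant iff p < α/m_tests with α = 0.01 and m_tests the number of
unmasked entries (66 for 11 genes × 6 cohorts); the *t-test score* is the
count of significant entries and a pair is "different" if the score is ≥ 1.
The per-cell across-embryo sd stored in the atlas is used directly (no
pooling across cells). Density grids are compared the same way node-wise,
on per-embryo density samples, reporting log₁₀ p and a "similar" mask at
p ≥ 0.05.

## Expression neighborhoods and calibration

N_i is computed by thresholding d_ij from the focal cell to all cells
(strictly d < t) and taking the connected component of the induced
subgraph of the surface triangulation that contains i. Connectivity uses
the triangulation, not a spatial radius, so neighborhoods live on the
embryo surface. Sizes are monotone non-decreasing in t cellwise.

Fluorescence scales are not comparable between atlases, so the target
threshold is calibrated: given t_query, find t_target such that the mean
over matched pairs of R = ln(|N_j(t_target)|/|N_i(t_query)|) equals
ln(n_target/n_query), the null of uniform scaling. The mean-R curve is
empirically monotone in t_target; the search brackets [t_query/100,
100·t_query] and bisects on a log scale (thresholds live on a ratio
scale), falling back to a 50-point geometric grid scan of the final
bracket if bisection stalls on a plateau, and raises with the evaluated
curve attached if the criterion is unreachable.

**Granularity.** Because neighborhood sizes are integers and a single
threshold crossing can resize a whole component, the mean-R curve is a
step function with jumps of order a few × 1/n_cells. The default
tolerance 1e-3 is therefore reliable for atlases of roughly 3,000 cells
and up (residuals 1e-5–8e-4 across seeds at 3,000/2,550 cells); the
pipeline driver widens its tolerance to max(1e-3, 6/n_query) so that
small runs fail only when calibration is genuinely impossible, not when
the target falls inside a discretization gap.

## Geometry

Surface area sums the triangle areas of the neighbor relation; faces are
recovered as 3-cliques and validated (every edge in 1–2 triangles).
Local density counts nuclei within a 15 µm *chord* (3D Euclidean) radius,
including the focal nucleus, over the disk area πr²; at 15 µm on a
~100 µm-radius surface the chord/geodesic discrepancy is negligible, and
including the focal nucleus keeps densities strictly positive. Cylindrical
projections put the AP axis on x (axial position as egg-length fraction)
and measure the angle from the dorsal midline (+y), increasing toward the
embryo's left, in [−π, π). Density maps are resampled nearest-cell onto a
regular axial × angle grid (with angular wrap-around) and averaged across
embryos.

## Synthetic atlases

The generator emulates the statistical structure the analysis assumes, not
any particular real dataset:

- **Geometry** — nuclei on a jittered Fibonacci lattice over an ellipsoid
  (egg length L, transverse radii L/4 by default), triangulated by the
  convex hull of the first cohort; per-cohort positions add a
  poleward-to-center drift reaching 2% of egg length at the poles across
  the time course, a qualitative stand-in for cell flow.
- **Patterns** — a 13-gene set shaped like the AP segmentation network:
  exponential/sigmoid maternal gradients (*bcd*, *cad*), Gaussian gap
  domains (*hb*, *Kr*, *kni*, *gt*, the last with dorsoventral
  modulation), exponential terminal caps (*tll*, *hkb*, *fkh*), and four
  7-stripe pair-rule patterns (*eve*, *ftz*, *odd*, *prd*) with per-cohort
  amplitude dynamics.
- **Noise** — per replicate embryo, additive Gaussian noise with sd equal
  to `noise_sd` × the slice maximum (default 5%), truncated at 0, then
  summarized to mean/sd/count exactly as a registered atlas would be. This
  matches the two-sample-t-test error model used downstream.
- **Perturbations** — per-gene AP/DV shifts, amplitude scalings and
  cohort timing offsets are injected into the second species and retained
  as ground truth.
- **Null control** — `split_replicates` summarizes disjoint halves of one
  replicate set as two atlases: the baseline for scores attributable to
  measurement error alone.
- **Morphology series** — `embryo_series` emulates within-cohort embryo
  variation: linear dimensions scale by ~Normal(1, 4%) and nuclei counts
  follow a common slope of 0.0278 nuclei/µm² of surface area with a
  species-specific offset, so counts are linear in area with a shared
  slope across species while equal-area embryos of different species can
  still differ in count.

Defaults: 6 cohorts, 10 replicates per (gene, timepoint), species presets
at the published average morphologies (5,974 nuclei / 393.8 µm; 6,128 /
451.8 µm; 5,087 / 394.6 µm). All generation is deterministic given the
spec seed; every stochastic stage derives its stream from (seed, stage)
tuples.

What the generator does *not* emulate: registration artifacts and their
spatially correlated errors, inter-gene expression correlations within an
embryo, mitotic changes in nuclei number, or real pattern shapes traced
from images. Passing tests therefore demonstrate correctness of the
algorithms and their statistical calibration under the stated error model,
not fidelity to any particular real atlas.

## Problem sizes and numerical choices

Tests and the acceptance script run on 200–3,000-cell atlases: large
enough that lattice spacing (~1.5–4% egg length) resolves the generated
patterns, small enough for a laptop-class run. Two resolution effects are
worth knowing. First, shift recovery via the displacement field is
accurate to about half the internuclear spacing, the natural resolution of
a discrete lattice; the 30-candidate window covers shifts up to roughly 4
cell widths. Second, neighborhood-based proportion estimates degrade when
the expression-distance threshold maps to a value band thinner than the
lattice spacing — the band's cells stop being surface-connected and sizes
truncate toward 1. With thresholds wide enough to span several cell rows,
a 3× stripe widening is recovered as a ~2.9× mean neighborhood expansion.

Other conventions: strict inequality (d < t) for neighborhood membership;
natural logarithm for R (the calibration criterion is base-invariant);
histograms of score distributions bin √d to spread values near zero, raw
scores stay in the data tables; every pipeline run writes a manifest with
a hash of the scientific configuration and the seed, sufficient to
reproduce all tables byte-identically.

## Known limitations

- Matching is local by design; a pattern shifted by more than ~4 cell
  widths falls outside the candidate window and will score as a large
  expression difference instead.
- The Bonferroni family is per cell pair; no correction is applied across
  cells, mirroring the per-cell framing of the score.
- Inter-gene correlations are not modeled (measuring them would require
  co-staining gene pairs), so the expression distance score carries no
  analytic null distribution — significance is gauged against the
  split-replicate control.
- Calibration assumes the mean-R curve is monotone in t_target; this is
  verified empirically per run (the evaluated curve is attached to errors
  and logged) with a grid-scan fallback.
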