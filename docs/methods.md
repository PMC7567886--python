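# Methods

This note records the statistical conventions, estimator definitions,
defaults and numerical safeguards used throughout `histoscape`, so that
every number the package produces is auditable.

## 1. Categorical rasters and patches

A landscape is an integer label raster with an optional nodata code and a
physical pixel resolution. Pixel (row, col) has centre
((col + 0.5)·res, (row + 0.5)·res) with y increasing downwards (image
convention). A *patch* is a maximal connected set of same-class pixels;
connectivity is 8 by default (4 available everywhere). Patches are labelled
deterministically: classes in ascending code order, components in raster
scan order, ids dense from 1 (0 = nodata).

Adjacency counts are 4-neighbour and double-counted (each interior pixel
pair contributes twice, matching the convention the aggregation and
contagion formulas expect); pairs touching nodata are excluded.

## 2. Landscape metrics

* **Patch level**: area, perimeter (4-neighbour boundary edges, *including*
  edges against nodata and the image border), shape index 0.25·P/√A
  (1 for squares), and Euclidean nearest-neighbour distance to another
  patch of the same class (pixel-centre to pixel-centre; NaN for singleton
  classes — undefined values are always NaN, never 0).
* **Class level**: PLAND, NP, PD, LPI, total edge (sum of patch
  perimeters), ED, mean patch area, and the aggregation index
  AI = 100·g_ii/max g_ii, where g_ii is the single-count like-adjacency
  count and max g_ii comes from the largest-integer-square construction
  (n = ⌊√a⌋, m = a − n²: 2n(n−1), plus 2m−1 if m ≤ n, plus 2m−2 if m > n).
* **Landscape level**: NP, TE (each unlike interior edge once plus
  class/nodata edges; the outer border is tissue extent, not class edge,
  and is excluded), ED, mean patch area, LPI, Shannon diversity/evenness,
  Simpson diversity, area-weighted AI, and contagion
  (1 + ΣP_ik ln P_ik/(2 ln m))·100 with P_ik = p_i·g_ik/Σ_k g_ik.
* **Complexity**: the normalised co-occurrence matrix is treated as a joint
  distribution p(i, j); we report marginal entropy H(x) (row marginal),
  joint H(x, y), conditional H(y|x) = H(x, y) − H(x), mutual information
  I = H(x) − H(y|x) and relative MI I/H(x), all in bits. A landscape with
  no adjacencies (single valid pixel) raises rather than returning zeros.

Every metric is validated against naive-enumeration oracles (flood-fill
labelling, explicit edge counting, dictionary adjacency counts) on small
rasters as part of the test suite.

## 3. Point patterns

Observation windows are axis-aligned rectangles; analyses of image sets
crop to the largest common rectangle. The default r-grid spans 0 to a
quarter of the short window side (512 points).

* **Clark–Evans**: mean NN distance over 1/(2√λ). The uncorrected index
  has a positive edge bias of order P/(n·E[d]) that does not vanish
  relative to its standard error (both scale as 1/√n), so calibration
  work should use the Donnelly-corrected expectation
  0.5√(A/n) + (0.0514 + 0.041/√n)·P/n, available via
  `correction="donnelly"`.
* **Hopkins–Skellam**: Σd²_event/Σd²_sample with equal counts of event
  NN distances and uniform-sample-to-event distances; < 1 indicates
  clustering (the numerator shrinks when events are clumped). *Seed
  hygiene*: the sampling seed must be independent of the seed used to
  generate the pattern — reusing the same integer seed replays the same
  generator stream and can place sample locations (nearly) on top of the
  events, exploding the index.
* **Ripley K / Besag L**: K̂(r) = |W|/(n(n−1))·Σ e_ij·1[d_ij ≤ r] with
  weights e_ij = 1 (none), the reciprocal translation overlap
  |W|/((W−|dx|)(H−|dy|)), or the reciprocal fraction of the circle of
  radius d_ij about point i lying inside the window (isotropic; closed
  form from the four edge caps with corner overlaps added back, valid for
  r below half the short side — r-grids are truncated there with a
  warning). The border correction averages reduced-sample counts over
  points farther than r from the boundary. L = √(K/π); `centred=True`
  returns L(r) − r so CSR plots as zero. Because √· of a discrete count
  is biased at very small r (few expected pairs), calibration statements
  about L − r are made on the range where the expected CSR pair count
  n(n−1)πr²/|W| is at least 5.
* **F, G, J**: F is estimated on a regular lattice of test locations
  (spacing short-side/128 by default), G on the events; both use the
  reduced-sample (border) estimator by default, with Kaplan–Meier
  censoring at the boundary distance as an option. The reduced-sample
  estimator is not intrinsically monotone, so a running maximum is applied
  (a CDF estimate must be non-decreasing); r values whose denominator is
  empty stay NaN. J = (1−G)/(1−F) is reported only where F < 1, and
  summaries of J are taken where F < 0.9, since the ratio degenerates as
  F → 1.
* **Envelopes**: CSR simulations with the observed n. Pointwise envelopes
  use the rank convention k = ⌈α/2·(n_sim+1)⌉ (3rd-lowest/highest of 99 at
  α = 0.05); global envelopes use the maximum absolute deviation from the
  simulation mean.
* **Grouped comparison**: the studentized permutation test summarises each
  pattern by a summary function on a common r-grid, integrates the
  squared studentized difference of group means over r (trapezoid rule;
  variance denominators floored at 1e−12), sums over group pairs, and
  permutes pattern-to-group assignment. P-values use the add-one
  convention and are never exactly 0; each group needs ≥ 2 patterns for a
  defined within-group variance.
* **Voronoi/Stienen**: cells are obtained by mirroring the pattern across
  all four window edges before tessellating, then clipping to the window,
  so cell areas sum exactly to the window area. Stienen circles have
  diameter equal to the NN distance (hence never overlap) and are flagged
  when they cross the boundary.

## 4. Microarchitectural models

* **Lobule hexagon model**: for each central vein, r is the mean of the
  distances to its 6 nearest portal tracts and the modelled area is
  (3√3/2)·r², the regular hexagon with circumradius r. On the idealised
  triangular lattice (spacing s, portals at hexagon vertices, circumradius
  s/√3) this reproduces the tessellation hexagon area (√3/2)·s² exactly,
  which is the basis of the exact-recovery acceptance check. Note the
  model requires ≥ 6 portals in total; the error message reports the
  deficit.
* **Scar-axis analysis**: distances are shortest point-to-polyline
  distances to the vein ring (shapely); the ring centre is the shoelace
  (area) centroid, falling back to the vertex mean with a warning for
  degenerate rings. Polar angles use the mathematical convention after a
  y-flip, so image-up is 90°. The angular density is a wrapped Gaussian
  kernel estimate on a 1° grid (kernels summed over ±360° shifts,
  integrating to 1 over the circle); the bandwidth defaults to Silverman's
  rule on the angle sample. Alignment shifts all angles by
  (90° − φ_peak) mod 360° and rigidly rotates the coordinates; the
  bandwidth is fixed from the original sample for both density evaluations
  (the Silverman default is not rotation-invariant on wrapped data), which
  makes the aligned peak land exactly on 90°. The axial test fits
  A·sin(2πϕ/P + φ₀) + C with all four parameters free, multi-started from
  periods {360°, 180°, 120°} and phases {0, π/2}; a fitted period near
  180° indicates bipolar organisation, and a negligible amplitude
  (< 10⁻³ of the density scale) flags the period as unidentifiable rather
  than reporting a meaningless value.
* **Distribution comparisons**: radial densities use a Gaussian KDE
  (Silverman); two-sample distance distributions are compared with a
  bootstrap Kolmogorov–Smirnov test (resampling from the pooled sample,
  valid under ties, add-one p-value) and means with Welch's t-test
  (zero-variance groups: identical means give t = 0, p = 1).

## 5. Machine-learning pipeline

Splits are by case, so paired regions of one case never straddle the
train/test boundary; unpaired designs are stratified by label, and a split
missing a class on either side raises. The feature filter is fitted on the
training split only and then applied frozen to test data:

1. drop features with undefined (NaN) values, zero variance, or near-zero
   variance (most/second-most frequent value ratio > 19 *and* unique-value
   fraction < 0.1);
2. per-feature rank-based inverse-normal transform
   Φ⁻¹((midrank + 0.5)/(n + 1)), test values ranked against the *stored
   training sample* (this is the leakage-freedom property the tests
   assert: transforming perturbed test data cannot move the reference
   quantiles);
3. greedy correlation filter: while any |r| > 0.75, drop the member of the
   worst pair with the larger mean absolute correlation.

The forest is a hand-rolled bagging loop over decision trees (√p features
per split) because importance introspection needs per-tree bootstrap/OOB
indices, root features, node counts and minimal depths, which packaged
forests do not expose. Importance columns: OOB permutation accuracy
decrease, total Gini decrease, mean minimal depth (trees not containing
the feature contribute their maximal depth + 1, so absence is penalised,
not ignored), node and root counts, and a one-sided binomial p-value for
the node count against uniform split-variable choice. Evaluation reports
ROC/AUC and an F1 sweep over thresholds 0–1 (step 0.01) with the best
threshold; single-class test sets yield AUC = NaN rather than an error.
Case clustering is k-means on standardised features with 10 restarts.

## 6. Synthetic generators and calibration choices

* `gen_clumpy_raster`: Gaussian blur (σ = clumpiness·min(shape)/16) of iid
  noise thresholded at class-weight quantiles. This gives exact marginal
  proportions and monotone aggregation in the clumpiness parameter —
  which is all the metric calibrations require — but it is not a
  mechanistic tissue model: patch shapes are isotropic blobs without
  anatomical anisotropy.
* `gen_point_process`: Poisson (N ~ Poisson(λ|W|)); Matérn cluster with
  parents on the dilated window (edge-effect free); simple sequential
  inhibition with a proposal cap that returns a partial pattern with a
  warning when the hard-core target is unreachable.
* `gen_lobular_lattice`: integer-index lattice arithmetic (no accumulated
  float drift), shared portal vertices deduplicated after rounding to
  12 decimals; only centrals whose 6 vertices fall inside the window are
  kept, so at zero jitter the model's "6 nearest portals" are exactly the
  lobule's own vertices. Welch-detection demonstrations use a small jitter
  (σ = 0.03·s): a jitter-free lattice has zero within-group variance and
  an undefined t statistic.
* `gen_scar_field`: axial von Mises mixture with antipodal modes (dominant
  weight ∈ [0.5, 1]), exponential radial distances, 64-gon vein ring in
  image coordinates. Rigid rotations of points relative to the polygonal
  ring change point-to-ring distances by up to the polygon sagitta
  (~r(1 − cos(π/64))), which bounds the tolerance of alignment
  round-trip checks.

Monte-Carlo calibration checks in the test suite use 20 seeded
replicates and 3-standard-error bands; the permutation-test type-I check
uses 100 null trials against an 8% ceiling at nominal 5% (the add-one
permutation p-value is exact for exchangeable nulls, so the rejection rate
is binomial around 0.05). The ML null-AUC check averages over 5 seeded
replicates because a single small test split has an AUC standard deviation
of roughly 0.15 under the null. All replicate counts, tolerances and seeds
were fixed before the checks were first run, and generator seeds are kept
independent of sampling seeds via separate `SeedSequence` children.
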