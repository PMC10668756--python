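# Methods

## The measurement problem

In a comet assay, electrophoresis pulls fragmented DNA out of a lysed
cell's nucleoid; intact DNA stays put. Under fluorescence each cell appears
as a bright, near-circular **head** with — if the DNA is damaged — a dimmer
**tail** smearing in the field direction. The quantity of interest per cell
is the **tail moment**: tail length × fraction of total DNA (integrated,
background-subtracted intensity) in the tail. Per-female tail-moment means
and sperm viability percentages are then modelled against sperm storage
time in months.

## Segmentation pipeline

1. **Preprocessing.** Grayscale morphological opening then closing with a
   3×3 square element. Opening removes salt noise (an isolated bright pixel
   cannot survive), closing fills pinholes; neither shifts edges the way a
   linear blur would. The pass is nearly idempotent, so repeated runs are
   safe.
2. **Candidate location.** Comets are brighter than background, but a
   comet image has *three* intensity populations (background, tails,
   heads), so a two-class Otsu threshold tends to land above the tails.
   We therefore use the lower threshold of a three-class between-class
   -variance split (falling back to two-class Otsu on sparse histograms),
   plus a configurable additive offset for dim slides. Binarization is
   hysteretic: regions seed above the global threshold and extend down to
   background median + 2 robust sigma, so dim tail ends connected to a
   bright seed are retained while isolated background fluctuations are
   not. 8-connected components within a configurable area window, sorted
   by centroid row-major, become candidates. Connectivity is 8-way
   throughout because tail pixels touch diagonally.
3. **Head segmentation.** Within a candidate, the head is the brightest
   compact spot, but no single threshold isolates it in every case: an
   undamaged cell's region *is* its head (no split wanted), while a heavily
   damaged comet's tail start can be as bright as the head's rim (high
   split wanted). A sweep of region-restricted thresholds (the region's
   Otsu value, its 0.3/0.5/0.7/0.8/0.9 intensity quantiles, and "no
   split") proposes brightest-blob candidates; each is gated on area
   (30–5000 px), circularity 4πA/P² ≥ 0.7 and convexity A/A_hull ≥ 0.9,
   and the largest passing blob wins. If the winner came from a genuine
   split, it is grown back to the full head disc estimated from the
   region's vertical chord through the blob centroid (heads are
   near-circular by the gate, and the tail band is narrower than the head
   diameter), so the head's dim rim is not miscounted as tail. No passing
   blob ⇒ the region is discarded as `no_head`.
4. **Tail segmentation.** The region is smoothed by a 5×5 closing; the
   tail is the convex hull of the smoothed region, minus the head,
   intersected with the smoothed region support (hull slack over
   background is excluded). The result may be empty.

**Classification.** A CART decision tree (Gini impurity, exhaustive
midpoint threshold search, ties broken by lowest feature index then lowest
threshold, depth ≤ 3) classifies each head/tail-candidate pair as
`tailed_comet` or `head_only` from four features: head/tail area ratio
(capped at 100 when the candidate is empty), the head centroid's normalized
x-offset within the region box (−1 = leftmost), and the mean head and tail
intensities. For head-only predictions the tail mask is emptied. The
packaged default model is trained on 300 synthetic single-comet patches
(seed 20231117); it is a stand-in for training on expert annotations, which
`train_tree` / the `train` subcommand support as a first-class path.

**Geometric discards.** Tailed comets are rejected when the head/tail area
ratio leaves [0.05, 20] or when the angle of (farthest tail pixel − head
centroid) against +x exceeds 20°. The farthest-pixel operationalisation is
conservative — a band corner can subtend ≈ atan(half-width/length) even
for a perfectly horizontal tail — which is why the default tolerance is
20° rather than a tighter value; head-only cells skip both tests. All
segmentation is deterministic: no stage draws random numbers.

## Quantification and evaluation

Background is the median intensity outside all comet masks (defined while
masks cover < 90% of the image). DNA sums clamp negative residuals to zero
(non-negative mass). Tail length is the x-extent from the head's rightmost
column to the tail's rightmost column — comets are enforced near-parallel
to x, so the x-extent is the migration distance. Tail moment uses the
fraction on [0, 1] (units "px·fraction"): lengths of order 100 px give the
0–120 scale damaged sperm shows.

Evaluation matches predictions to ground truth greedily by descending
whole-comet IoU, one-to-one, discarding pairs under 0.2 (permissive
detection; overlap quality is reported separately as mean head and tail
IoU over matched pairs — tail IoU only over pairs where either tail is
non-empty). On well-separated scenes greedy matching coincides with the
exhaustive optimal assignment; the test suite verifies this against a
brute-force search.

## Synthetic scenes

The generator renders what the pipeline must be able to undo:

* **Head**: isotropic Gaussian disc truncated at radius r (8–14 px),
  σ = r, so the rim sits at ≈ 0.6 peak — a flat-topped nucleoid. Peak
  intensity 150–220 counts (8-bit).
* **Tail**: present with probability 0.5; a band of length 60–110 px
  starting at the head boundary, half-width 0.55 r, tilted by a uniform
  angle within ±8° of +x, with exponential decay (length constant 120 px)
  along the axis and a near-uniform quartic cross profile.
* Head and tail components are rescaled so the integrated tail intensity
  over the total equals a drawn tail-DNA fraction (0.3–0.7); rendering
  therefore *is* the quantification ground truth, exact to pixel
  discretization (< 2%).
* Background 12 counts plus Gaussian read noise σ = 3; comets placed by
  rejection sampling with non-overlapping padded bounding boxes
  (spacing 12 px).

All randomness flows through NumPy's seeded PCG64 generator with a fixed,
documented draw order, so scenes are reproducible across platforms. Sizes,
intensities and noise are calibration choices made once — the source study
reports no intensity statistics for its micrographs — selected to look like
a clean SYBR-stained field at moderate magnification.

What the generator does **not** emulate: optics (PSF blur, vignetting,
halo), overlapping or touching comets, gel-edge artifacts, non-Gaussian
camera noise, and staining inhomogeneity. Passing benchmarks on synthetic
scenes therefore demonstrates correctness of the algorithmic chain, not
performance on arbitrary real micrographs; the detection ≥ 90% and
IoU ≥ 0.8/0.7 bars in the test suite are this repository's own, measured
against generator truth, and are deliberately not comparable to published
figures measured on expert-annotated real images.

## Statistics

* **Per-female means** are plain arithmetic means — the female is the
  experimental unit.
* **Spearman correlation** uses average ranks for ties and Pearson
  correlation of the rank vectors; the two-sided p-value uses the
  t-approximation with n − 2 df and is reported but never used as a
  decision criterion here.
* **Segmented regression** fits y = β₀ + β₁x + β₂(x − ψ)₊ (one breakpoint;
  continuity is structural). ψ is estimated by iterative linearization:
  refit with the working covariate V = −1{x > ψ}, update ψ ← ψ + γ̂/β̂₂.
  Updates are accepted only if they reduce the SSE (step-halving
  otherwise), ψ is clamped to the observed x range (flagged), and the
  iteration is started from the three best points of a 50-point SSE grid
  over the interior 10–90% x-quantiles, keeping the best converged
  solution — the profile can hold nearly tied local minima in adjacent
  inter-observation intervals. Slope CIs are Wald intervals from the final
  working model *including* V, which propagates breakpoint uncertainty
  into the slope covariance (without it, simulated coverage drops from
  ≈ 0.95/0.91 to ≈ 0.81 at n = 30, σ = 5). The right-segment slope is
  β₁ + β₂ with variance var β₁ + var β₂ + 2cov. Adjusted R² uses n − 4
  residual df, counting ψ as estimated; the convention is stated because
  alternatives differ in the third decimal at n = 30.
* **Ridgeline summaries** are per-group Gaussian KDEs (Silverman
  bandwidth) on one shared grid spanning all groups ± 10%; modes are
  interior local maxima above 10% of the global density maximum.

Numerical edge cases: constant vectors are rejected for correlation;
breakpoint fitting requires n ≥ 6 and ≥ 4 distinct x values; degenerate
single-point groups are rejected for densities; `iou` of two empty masks is
defined as 1 (perfect agreement about absence).

## Problem sizes

The test suite benchmarks segmentation on ten fixed-seed 512×512 scenes of
ten comets each, trains the default classifier on 300 patches, and runs 200
replicates for breakpoint-recovery and oracle-equivalence checks; these
sizes give stable statistics while keeping a full run around a minute on
one CPU.

## Known limitations

* Overlapping comets are neither generated nor separated (no watershed).
* The tail length anchor (head's rightmost column) differs from tools that
  measure from the head centroid; comparisons across tools need a scale
  alignment.
* The packaged classifier reflects synthetic training data; real
  micrographs should use a model retrained on local annotations.
* One breakpoint only; model selection over the number of breakpoints is
  out of scope.
* The minimal CLI writes whole-image label masks and per-comet contours
  but has no interactive editing; manual corrections go through
  programmatic `Project` contour replacement (manual edits survive
  automatic re-runs).
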