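# Methods

This note documents the models and procedures implemented in `flrw`, the
defaults chosen where the method leaves freedom, and what the synthetic
phantoms do and do not establish.

## Pipeline

All images, training and test, are denoised before feature extraction
(median, radius 1 by default; switchable to `none`/`gaussian`).  Seeds and
the walker operate on the *original* intensities: denoising stabilizes the
texture descriptors, but the seeding step relies on the raw histogram and
the walker on raw edge contrast.  3-D volumes are processed slice-by-slice
for features and probabilities (the descriptors are 2-D) and on the full
3-D lattice for the walker.

## Texture features

Each pixel is described over an h×w window (default 11×11, odd sizes only):

- **LBP** — N = 8 samples on a radius r = 1 circle, starting at angle 0
  (east) and proceeding counter-clockwise, bilinear interpolation at
  non-integer sample points, ties (sample ≥ centre) set the bit; the code is
  Σ s(n)·2ⁿ with n = 0..N−1.  The feature is the window's h·w codes in
  row-major order.
- **GLCM** — intensities are quantized to 16 equal-width levels over the
  *global* image range; co-occurrence counts at displacement (d = 1, θ = 0°)
  are symmetrized and normalized per window.  Twelve statistics are
  computed in fixed order: energy, contrast, correlation, homogeneity,
  entropy, autocorrelation, dissimilarity, cluster shade, cluster tendency,
  maximum probability, variance, sum mean.  The formulas follow the
  conventional co-occurrence definitions and are written out in the
  docstring of `glcm_statistics`; correlation of a degenerate (zero-variance)
  matrix is defined as 0.  The number of (d, θ) offsets is configurable.
- **Haar** — a frozen bank of 15 rectangle filters: five shapes
  (horizontal/vertical two-rectangle edge, horizontal/vertical
  three-rectangle line, centre–surround) at three centred scales (full,
  half, quarter window).  Every feature is the area-normalized white mean
  minus black mean, evaluated with an integral image.  Shapes degenerate at
  a scale (sub-window too small) contribute 0.
- **HOG** — central-difference gradients, magnitude-weighted orientation
  histogram over K = 9 equal bins on [0°, 180°) (two-argument arctangent
  folded to half-turns, which is defined at vertical edges), normalized to
  sum 1; a gradient-free window yields the zero vector.

Borders are handled by edge replication so the descriptor field covers the
full grid.  `extract_features` is the per-pixel reference implementation;
`feature_maps` computes the same values for all pixels with integral-image
sliding sums, and the two paths are bit-compatible (tested to 1e-9).

## Fusion and classifier

PCA is fit on the centred training features with unbiased (1/(n−1))
covariance scaling; the retained dimension D is the smallest one reaching a
0.95 cumulative eigenvalue fraction (configurable, capped at
min(L−1, n−1)).  Basis signs are fixed (largest-magnitude entry positive)
for run-to-run determinism.

Training pixels are drawn per slice from three regions — mask interior
eroded by the edge band, background eroded by the same band, and the
symmetric boundary band (band default 3 px) — 7000 each by default, capped
at the region size with a warning.  Labels are ±1 from the mask.

AdaBoost runs T = 10 cycles.  Weights start at 1/N; each cycle trains an
RBF-SVM (C = 1) on a weight-proportional bootstrap resample (2000 samples
by default) — resampling was chosen over cost-sensitive SVM training
because it works with any SVM trainer and is seed-controlled.  The kernel
width decreases geometrically, σ_t = σ₀·0.8^(t−1), σ₀ defaulting to the
median pairwise training distance.  The weighted error e_t of the hard ±1
vote gives α_t = ½ ln((1−e_t)/e_t); weights update by
w·exp(−α_t·l·h_t) and renormalize.  Edge cases: e_t ≥ ½ clamps α_t to 0 and
resets weights to uniform; e_t = 0 clamps α_t to 10 (a saturated but finite
vote).  The ensemble margin (the signed sum *before* the sign function) is
mapped through the logistic p = e^C/(1+e^C); a hard ±1 ensemble output
would make the probability two-valued, while the probability image is
visibly graded.  Weak-learner votes are evaluated from the fitted SVM's
support vectors with chunked BLAS kernel products, which is numerically
identical to the standard per-sample prediction (tested) and an order of
magnitude faster on whole slices.

## Seeds

The histogram of rounded gray values is smoothed with a 5-bin moving
average; the mode inside the search band (default [125, 155], tie → higher
intensity) is the liver peak.  Thresholds are s1 = peak − 3·13 and
s2 = peak + 2·13 — offsets stated in HU for contrast-enhanced CT and
applied on whatever intensity scale the image carries (both the band and
the offsets are configuration for non-CT data).  g1 is the strict open
interval (s1, s2); g2 is strictly below s1.  Both are eroded by a disk/ball
of radius 2 (g1 conservatively at the grid border, g2 treating beyond-grid
as background); the largest 8-connected (26 in 3-D) component of the eroded
g1 gives liver seeds and all of the eroded g2 gives background seeds.
Erosion precedes component selection.  For volumes the peak is taken from
the whole-volume histogram.

## Random walker

Edge weights on the 4-connected lattice (6 in 3-D; 8/26 available) are
ω_ij = exp(−β[(1−α)(T_i−T_j)² + α(p_i−p_j)²]) with T rescaled to [0, 1] so
both difference terms share a scale; α = 0.5 and β = 150 are the reference
operating point, and a floor ε_w = 1e-6 keeps the Laplacian positive
definite at large β.  Unseeded potentials solve the reduced SPD system
L_U x_U = −B^T x_S — dense for fewer than 2500 unknowns, otherwise
Jacobi-preconditioned conjugate gradients at tolerance 1e-8.  Lattice
components containing no seed are assigned background with a warning.
Labels are x > ½ strictly, so exact ties go to background.

## Evaluation and scores

Volumetric measures are voxel-count ratios in percent (A gold, B
automatic): ACC (Dice), VOE (1 − Jaccard), RVD = vol(A∖B)/vol(B),
FN and FP relative to the union.  Surfaces are mask voxels with a
face-neighbour outside the mask (grid borders count as outside); distances
are voxel-centre Euclidean in mm via the physical spacing; ASD, RMSE
(true root-mean-square) and MSD (symmetric Hausdorff, unsquared — the
squared-distance spelling sometimes seen is dimensionally inconsistent with
reporting mm) are computed over both directions jointly.  Scores use
S = max(100 − 25 ε/ε̄, 0) with standards VOE 6.4 %, RVD 4.7 %, ASD 1.0 mm,
RMSE 1.8 mm, MSD 19 mm; per-metric scores are displayed rounded half away
from zero, the total averages the *unrounded* scores to one decimal, and
case averages are computed in decimal arithmetic so that averaging printed
two-decimal values never falls a binary half-ulp below a decimal midpoint.

## Phantoms: what they emulate, and what they do not

A phantom is a star-convex "liver" blob (Fourier-perturbed radius, default
base radius 34 px on a 128×128 grid) filled with correlated texture
(Gaussian-smoothed noise, σ = 10, correlation length 2 px) around mean 140,
so the default seeding band applies unchanged; an adjacent "confuser" blob
placed tangent to the liver with mean 143 but *white* noise of σ = 30; and
background at 70 with σ = 2 global noise.  Cohorts jitter centres, radii,
boundary phases and the contact direction, rejecting draws that overflow
the grid.

The confuser's high-variance white noise serves two purposes.  It is the
texture signal itself (several-fold GLCM-contrast ratio against the liver),
and it speckles the confuser's thresholded mask so that erosion dissolves
it and the largest-component step keeps only the liver — the same reason
gas-containing bowel does not survive threshold seeding in CT.  A plain
low-noise confuser cannot play this role: a rasterized tangent contact has
no background pixels in the wedge between the blobs, so no disk erosion can
separate the two regions, and seeds would leak.

What passing phantom tests shows: every stage behaves as specified, and the
probability term closes intensity-matched leaks that defeat the classic
walker.  What they do not show: performance on real CT — phantoms have
step boundaries (no partial-volume ramps), a single confuser, no
anatomy-dependent shape priors, and 128×128 resolution.  In particular the
choice of β matters little on phantoms (threshold seeds already hug the
sharp boundary, and low-β diffusion suppresses leaks geometrically), so the
β = 150 operating point is carried as the method's stated reference rather
than re-derived from phantom sweeps; `beta_sweep` exists to tabulate the
effect on any data.

## Desk-scale problem sizes

The end-to-end experiment in the test suite trains on 10 phantom slices
(7000 samples per region, capped at region size — about 11 000 samples per
slice at 128×128) and evaluates on 5 held-out phantoms; a full run takes a
couple of minutes on one CPU.  The mechanism is scale-free: the same
pipeline runs unchanged on 512×512 slices, only slower.

## Known limitations

- Descriptors are 2-D; volumes get per-slice probabilities.
- Two labels only (liver vs background); no multi-organ walker.
- The probability image is calibrated only by the logistic map of the
  ensemble margin — no held-out calibration refit.
- Seeding assumes the liver is the dominant homogeneous structure in its
  gray band; images violating that need a custom search range.
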