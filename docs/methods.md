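# Methods

`sagakit` quantifies 3D collective invasion of tumour spheroids from
time-lapse image stacks, measures invasive-chain dynamics from cell
tracks, and tests for leader-vs-follower differential expression with a
permutation procedure that controls for photoconversion artifacts.  This
note records the models, the defaults and why they were chosen, and what
the synthetic benchmarks do and do not demonstrate.

## Imaging pipeline

**Projection.** A 4D stack (t, z, y, x) is reduced to (t, y, x) by the
sample standard deviation (divisor n−1) of intensity along z.  Invading
structures are optically heterogeneous across z while the background is
flat, so the z-std projection enhances dim branches far better than a
mean or max projection.  The divisor convention matters only as a global
scale and is fixed at n−1.

**Smoothing.** Isotropic 3D Gaussian over (t, y, x), default
`gaussian_sigma = 1.0` px.  One pixel of smoothing suppresses shot noise
without erasing branches a few pixels wide; σ = 0 disables the step.

**Segmentation.** Default is a two-class binary Markov random field over
the 6-connected (t, y, x) lattice solved exactly by max-flow/min-cut
(`scipy.sparse.csgraph.maximum_flow`; capacities quantised at 0.01):

* unary terms: homoscedastic two-class Gaussian negative log-likelihoods.
  Class means come from a global bimodal (Otsu) initialisation, the shared
  variance is the pooled within-class variance, and the class pair is
  re-centred so the unary decision boundary sits exactly on the
  initialisation threshold.  Heteroscedastic class models were rejected:
  the wide foreground class absorbs blurred-edge pixels and inflates the
  mask by several pixels.
* pairwise terms: contrast-sensitive Potts,
  λ·exp(−(Iᵢ−Iⱼ)²/(2β²)), default λ = 2; β² defaults to the mean squared
  neighbour difference.  Temporal edges give the labelling coherence
  across frames.

A global-Otsu `threshold` method is kept as an independent oracle and
fallback.  On a genuinely bimodal image (a near-noiseless projection,
before smoothing) the two methods agree to Dice 1.0; with pre-smoothing
the Potts term rounds ambiguous ramp pixels at branch tips, which is a
property of the blurred input, not a defect of either method.  An image
with no separable foreground yields an all-background mask plus a
recorded warning.

**Polishing.** Per frame: morphological closing (disk, default radius 2),
hole filling, then retention of a single connected component — the one
overlapping the previous frame's component most (frame 0: the largest;
ties by size, then by centroid proximity to the image centre).

**Features.** Per frame, from the polished mask:

* area = foreground pixel count; centroid = pixel mean;
* invasive radius = max Euclidean distance from the centroid to a
  boundary pixel (foreground with a 4-connected background neighbour);
* perimeter = length of the outer marching-squares contour after a
  5-point circular moving average.  The raw staircase polygon
  overestimates smooth perimeters by ~7% (a digital disk of radius 20
  would report circularity 0.87); the smoothed contour reports 0.99 for
  the disk while moving an axis-aligned square only from 0.797 to 0.824
  (ideal π/4 ≈ 0.785);
* circularity = 4πA/P² (the ImageJ definition);
* branch count = endpoints (skeleton pixels with exactly one 8-connected
  skeleton neighbour) of the skeleton after iteratively stripping
  endpoint pixels `spur_prune_length` (default 3) times, which removes
  rasterisation spurs; a solid disk therefore reports 0 branches;
* core area = area after morphological opening with a disk of
  `core_opening_radius` (default 6 px, a branch-width scale): opening
  removes thin protrusions, approximating a manually traced core;
  invasive area = area − core area, exactly, in pixel counts.

Lengths are pixels; µm and hours are emitted when a pixel size (µm/px)
and frame interval (minutes) are supplied.

## Track metrics

A track is ≥2 samples (frame, x, y) at strictly increasing frames.  Path
length is the sum of consecutive Euclidean steps (a missing-frame gap is
a single straight step); displacement is first-to-last distance; the
triangle inequality guarantees path ≥ displacement.  Two velocities are
reported because both readings of "velocity" occur in practice:
`mean_velocity` = path length / elapsed time and `net_velocity` =
displacement / elapsed time.  Splitting at a detachment event computes
both halves independently with the event sample shared.  Speed-ratio
recovery checks use `net_velocity` on ballistic (persistence 1) tracks:
with positional jitter σ, each measured step of true length v has
expectation ≈ √(v² + 2σ²), so path-based speed is biased upward exactly
where v is small (after detachment), while the net velocity of a straight
track is unbiased to first order.

## Permutation differential-expression test

Design: four groups × n = 3 replicates — leader (L), follower (F),
photoconverted invasive control (IR), non-photoconverted invasive control
(NG).  The controls calibrate the photoconversion artifact: a gene that
responds to photoconversion itself shifts both L (photoconverted) and IR.

For each gene and direction, all n² pairwise differences are formed
between L and F samples (treatment set; reversed for the follower
direction) and between IR and NG samples (control set).  Two statistics:
`t_one`, the one-sample t of the treatment differences against zero, and
`t_two`, the pooled-variance two-sample t of treatment differences versus
the *absolute* control differences.  Zero-variance cases take ±∞ by the
sign of the numerator (0 at 0); with equal set sizes the Welch variant
coincides with the pooled statistic, so the `welch` flag only matters for
unbalanced extensions.

**Null model.**  The permutation must preserve the dependence inside each
difference set: the n² cross differences are built from 2n samples, so
they are strongly correlated, and reshuffling the 2n² difference values
directly produces permuted sets that are *less* correlated than the
observed ones — in simulation that inflates the global-null selection
rate at α = 0.05 to ≈ 0.28.  The default `regroup` scheme instead
reassigns which 3 of the 6 minuend samples {L, IR} and which 3 of the 6
subtrahend samples {F, NG} form the treatment grid, the complements
forming the control grid: C(6,3)² = 400 assignments, enumerated
exhaustively.  Every permuted grid then has exactly the observed
dependence structure.  Under the no-difference null the 12 samples are
exchangeable across these regroupings, and a photoconversion-artifact
gene (equal shift in L and IR) is *distributionally invariant* under
them, so artifact genes are selected only at the nominal rate — the
purpose of the construction.

**p-value.**  For each assignment a the joint-exceedance count
N(a) = #{b : t_one(b) ≥ t_one(a) and t_two(b) ≥ t_two(a)} is computed;
the p-value is the fraction of assignments at least as extreme as the
identity (smaller N, ties broken by larger t_one — a total order, so the
identity's rank is uniform under exchangeability and the test is exact).
Directly thresholding the raw joint count is anti-conservative (the
dominance relation is a partial order; measured type-I ≈ 0.11), while
requiring both marginal permutation p-values below α is valid but
markedly conservative (≈ 0.016); the calibrated count achieves ≈ 0.046 at
α = 0.05 in a 2000-gene global-null simulation.

A literal difference-pool reassignment (`scheme="pool"`) is retained: it
pools the 2n² signed differences, gives n² of them the treatment role and
n² the control role (absolute value applied), and reports
(count + 1)/(B + 1) for B sampled distinct assignments or the exact
fraction under exhaustive enumeration (C(8,4) = 70 for the reduced
2-replicate design).  It is used to validate the sampling machinery
against enumeration; it does not control the type-I error and never
drives selection.

Selection is at raw p < 0.05 in each direction, as the study design
prescribes; Benjamini–Hochberg q-values are emitted as supplementary
columns only.  One assignment plan per direction is shared across all
genes and recorded as a digest in the run metadata.

Preprocessing utilities mirror the expected microarray pipeline: log2
transform, quantile normalisation (rank means; ties receive the mean of
their ranks' means), and mean probeset-to-gene summarisation.  CEL-level
vendor corrections are out of scope; the pipeline ingests a numeric
matrix.

## Synthetic data: what it emulates, and what it does not

**Spheroid phantoms** are a bright core disk plus radial rays (capsules of
width `branch_width` whose tip sits at radius core + rate·t) on a flat
background.  Foreground columns carry a linear intensity ramp across z
(mean `fg_intensity`), so their z-std exceeds the (zero) background
z-std — the property the projection exploits — while keeping every truth
quantity closed-form.  Rays are spaced evenly with a random global
rotation: even spacing keeps the centre of mass at the core centre, so
the analytic invasive radius (from the centre) coincides with the
centroid-based measured definition.  Rays have zero length at frame 0
while the truth branch count stays constant, so the first frame of a
movie is undetectable by construction; the benchmark movies use 12 frames
so that this frame is a known 8.3% floor on branch-count disagreement.
The phantoms do not model PSF blur, photobleaching, intensity gradients,
branch curvature or branch birth/death; passing the recovery benchmarks
therefore demonstrates correctness of the measurement chain, not
performance on real microscopy.

**Tracks** are persistent random walks (direction mixing parameter
`persistence`, 1 = ballistic) with a step-length drop at a detachment
frame and optional positional jitter.  Real chains additionally exhibit
confinement and collective coupling not modelled here.

**Expression matrices** are i.i.d. Gaussian on the log2 scale (baseline
mean 8.0, sd 0.25 — a typical post-normalisation array scale) with
additive effects: leader-up genes shift the 3 leader samples by δ,
follower-up genes the follower samples, artifact genes both the leader
and the IR samples.  Real arrays have correlated noise, heavy tails and
intensity-dependent variance; the simulations validate calibration of the
test under its own assumptions.

## Benchmark study conditions

Fixed in `sagakit.benchmarks` and reported by `scripts/acceptance.py`:
50 random phantoms (12 frames, 176² px, 6 z-planes, 3–8 branches, core
12–16 px, growth 4.5–6 px/frame, noise 4% of projected contrast) for
parameter recovery; 3 near-noiseless phantoms for the graph-cut/threshold
Dice; 1000 random walks for the triangle inequality and 100 tracks per
noise level for 4:1 speed-ratio recovery; 2000 genes × 3 seeds × 2
directions for the global-null selection rate; 200 effect genes per
condition for power (δ ∈ {0.5, 1, 2}·sd) and artifact exclusion
(δ = 4·sd).  These sizes keep each routine deterministic given its seed
and the full run under a minute of compute while holding Monte-Carlo
error on reported rates to a few percent.

## Known limitations

* The graph-cut energy is a standard contrast-sensitive binary MRF; no
  attempt is made to reproduce any particular historical implementation's
  energy, and λ, β, σ are exposed configuration, not fitted values.
* The inner "core" is defined by morphological opening; for spheroids
  with sheet-like (wide) protrusions the opening radius conflates sheet
  and core, and circularity is then the more informative readout.
* The permutation test's exactness argument requires group-level
  exchangeability under the null; batch structure aligned with the
  photoconversion axis would violate it.
* With n = 3 replicates the assignment group has 400 elements, so
  attainable p-values are multiples of 1/400 and the smallest is 0.0025.
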