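# Methods

`organotrack` quantifies tumor-organoid / fibroblast 3D co-cultures from
two kinds of imagery: long-running two-channel time-lapse sequences (phase
contrast + green fluorescence, nominally one frame per hour) and end-point
confocal maximum projections. This note records the models, the parameters
that matter, the numerical choices, and what the synthetic phantoms do and
do not establish.

## Stabilization

Sequential imaging introduces frame-to-frame camera jitter. A pure
translation model is assumed: for frames *f*, *g* related by a shift Δ,
the normalized cross-power spectrum T(u) = F·G\*/(|F|·|G|) equals
e^{2πiu·Δ}, so the inverse transform peaks at the shift (phase
correlation). Numerical choices:

- **Relative spectral floor.** Instead of whitening every frequency to unit
  modulus, the cross-power magnitude is floored at 10⁻⁶ of its maximum.
  Frequencies whose signal has been wiped out (defocus blur, noise) then
  contribute negligibly rather than as unit-modulus noise. This leaves the
  peak location of clean integer shifts untouched and makes even the
  standard method usable on blurred frames.
- **`blur_robust` method**: phase correlation on gradient-magnitude images,
  for heavily defocused movies. On our blur phantoms both methods stay
  within 1 px; the gradient variant is never worse.
- **Hann taper** (default on) suppresses wrap-around edge energy on real,
  non-circular scenes. The integer-jitter phantoms are circular by
  construction, so exact-recovery tests disable it.
- **Sub-pixel refinement** is a separable three-point parabola around the
  peak, clamped to ±0.5 px; disabling it yields pure integer estimates
  (exact on integer-jitter phantoms).
- Compensation accumulates consecutive-pair shifts against frame 0; output
  is cropped to the rectangle covered by every compensated frame, never
  padded. Cumulative drift beyond half the frame is an error.

## Denoising

Median 5×5 → non-local means (patch 7×7, search 31×31, h = 15; scikit-image
fast variant, outputs clipped to the input range) for the fluorescence
channel. The tumor (phase) channel uses two cascaded NLM passes followed by
mean-shift filtering. Mean-shift is implemented as iterated joint
spatial/range averaging (box window of radius 10 px, range radius 10
intensity units, ≤5 iterations), computed by an intensity-binned
decomposition (bin width = range_radius/2) so each iteration is a handful of
box filters rather than a sliding-window scan. All windowed filters use
mirror-reflection borders; the test oracles pad the same way.

## Fibroblast (CAF cohort) segmentation

Cohorts are segmented by local adaptive thresholding: each pixel is compared
with the Gaussian-weighted mean T(x, y) of its (2k+1)×(2k+1) neighborhood
(default k = 25, σ = (2k+1)/6, weights w(i,j) ∝ e^{−(i²+j²)/σ²} normalized
to unit sum). A pixel is foreground iff p − κ > T with κ = 2 by default and
ties falling to background. κ is applied on the pixel side, so it acts as a
noise margin: flat regions (where p ≈ T) are background for any κ > 0, and
raising κ can only remove foreground. Components are 8-connected; regions
under 50 px are removed as noise; the region enclosed by each cluster's
outer boundary is filled, since the cluster is the unit of measurement and
a flat bright interior (whose whole neighborhood is equally bright) would
otherwise fall below its own local mean. Growth is the total foreground
pixel count per frame; the growth rate divides by the first frame's area,
so element 0 is exactly 1.

Known limitation: a convex object whose inscribed radius greatly exceeds
the Gaussian's effective support would still be measured through its filled
outline, but its interior texture is invisible to the local threshold;
density-type measures for such objects should use the morphometrics module.

## Motility (dense optical flow)

Farnebäck-style polynomial expansion: each neighborhood is modeled as
f(x) = xᵀAx + bᵀx + c, fit by weighted least squares with a Gaussian
applicability (window poly_n = 5, poly_sigma = 1.1). Because the weights are
spatially constant, the fit reduces to six correlations and a constant 6×6
normal-matrix inverse. A displacement d of the quadric implies
A₂ = A₁, b₂ = b₁ − 2A₁d, i.e. d = −½A₁⁻¹(b₂ − b₁); the estimator averages
the pointwise normal equations over a 15-px box, iterates 3 times with
bilinear warping, and refines coarse-to-fine over a 3-level pyramid.
Near-singular windowed systems get Tikhonov regularization (ε = 10⁻⁶) and
are flagged invalid. Identical frames short-circuit to an exactly zero
field.

Per-frame motility is the mean displacement magnitude over the
segmentation-mask foreground (empty mask → 0). The mask restricts the
average to the cellular compartment; background flow is dominated by noise.

## Branching (convexity defects)

Each cohort's closed outer contour is traced at sub-pixel level 0.5
(marching squares on a padded copy, so border-touching clusters still close).
The convex hull comes from qhull; for each gap between consecutive hull
vertices along the contour, the deepest intermediate point and its
point-to-chord distance define one convexity defect. Defects deeper than
`depth_threshold` (default 5 px) count as extensions; extension size is the
defect depth. The star phantom provides an analytic oracle: a star with
outer radius R and inner radius r has notches of depth exactly
R·cos(π/n) − r. Depth is Euclidean point-to-line distance; rasterization
tolerance in tests is ±1 px.

## Tumor organoid segmentation

Phase-channel pipeline: heavy denoise (above) → adaptive threshold →
morphological closing then opening with a 3-px disc → hole filling →
small-region removal → subtraction of the fibroblast mask (channels are
registered after stabilization). Subtraction wins at contact pixels, so
organoid and fibroblast masks are disjoint by construction; the count of
removed pixels is reported per frame. Collagen-only sequences are accepted
with a warning: granular pure-collagen backgrounds segment unreliably.

## Confocal MRF segmentation

Maximum projections are scaled to 8-bit and passed through a local entropy
filter (disc radius 3; texture boundaries blur by roughly the disc radius,
which is why the radius is small). A 3-component Gaussian mixture (EM,
k-means++ init, 5 restarts, best log-likelihood, spherical covariances
floored at 10⁻⁶) is fit to the entropy values — on ≥ 50k subsampled pixels
for large images — and components map to labels in mean order: background <
cell shadow < in-focus cells. Unaries are θ_{i;l} = −log f_l(z_i) with the
density floored at 10⁻¹²; pairwise terms over 4-neighbor pairs are
θ_{ij;lk} = λ₀ + λ₁·e^{−½β(z_i−z_j)²} for l ≠ k and 0 otherwise, with the
contrast z taken from the 8-bit intensities. Defaults λ₀ = 0.5, λ₁ = 2.0,
β = 0.05 were chosen from the unary-potential distribution on the phantoms
(a helper, `unary_quantiles`, prints per-label quantiles to guide manual
setting on other data). This energy is a scaled Potts metric whenever
λ₀, λ₁ ≥ 0.

α-expansion solves each move as a binary min-cut
(Boykov–Veksler–Zabih auxiliary-node construction) via
`scipy.sparse.csgraph.maximum_flow` on fixed-point capacities (scale 2²⁰).
Moves are accepted only if the true floating-point energy decreases, so the
energy is monotonically non-increasing regardless of rounding. Expansion is
a local search; by default the solver restarts from the maximum-likelihood
labeling and from each constant labeling, each under every label visiting
order, and keeps the best result — a deterministic 24-run portfolio that
reaches the exhaustively-verified global optimum on every tiny random
instance we test. 3-D stacks are segmented as maximum projections; a voxel
graph is out of scope.

## Morphometrics

Per-organoid parameters: Area (pixel count); Roundness = 4πA/P² with the
Crofton perimeter, clipped to ≤ 1 (≈1 for discs, falling as the outline
roughens); Density = mean channel intensity over the object; FiltRound =
Roundness after an opening with a 4-px disc that strips thin protrusions;
appendages are skeleton branches protruding beyond that opened body, their
lengths measured as geodesic diameters of the branch pixels (8-connected,
diagonal √2), giving AppNumber/MaxApp/MedApp; CellNumber = Area / 250 px²
is a calibrated proxy, clearly an estimate, not a count. These formulas are
this package's own concrete definitions of the classic multi-parametric
organoid read-outs; they are not a bit-compatible clone of any prior tool.

Group statistics: two-sided Mann–Whitney U (exact for small tie-free
samples) or Welch t-tests of each group against the control, Bonferroni
multiplied by the number of comparisons in the call and capped at 1.
Direction comes from medians (U) or means (t). Heatmaps report log₂ fold
change of group median over control median with the aligned adjusted-p
matrix; a zero control median flags the cell as NaN with a warning.

Growth curves are normalized pointwise to the vehicle control and expressed
in percent, so the control maps to a flat 100% line and the final-point
inhibition is 100·(1 − treated/control). Curve smoothing for display is a
centered 5-frame moving average (truncated at the ends); raw values are
always retained.

## Synthetic phantoms — what they do and do not show

The generators emulate the statistical structure the pipeline assumes:
bright star-shaped "cohorts" with geometric area growth (linear scale grows
by √(1+g) per frame), known integer jitter applied as a circular scene
shift before per-frame Gaussian read noise, a smooth multiplicative
background field (Gaussian-filtered noise, ±25%) standing in for ECM
granularity, organoid discs with thin appendages of known count and length,
and three-label confocal scenes with per-label Gaussian intensities (texture
contrast via per-label σ when the entropy pathway is under test). Everything
is deterministic under a fixed seed, and ground-truth areas are exact drawn
pixel counts.

They do not emulate: photobleaching, focus drift, cell division and death,
deformable motion, anisotropic PSFs, or real ECM fiber structure. Passing
the phantom suite therefore demonstrates the correctness of the
measurement machinery (registration, thresholding formula, flow solver,
hull geometry, energy minimization, statistics), not biological validity on
any particular instrument's data; the config surface exists precisely so the
tunables can be recalibrated per data set.

Problem sizes in the test suite and acceptance script (160–512 px frames,
5–30 frames, 50k mixture samples, 1000-rep null simulations) were chosen so
rasterization and estimation error sit well below the stated tolerances
while a full run stays in the minutes range on a single CPU.
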