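# Methods

`stereoslant` implements model observers for slant and depth
discrimination of textured planar surfaces from binocular disparity, the
stimulus synthesis those observers are evaluated on, and the psychometric
machinery that turns simulated estimates into discrimination thresholds.
This note records the model, the numerical choices, and what the
simulations at the package's default problem sizes do and do not show.

## Viewing geometry and the plane-induced map

Both eyes are pinhole cameras with nodal points at `x = ±a` (interocular
distance `2a = 6.5 cm` by default), zero vergence, projecting onto a
single shared image plane at `z = D = 100 cm` on the cyclopean axis.
Image coordinates are degrees through the tangent map
`X_screen = D·tan(x)`; left and right images share one raster, so a
surface lying in the image plane has zero disparity by construction.

A plane is parametrized by slant `s` (rotation away from frontoparallel),
tilt `τ` (direction of the depth gradient in the image; tilt 0 means a
horizontal gradient) and intercept distance `ζ` (where the plane crosses
the cyclopean axis):

    Z = ζ + tan(s)·(X·cos τ + Y·sin τ)

Sign conventions (tilt 0): positive slant puts the right half of the
surface farther away; `ζ > D` is uncrossed disparity, `ζ < D` crossed.

Mapping an image point in one eye to the other eye through a plane
(back-project along the eye ray, intersect, re-project) has a closed form
that the test suite validates against an independent numeric ray tracer to
better than 1e-9 degrees, along with exact round-trip invertibility.  For
tilt-0 planes the map is 1-D projective in `x` and leaves `y` unchanged on
the shared image plane; the matching observers exploit this to resample
along rows only.

Local surface patches are parametrized by `(s_i, z_i)` — slant and the
depth of the patch-center surface point — rather than `(s_i, ζ_i)`,
because slant and intercept estimates become strongly correlated away from
the cyclopean axis while slant and point depth stay nearly independent.
The two parametrizations are related exactly by `ζ_i = z_i − x_i·tan s_i`
with `x_i` the lateral position (cm) of the patch-center surface point;
the conversion is an exact involution (tested to 1e-9).

## Stimuli

Surface textures are sums of 59 sinewaves with frequencies 0.1–3
cycles/degree in 0.05 cpd steps (as seen frontoparallel at 100 cm; one
degree ≙ `100·tan 1°` cm on the surface), equal amplitudes, random
orientations uniform on [0, π) and random phases uniform on [0, 2π).  The
common amplitude is set so the expected planar RMS contrast is 14.7%
(`A·sqrt(K/2)` for K equal-amplitude components).

Two conventions deserve a note:

* **Phase range.**  Orientations on [0, π) cover all sinewave
  orientations, but phases restricted to a half circle would give every
  component a nonzero spatial mean — summing 59 such components adds a
  coherent, seed-independent ridge near the origin and inflates measured
  RMS contrast to ~17%.  Full-circle phases are therefore the default
  (a `phase_range` argument exposes the alternative), and with them the
  measured contrast is the nominal 14.7%.
* **RMS contrast** is measured about the true (zero) mean luminance, not
  the sample mean of the analysis window: the lowest components complete
  only ~0.2 cycles across the 2.23° window, so their contribution to the
  window's sample mean is texture signal, not an offset.  With this
  convention the expectation of the measured RMS equals the nominal value
  exactly, for any window size.

Rendering is analytic: each raster pixel's eye ray is intersected with
the plane and the texture is evaluated in closed form at the in-plane
coordinates of the intersection.  No interpolation enters rendering, so
the left and right images are exact perspective views of one 3D texture.
Independent Gaussian white-noise fields (RMS contrast 5%, 17.5%, or 34%
in the standard conditions) are added per eye.

Both eyes' images are rendered over the analysis rectangle plus a margin
(default 0.5° horizontally, 0.25° vertically).  This mirrors the
experimental display, where texture and noise extended beyond the test
region, and matters numerically: the prefilter kernel spans about a
degree, so filtering a bare window against zero padding would imprint
edge artifacts well inside the analysis region.  The model observers are
restricted to the 2.23° × 2.12° right-eye analysis rectangle regardless
of the rendered support.  The experiment's trapezoidal silhouette jitter
is a display-side manipulation against monocular cues and is not
modelled; observers always analyze the fixed rectangle.

## Prefiltering

Before matching, both eyes' images pass one radially symmetric low-pass
filter: gain 1 below the ramp, a half-cosine ramp of 1 cpd span centered
on the cutoff, 0 above.  Filtering is frequency-domain on a zero-padded
window (2° pad; the suite checks agreement with direct spatial
convolution).  The filtered-noise SD `σ_f` follows from Parseval's
relation — the mean squared gain over the raster's frequency square —
and is verified against Monte-Carlo filtering of white noise.

The performance-optimal cutoff trades off passed noise power against
slant-compressed texture content above 3 cpd.  A pilot search
(`optimize_cutoff`) reproduces the standard assignments used throughout:
16, 8, and 5 cpd for 5%, 17.5%, and 34% noise.  The threshold-vs-cutoff
curve is flat within 1–2 cpd of the optimum, so at reduced simulation
scale the measured argmin can land one step to either side.

## Matching observers

All observers minimize the same quantity: the squared error (per valid
pixel) between one eye's filtered image and its prediction resampled from
the other eye through a candidate plane, equivalent under the uniform
prior (slant ±70°, intercept 100 ± 1 cm) to the maximum-posterior rule.
A normalized-correlation error (`1 − r`) is available as an alternative
metric.

* **PM** searches global `(s, ζ)` over the whole analysis rectangle.
* **LPM** runs the same search per square patch over `(s_i, z_i)`, then
  pools: regressing `ẑ_i` on lateral position gives one slant estimate
  (`atan` of the slope, with the intercept estimating `ζ`) — the
  closed-form minimizer of the pooled-distance objective, verified
  against grid minimization; averaging `ŝ_i` gives a second; the two are
  combined by reliability (inverse-variance) weighting.  Reliabilities
  come from the dispersion of bias-corrected estimates over repeated
  simulated stimuli of the same condition (`calibrate_reliability`); in
  the threshold harness they are calibrated from the condition's own
  trials.
* **LFM** is LPM with the local slant clamped to zero — a pure
  horizontal-shift search, i.e. standard cross-correlation — and is
  asserted to be bit-identical to LPM run with a `{0}` slant grid.

Numerical choices:

* **Interpolation.**  Prediction resamples the source image with a
  separable quintic B-spline, exact at grid nodes.  Pixels whose
  pre-image falls outside the analysis rectangle, or within the spline's
  3-pixel half-support of the raster border, are flagged invalid and the
  error is renormalized by the valid-pixel count.  Measured interior
  interpolation error on band-limited textures is below 1% of texture RMS
  contrast (asserted in tests).
* **Search.**  Coarse-to-fine refinement over the parameter rectangle
  (slant coarse step 2.5°, final 0.25°; intercept coarse 0.25 cm, final
  0.02 cm; local searches: slant to 1°, distance to 0.02 cm, and 0.002 cm
  in the depth task where thresholds are a few thousandths of a cm).
  Grids live on the final-step lattice so an on-lattice minimum is hit
  exactly; ties break to the first (lowest) grid index.  Agreement with
  exhaustive search is asserted on seeded noisy stimuli.
* **Patch layout.**  Square patches of width `w` (default 0.5°) on a
  stride of `w/2`, as many as fit fully inside the window with the set
  centered.  The stride is configurable; per-pixel patch placement is a
  limiting case the defaults do not attempt.
* **Prediction direction.**  Right-to-left by default; the opposite
  direction changes estimates by less than their dispersion (tested).

## Thresholds and the two-parameter model

Discrimination is summarized by a cumulative Gaussian
`p = Φ((Δs − β)/(k·σ))` with `k = 1`, so `d′ = Δs/σ` and the threshold
(`d′ = 1`) equals σ.  The harness computes model thresholds by the
moments route: simulate slant-difference estimates at four levels placed
at ±0.75 and ±1.5 pilot SDs around the reference, take the bias-corrected
pooled dispersion σ and the response slope b (least squares of mean
estimate on level), and report `σ/b`.  The trial route — binary responses
fitted by maximum likelihood — is implemented in full (with binomial
bootstrap CIs) and agrees with the moments route within Monte-Carlo error
on synthetic estimators; the moments route needs an order of magnitude
fewer trials and is the default for model observers.

Real-observer data enter through the two-parameter model: an efficiency
scalar ε and internal estimation noise σ₀ added in quadrature,

    d′(Δs) = ε·Δs̄ / sqrt(σ² + σ₀²),    Δs_t = (1/ε)·sqrt(σ² + σ₀²),

fitted to trial-level data by maximum likelihood (`fit_noise_efficiency`;
`efficiency_scalar` is the σ₀ = 0 special case used for cross-task
efficiency comparisons).  Since the original trial-level human data are
not published, these fitting routines are exercised on synthetic data
with known parameters (recovery within bootstrap intervals) and on
threshold tables engineered to have known observer scale factors.

Mirrored reference-slant conditions merge by reflecting the slant
difference and the response; observer threshold curves are aligned by a
single least-squares multiplicative factor per observer.

The depth task fixes the test-plane slant at ±44° (its edges then
straddle the frontoparallel reference at 100 cm by about ±2 cm), varies
the center distance, and reads the near/far decision from the estimated
window-center distance (PM searches distance with the slant clamped to
the known value; the local observers' pooled intercept is their center
distance).  Thresholds are reported in arcsec of equivalent disparity —
the angular-disparity change per cm of distance at 100 cm, 134.07
arcsec/cm — and in mm.

## Problem sizes, reproducibility, and limitations

The default harness runs 50 estimate draws per psychometric level; the
test suite uses 12–16 draws per level with fixed seeds and reports
bootstrap confidence intervals for every stochastic comparison.  At these
sizes the qualitative structure is stable and clearly resolved —
threshold ordering PM < LPM ≤ LFM, monotonicity in noise and reference
slant, the U-shaped cutoff curve, the patch-width trade-off — while
individual thresholds carry roughly 10–20% Monte-Carlo error.  Every
experiment cell derives its random stream deterministically from the
experiment seed and the cell's key, so reruns reproduce outputs
byte-for-byte.

The synthetic stimuli are idealizations: an infinite textured plane
sampled over a rectangular window, no silhouette or aspect-ratio jitter,
no display quantization or gamma, no monocular-cue suppression to model,
and eye pose known exactly.  Passing tests therefore speak to the
disparity computations, not to monocular-cue handling, non-planar
surfaces, half-occlusions, or eye-pose uncertainty — all outside this
package's scope.
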