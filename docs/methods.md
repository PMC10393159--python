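# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of `nictrack`. Units are micrometers, seconds, and 8-bit gray
levels unless stated otherwise. The default physical calibration is
3.75 µm/px at 5 frames/s.

## Coordinate and geometry conventions

Pixels are indexed row-major, 0-based; a pixel's physical position is its
center, `µm = px × um_per_px`. Centerlines are 50 ordered (x, y) points in
µm, equally spaced by arc length, running **tip to tip**: the body is
modeled as a constant-width tube with semicircular caps, and the centerline
spans the full visible extent, nose apex to tail apex. A rendered or
rasterized tube is therefore stamped around the *spine* obtained by
trimming half a body width from each end of the centerline; the round caps
restore the tips. This matches the ridgeline extractor, whose endpoints are
the most convex points of the ROI outline — i.e., the tips.

## Synthetic arena and worms (`nictrack.synth`)

The generator emulates top-down recordings of dispersal-stage nematodes on
a molded micropost arena.

**Arena.** Posts are darkened discs (diameter 50 µm) on a rectilinear grid
(75 µm center-to-center), with a stronger dark rim just inside the disc
edge, emulating light scattering at the molded post wall. The interior
darkening is 35% and the rim 65% of `post_edge_darkening` (default 40 gray
below a background of 180). Optional background jitter is a Gaussian random
walk of the whole field, clipped to the stated amplitude — the residual
arena motion that motivates video stabilization.

**Locomotion.** Each worm is a head-trail model: the head advances at
`crawl_speed` (default 50 µm/s) with heading = base heading +
`wave_amplitude · sin(2π t / period)` (defaults 0.55 rad, 2 s), and the
body occupies the trailing `length` µm of the head's path — the
track-following gait of real crawling nematodes. The base heading steers
smoothly toward the center of the worm's roaming cell when the head nears
the cell boundary, so distinct worms never touch (the frame is partitioned
into per-worm cells, inset by 0.55 body lengths). The initial body is
seeded by walking the trail backwards with the same steering rule. On a
straight path the centroid advances exactly `crawl_speed / fps` per frame;
undulation reduces the centroid speed by the usual chord-vs-arc factor
(about 7% at the default amplitude).

**Behavior.** Each worm carries a two-state continuous-time Markov chain
(recumbent ↔ nictating) sampled at the frame rate with per-frame switch
probability `1 − exp(−rate/fps)` — the exact discretization of a rate in
Hz at any fps. Default rates are (0.073, 0.094) Hz, typical trainer-scored
dauer values, giving a stationary nictation fraction of ≈ 0.44. The
initial state is drawn from the stationary distribution.

**Nictation rendering.** A nictating frame freezes translation, shortens
the rendered body by `nictation_foreshortening` (default 0.35, emulating
the elevated portion leaving the image plane), and defocuses the image
near the leading tip (Gaussian blur, σ = 1.6 px, blended with a weight
that decays linearly over 0.6 body lengths from the tip). These are
exactly the cues the behavioral features measure: speed, length, and
focus. The label mask is the *sharp* tube support — defocus affects
intensities, not ground-truth geometry.

**Worm dimensions.** Default 500 × 25 µm, giving a rendered area of
~12,400–13,600 µm², inside the 3674–16533 µm² ROI acceptance band used for
dauers.

**What the generator does not emulate** — and hence what passing tests do
not show about real recordings: true 3-D elevation and perspective,
worm–worm contact and occlusion, worm–post occlusion effects on intensity
(worms are drawn over posts), illumination drift, optical noise, and the
full diversity of real postures (the generator's curvature distribution is
set by the gait parameters). Classifier accuracies measured on synthetic
data are upper bounds: the features separate the synthetic behaviors by
construction.

## Segmentation (`nictrack.segmentation`)

Intensity route: pixel-wise **max-merge** of all frames forms a worm-free
background (dark worms vanish under the maximum wherever they move);
clamped `background − frame` makes worms bright on ~0; Gaussian smoothing
(σ converted µm→px and rounded to 2 decimals of a pixel — not an integer,
so 1 µm σ increments remain distinct) precedes binarization at
**strictly greater than** *t* (so *t* = 0 segments everything nonzero).
Connected components are 8-connected — tolerant of 1-px diagonal necks
over post edges. Components outside the species' area band or touching the
frame edge are discarded. Video stabilization is translation-only subpixel
phase correlation against a reference frame; the method choice is the
package's own (only the fact of stabilization is prescribed by the
workflow it implements).

Adapter route: per-frame soft instance masks with confidence ≥ 0.7 are
max-merged, scaled to 0–255, and sent through the *same* smoothing and
thresholding code path. Segmentation evaluation (detection / IoU against
the union of overlapping ROIs / gaps = overlapping ROIs − 1 / centerline
RMSD minimized over both orientations and overlapping ROIs) is applied
after area filtering: the evaluation sees what the tracker sees.

## Centerlines (`nictrack.centerline`)

**Endpoints.** The outline (longest sub-pixel contour) is lightly smoothed
(moving average over ~k/2 vertices) to suppress pixelation jaggies, then
the interior angle at each vertex is measured between the vectors to the
neighbors k = max(3, n/30) steps away, signed by the polygon orientation
so convex tips (small angles) are never confused with concave elbows
(reflex angles). The two smallest local angles at least a quarter contour
apart are the endpoints. If no vertex is distinctly convex (minimum
interior angle > 2.2 rad — e.g. a coiled ball or a disc), the ROI is
rejected as degenerate. The neighborhood k and the 2.2 rad floor were
chosen to separate rendered worms (tip angles ≲ 2.0 rad) from discs of any
size (≥ 2.5 rad).

**Ridge points.** Pixels of the Euclidean distance transform that are ≥
both horizontal neighbors *and* ≥ both vertical neighbors. The ≥ (plateau
tolerant) comparison keeps flat ridges of even-width bodies. Unlike
morphological thinning, this point set rarely grows spurs. Points are
chained by greedy nearest neighbor starting from the ridge point closest
to one endpoint; the jump cap is adaptive, `max(3 px, half-width + 1)`,
because diagonal ridge sections have intrinsic gaps on the order of the
body half-width (a fixed 3 px cap truncates chains on smoothly curved
bodies). Points beyond the cap start discarded branches.

**Spline.** A cubic smoothing spline (smoothing factor 0.25 per support
point, absorbing sub-pixel ridge quantization) through endpoint → chain →
endpoint, resampled to 50 equal-arc-length points. Fewer than four
distinct support points, or any spline failure, falls back to
piecewise-linear interpolation.

**Flags.** `too_long` (> 750 µm), `sharp_angle` (the path bends by more
than 135° at a vertex, i.e. an interior angle sharper than 45°),
`self_intersecting` (exact segment-intersection test over all non-adjacent
segment pairs). Flagged centerlines go to the deformable model; worm-frames
still flagged after repair are censored.

## Deformable model

Nine model points are initialized along the nearest-in-time clean
centerline of the same track. The moving ROI is the tube around the
Chaikin-smoothed (2 rounds of corner cutting ≈ quadratic B-spline) model
polyline, end-trimmed by the half-width; the half-width starts at the
closed-form stadium solution of `π w² + 2 L w = A` and is then adjusted
each iteration by `√(A_target / A_moving)` (clipped to ±10%) so the
*rasterized* areas match — rasterization is a few percent fatter than the
analytic stadium, so a one-shot algebraic solve systematically
under-covers.

Per iteration, each uncovered target pixel attracts each model point with
magnitude `1/(r² + ε)`, ε = 1 px². The forces are applied sequentially:
(1) each point moves along its own force, the largest single-point
displacement normalized to 1 px; (2) the summed force translates the whole
model (≤ 1 px); (3) the summed moment about the model centroid rotates it
(≤ 0.05 rad). Fitting completes after at least 50 iterations once IoU >
0.6 and the best IoU of the trailing 50 iterations exceeds the best before
them by ≤ 10⁻⁴, or at 300 iterations; the best-IoU model encountered is
returned, splined and resampled to a 50-point centerline marked
`corrected`. Step sizes, the sequential (points → translation → rotation)
update order, and IoU as the plateau quantity are the package's own
choices; the procedure is insensitive to them in the benchmark (repair
succeeds on 50/50 displaced-initializer cases).

## Tracking (`nictrack.tracking`)

Greedy closest-centroid-first matching between adjacent frames only (no
gap bridging): all track–detection pairs within the displacement cap are
sorted by (distance, track id, detection index) — the tie-break makes
matching deterministic — and accepted when neither member is taken.
Unmatched detections found tracks; unmatched tracks end. Orientation
alignment reverses a centerline when the summed end-to-end distances to
the previous aligned centerline are smaller reversed. Tracks shorter than
10 s are dropped.

## Features (`nictrack.features`)

The 17 primary features are the package's selection of the motion,
postural, and image cues that distinguish a standing, waving worm from a
crawling one, named by what they compute. The registry is configurable,
but the default is pinned to 17 names to preserve the 136-column contract
(17 × (1 + 2 derivatives + 5 window statistics)).

Definitions worth noting: width = area/length; straightness = end-to-end
distance / length; curvature summaries are turning angles between
consecutive centerline segments (total |·|, max |·|, mean signed); blur =
variance of the 3×3 Laplacian over ROI pixels divided by mean ROI
intensity (drops when the elevated end defocuses); difference-image
activity = mean |frame difference| over the ROI dilated by one half-width;
intensity contrast = surrounding-ring mean minus ROI mean (worms are
dark). Derivatives are one-frame differences × fps (backward and forward);
window statistics use a centered 5-frame window, truncated at track
boundaries, with population variance. Motion features at track boundaries
copy the nearest computable frame, keeping the matrix dense; tracks
shorter than 3 frames are marked invalid. Min-max scaling maps each
column's *training* range to [0, 1]; inference values may fall outside.
Alternatives (none, z-score, robust) exist for the model-comparison
harness.

## Scoring and denoising (`nictrack.scoring`)

Training rows exclude censored frames, frames whose centerline remained
flagged after repair, and everything within 2 frames of those (behavior
near an unscoreable frame is unreliable). Cross-validation partitions worm
tracks (never frames) into k = 5 folds, re-drawing the permutation if a
fold misses a class; scaling is fitted per fold on training rows. The
default model grid: logistic regression, k-NN, decision tree, random
forest, SVC, and a feed-forward network (one hidden layer of 64 units,
early stopping, fixed seed — the architecture is this package's choice).

Denoisers, all operating within tracks and never across censored gaps
(censored frames split a track into independent segments):

- **Gaussian smoothing** of each class-probability series (σ in seconds ×
  fps frames, reflective boundaries), label = argmax after smoothing; σ=0
  is exactly the identity. Probabilities are not renormalized after
  convolution — irrelevant to a two-class argmax.
- **Short-bout removal**: one forward pass; each bout shorter than the
  minimum is merged into the preceding bout (track-initial short bouts
  merge into the following one), re-examining in place so newly merged
  neighbors coalesce. Forward order is part of the definition — a reverse
  pass can differ. The result is idempotent, and every remaining bout
  reaches the minimum length unless the whole track is one bout.
- **Viterbi, state-based**: raw labels are noisy observations with
  emission accuracy a (default 0.95; the intended value is the scorer's
  typical accuracy, e.g. its mean cross-validation accuracy — the choice
  is the package's own), bisymmetric transitions with persistence
  probability P_P, initial distribution from the training-set behavior
  ratio; log-space decoding.
- **Viterbi, probability-based**: the classifier's per-frame probabilities
  are used directly as emission terms, floored at 10⁻¹²: δ_t(s) = p_t(s) ·
  max_{s'} δ_{t−1}(s') A(s', s).

Both decoders are verified against exhaustive enumeration of all 2^T paths
on short tracks. At P_P = 0.5 both reduce exactly to per-frame argmax; at
P_P = 1 the decoded track is constant in the state with the larger total
emission weight (the probability floor makes this limit well-defined).

The smoothing-parameter optimizer evaluates a denoiser over a parameter
grid on held-out cross-validation output and minimizes |relerr NR| +
|relerr IR| + |relerr SR| + (1 − accuracy), skipping terms undefined in
the reference (e.g. SR when the reference contains no terminations).

## Metrics (`nictrack.metrics`)

Each frame contributes 1/fps seconds to its state's time; transitions are
instantaneous at frame boundaries (no half-frame correction). Censored
frames are excluded from all denominators and break transition counting.
NR = nictating/(nictating+recumbent) time; IR = initiations / recumbent
time; SR = terminations / nictating time; TR = all transitions / scored
time; a zero denominator leaves the metric undefined (None), never 0.
Pooled metrics sum counts over tracks before forming ratios — equivalent
to a track-duration-weighted average. Agreement excludes frames censored
in either ethogram. Transition-offset analysis considers reference
transitions with ≥ 2 s of uninterrupted behavior on both sides, reports
the per-offset accuracy curve in a ±2 s window, and the signed offset when
the comparison has exactly one same-kind transition in the window
(multi-transition windows are ambiguous and excluded), with a two-sided
binomial sign test on the nonzero offsets. The recording-duration analysis
computes per-video NR from frames before each cutoff and averages the
groups' relative variances (variance/mean across a group's videos);
snapshot selection picks the frame where every video has ≥ 2 spanning
tracks of ≥ 1 min (ties → earliest, maximizing the total count), each
truncated to its first minute before per-track NR.

## Problem sizes used in tests and the acceptance script

Benchmarks run on synthetic data sized for a single CPU: the centerline
oracle uses 100 postures with heading amplitudes 0–1 rad; the repair
benchmark 50 cases with the initializer displaced by half a body width;
Viterbi verification 200 random tracks of T ≤ 12 (4096-path enumeration);
rate recovery 200 × 60 s tracks; the end-to-end run one 2-minute,
10-worm, 800×800 px video (≈ 6,000 worm-frames), scored by a network
trained on half the tracks with the generator's ethogram as the manual
labels. These sizes give comfortable statistical margins for every
property checked while keeping a full run in minutes.

## Known limitations

- Head/tail identity (anterior vs posterior) is not assigned; orientation
  is only made temporally consistent within a track.
- Colliding worms are not untangled; merged ROIs fail the area filter or
  produce flagged centerlines and are censored.
- Tracks do not bridge missed detections; a single dropped frame splits a
  track (by design, matching adjacent-frame stitching).
- The intensity route assumes a static background brighter than the worms;
  the max-merge background requires each pixel to be worm-free in at least
  one frame.
- The deformable model needs a clean centerline somewhere in the track for
  initialization; tracks flagged everywhere are censored wholesale.
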