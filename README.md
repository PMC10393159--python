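# nictrack

Tracking and automated scoring of nematode **nictation** behavior on
micropost ("microdirt") arenas.

Nictation is the host-finding behavior of dispersal-stage nematodes
(*Caenorhabditis elegans* dauers, *Steinernema* infective juveniles): the
worm stands on its tail and waves the elevated body to attach to a passing
host or carrier. Quantifying it requires scoring hours of video of dark,
~450–550 µm worms crawling over a molded post grid (75 µm center-to-center) —
a textured background that defeats classical worm trackers and makes manual
scoring the bottleneck of whole studies. `nictrack` is a complete, testable
pipeline for this problem, aimed at researchers who record such assays.

## Pipeline

1. **Segmentation** — either classical intensity segmentation (stabilize →
   max-merge background → background-subtract → Gaussian smooth (σ) →
   threshold (*t*) → area/edge filters), or an **adapter** for per-frame
   worm-probability images from an external instance-segmentation model
   (soft masks max-merged above confidence 0.7, scaled to 0–255, then fed
   through the *same* smoothing/thresholding path). A grid-search utility
   benchmarks any (σ, *t*) combination against annotations by detection
   rate, IoU, gap count, and centerline RMSD.
2. **Centerline extraction** — the ridgeline method: body endpoints are the
   two interior-curvature minima of the ROI outline; ridge points are
   distance-transform pixels that are local maxima both horizontally and
   vertically; a smoothing spline through endpoints + chained ridge points
   is resampled to 50 equal-arc-length points. Centerlines longer than
   750 µm, bent sharper than a 45° interior angle, or self-intersecting are
   flagged.
3. **Deformable-model repair** — flagged centerlines (omega turns, etc.)
   are re-fit with a 9-point constant-width tube whose area matches the
   target ROI, initialized on the nearest-in-time clean centerline and
   pulled onto the target by inverse-square attraction from uncovered
   pixels plus a rigid net-force/net-torque update, for 50–300 iterations.
4. **Tracking** — adjacent-frame detections linked greedily by centroid
   proximity (closest pairs first, capped at 429 µm for *C. elegans* /
   300 µm for *S. carpocapsae*); centerline orientation made temporally
   consistent by endpoint proximity; tracks shorter than 10 s dropped.
5. **Features** — 17 per-worm-frame features (length, area, width,
   straightness, curvature summaries, centroid/end/body speeds, path
   direction change, movement–body-axis alignment, focus ("blur"),
   difference-image activity, intensity contrast and spread), each expanded
   with two first derivatives and five window statistics (mean, median,
   min, max, variance over a centered 1 s window) → 136 columns.
6. **Classification** — scikit-learn models (neural network default,
   min-max scaling) trained on manually scored ethograms; cross-validation
   folds split worm *tracks*, never frames.
7. **Denoising** — Gaussian smoothing of the class probabilities in time,
   short-bout removal, or Viterbi decoding of a bisymmetric two-state HMM
   (raw labels as noisy observations, or classifier probabilities as
   emissions), with a parameter optimizer minimizing
   |relerr NR| + |relerr IR| + |relerr SR| + (1 − accuracy).
8. **Metrics** — nictation ratio NR, initiation rate IR (starts per
   recumbent second), stopping rate SR (stops per nictating second),
   transition rate TR; scorer agreement and confidence margins; transition
   timing offsets; recording-duration sufficiency (relative variance of NR
   vs cutoff); snapshot-frame selection for cross-video comparisons.

Because raw assay recordings are rarely shareable, the package ships a
**synthetic-video generator** (`nictrack.synth`) that renders dark worms
undulating over a post grid with exact ground truth (label masks, 50-point
centerlines, two-state Markov ethograms). Nictation is rendered with the
cues the features detect: the body foreshortens, the elevated end defocuses,
and translation stops. Every stage of the pipeline is benchmarked against
this generator in the test suite.

## Worked example

```python
import numpy as np
from nictrack import synth, pipeline as pl, metrics as mx, segmentation as seg

# 1. synthesize a 60 s recording of four dauers on a micropost arena
arena = synth.ArenaSpec(frame_shape=(512, 512))   # 1.92 x 1.92 mm at 3.75 um/px
worms = synth.default_worms(4)
video, masks, truth, _ = synth.simulate_video(arena, worms, 60.0, fps=5.0, seed=42)

# 2. segment, extract centerlines, stitch tracks (intensity route)
config = pl.PipelineConfig(species="elegans", sigma_um=6.4, threshold=30)
bg = seg.max_merge_background(video)
diff = np.stack([seg.background_subtract(f, bg) for f in video])
tracks = pl.build_tracks(diff, config)
print(f"recovered {len(tracks)} worm tracks "
      f"({sum(t.n_frames for t in tracks)} worm-frames)")

# 3. nictation metrics of the generator's ground-truth ethogram
eth = {i: truth.ethogram[i] for i in range(truth.n_worms)}
m = mx.nictation_metrics(eth, fps=5.0)
print(f"NR = {m.nr:.3f}   IR = {m.ir:.3f} Hz   SR = {m.sr:.3f} Hz")
```

Output:

```
recovered 4 worm tracks (1200 worm-frames)
NR = 0.677   IR = 0.116 Hz   SR = 0.062 Hz
```

All four simulated worms are recovered as unbroken 300-frame tracks. The
nictation ratio is the fraction of scored time spent nictating; with only
four worms for one minute it scatters widely around the stationary value of
the generator's behavior chain, IR/(IR+SR) ≈ 0.44 — exactly the
sampling-noise effect the recording-duration analysis in
`nictrack.metrics` is designed to expose.

A command-line interface wraps the same stages
(`nictrack simulate | segment-eval | track | train | score | metrics`);
run `nictrack --help` for details.

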