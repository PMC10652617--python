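# Methods

## Pipeline overview

A cone-assay video is standardized to 540 × 960 px, 30 fps, single-channel
intensity, then sampled at 0.1-s intervals (every 3rd frame; nearest-frame
mapping for non-integer rates).  Timestamps are derived from frame index /
fps rather than container timestamps so that sampling is reproducible
across decoders.  Each sampled frame passes through: 3 × 3 median smoothing
→ per-pixel Gaussian-mixture background classification → morphological
opening (3 px) and closing (5 px) of the foreground mask → connected-component
area filtering → clipping to the calibrated cone ROI → a cap of five blobs
(the cone's occupancy).  Per-sample detections are aggregated into
thirty-five 5-s epochs starting at t = 5 s, stratified into the upper and
lower halves of the cone projection, and reduced to whole-assay metrics.

## Background model

The model is the standard adaptive per-pixel mixture of Gaussians over
intensity, K = 3 components per pixel, maintained in float32.  Matching
uses a squared-Mahalanobis gate of 9 (3σ); the matched component's mean and
variance follow exponential updates at learning rate α; unmatched
observations replace the lowest-weight component (weight α, variance 225).
Weights decay by (1 − α) and renormalize each frame.  The background set is
the heaviest components whose cumulative prior weight is below 0.9, and a
pixel is foreground when it lies outside 16 σ² (4σ) of every background
component.  Variances are clamped to [4, 1125] to keep the gate meaningful
on noise-free renders and bounded under heavy clutter.

The learning rate is α = 1/min(n, history) with history = 150 frames by
default: early frames acclimatise the model quickly (the first seen frame
seeds component 0 directly), after which adaptation settles at 1/150 per
sample.  Because the analysis samples at 10 Hz, history = 150 corresponds
to 15 s of scene memory.  The first 5 s of every assay is excluded from
epoch aggregation while the model acclimatises; the exclusion is part of
the epoch schedule, not of detection, so the detection log still has all
1800 rows.

Consequences worth knowing:

- Only *moving* mosquitoes are detected.  A mosquito that settles stays in
  the foreground until its appearance accumulates ~10% background weight
  (≈ 1.6 s at the defaults), and a vacated resting spot is briefly
  re-flagged ("ghost") on departure for the symmetric reason.  Resting
  estimates therefore lag the truth by a few samples per motion/rest
  transition; on the high-rest preset (all five mosquitoes settling once,
  simultaneously) the measured resting time is within ~0.5 s of ground
  truth.
- Two mosquitoes merging into one contour count as one mover (no split
  heuristics); this undercounts crowded scenes and is why preset scenes
  keep trajectories ≥ 3 blob diameters apart.
- The pipeline contains no randomness: identical file + configuration give
  byte-identical detection logs.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| history | 150 | frames | scene memory; absorption lag ≈ ratio-complement × history |
| variance_threshold (T_b) | 16 | σ² multiples | 4σ foreground gate, standard for this model family |
| match_threshold (T_g) | 9 | σ² multiples | 3σ component-update gate |
| background_ratio | 0.9 | weight | fraction of prior mass treated as background |
| open/close kernels | 3 / 5 | px | remove specks below mosquito scale, bridge soft edges |
| min_area / max_area | 20 / 2000 | px² | plausible mosquito sizes at 540 × 960 |
| max_movers | 5 | count | WHO cone occupancy |
| median_kernel | 3 | px | sensor-noise suppression before classification |

All are exposed in `SegmenterConfig` (YAML-serializable).  The blob-area
bounds and kernels assume the standard resolution; scale them together with
frame size (the test suite runs a 160 × 280 "small rig" with min_area = 10).

## Region geometry

The cone's projection is a per-rig calibration (polygon + horizontal split
line + frame size), not something detected per video: the rig fixes the
camera, so the calibration is made once per setup and saved as YAML.
Region assignment is by blob centroid: strictly above the split line is
"upper", on or below is "lower" — the tie goes to the net-facing half and
must be fixed for determinism.  Epoch windows are half-open [start, end) to
prevent double counting.  Membership tests use the rasterized polygon mask,
so `contains` and mask-based clipping can never disagree.

## Metrics definitions

- Activity is counted in mosquito-samples: each detected mover in each
  0.1-s sample contributes 1.  A fully active test is 5 × 1750 = 8750 over
  the epoch schedule.
- `total_activity` is the epoch-based total (t ∈ [5, 180) s);
  `total_activity_full` additionally includes the acclimatisation window
  and is emitted as an auxiliary column, since "the whole test" and "the
  epoch schedule" differ by construction.
- `prop_lower` = lower/total, emitted as missing (never 0) when total = 0
  to avoid biasing downstream models.
- Strict resting counts valid samples with zero movers, over the full
  record, first sample excluded (no predecessor).  `resting_seconds` =
  0.1 × resting_frames identically.
- `valid_frames_proportion` = decodable, model-ready samples / expected
  samples (1800 for a standard assay).  Samples that fail to decode carry
  zero blobs, are flagged invalid, and are excluded from activity and
  inactivity numerators and denominators alike.

## Synthetic scenes

The simulator renders dark anti-aliased discs (default 9 px diameter,
intensity 30, 2-px soft edge) on a bright background (intensity 200,
default drift +0.1 intensity/s) with optional i.i.d. Gaussian pixel noise
(default σ = 5, clipped to [0, 255]), at the standard format.  Trajectories
are piecewise-linear waypoint paths; a mosquito counts as "moving" at a
sample when its centroid displaced more than 1 px since the previous
sample, which is what a background-subtraction detector physically
responds to.  Preset paths are rectangular loops: the 90° corners keep
per-sample displacement above threshold (a straight reversal could
momentarily cancel it), and loop periods are long enough that no pixel
accumulates background weight from repeated visits.

What the simulator does *not* emulate: perspective and lens distortion,
cone-wall refraction and occlusion at the lip, shadows, reflections,
exposure changes, compression artefacts, and mosquitoes occluding each
other.  Passing ground-truth recovery on these scenes therefore validates
the algorithmic chain (sampling, modelling, morphology, region accounting),
not robustness to real-footage nuisances — those are what the configurable
thresholds are for.

Presets (all five mosquitoes, standard geometry): `crawler` (net-surface
loops, true prop_lower = 1.0), `dispersed` (continuous flight, 3 upper /
2 lower cells, prop_lower = 0.4), `high_rest` (loops until t = 55 s, then
still; > 90 s true resting), `mixed`.  On noise-free continuous-motion
presets the pipeline recovers per-sample counts and per-epoch regional
counts exactly; with σ = 5 noise the recovery is unchanged in our runs, and
rest-transition lag is the only systematic deviation (see above).

Synthetic life-history tables draw feeding (90% at 1 h, second offer at
24 h only for the unfed), haematin (N(12.5, 7.6²) µg/ml, fed only), wing
length (N(3.0, 0.2²) mm) and longevity (N(12, 4²) days, floored at 0) from
ranges typical of untreated-net assays.

## Numerical and I/O choices

- The mixture update and the 3 × 3 median (a 19-exchange sorting network,
  verified against `scipy.ndimage.median_filter`) are numba kernels;
  morphology uses separable `scipy.ndimage` min/max filters (equivalent to
  binary open/close with square elements).  A full assay analyses in about
  a minute on one core.
- The native container is multi-page TIFF via `tifffile` (lossless uint8,
  fps in the page description); H.264-in-MPEG-4 read/write (~1500 kb/s)
  activates when an `ffmpeg` executable is on PATH.  Assets are described
  by probed, not declared, properties.
- Standardization letterboxes aspect mismatches (scale-to-fit, centre-pad
  with black) rather than stretching, preserving the geometry calibration;
  integer-factor downscales use an exact box mean, everything else
  bilinear resampling.
- Blob ordering (by descending area, ties by image position) and the
  split-line tie rule exist purely so that equal inputs give equal logs.

## Problem sizes used in bundled checks

Unit and integration tests run 2–20-s scenes on a 160 × 280 scaled rig plus
a handful of full-length small-rig assays; the acceptance-style checks and
`scripts/acceptance.py` render full 180-s, 540 × 960 scenes (one noise-free,
two at σ = 5) and analyse them end to end.

## Known limitations

- No identity tracking, trajectories, re-identification, or knockdown
  classification; no statistical modelling of the merged table (that is
  downstream GLMM/Cox territory).
- Individual mosquitoes cannot be matched between the cone and their
  post-exposure tubes, so merged tables attach assay-level behaviour to
  each of the five individuals.
- Counts are biased low when mosquitoes overlap or hug the ROI boundary,
  and "resting" means "not displacing between 0.1-s samples", which cannot
  distinguish true rest from sub-pixel movement or hovering in place.
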