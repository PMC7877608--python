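# Methods

`hybridtrack` follows one unmarked insect through fixed-camera video by
switching between two detection channels, inferring why the insect
disappeared when it does, and assembling the accepted positions into a
single trajectory. This note documents the model, its parameters, the
numerical choices, what the synthetic scenes do and do not emulate, and the
known limitations.

## The tracking loop

The tracker is a predict-and-detect loop over one focal insect at a time.
A track is seeded by the appearance channel (the first confident detection
in the video), after which each frame proceeds:

1. **Prediction.** Constant velocity over three frames:
   `P_k = 2·D_{k−1} − D_{k−2}`, where `D` are the detected positions of the
   two preceding frames. After the very first detection, and after any gap,
   the prediction is the current position (no velocity information).
   During undetected frames the prediction is carried forward unchanged —
   extrapolating the last velocity indefinitely would drive the prediction
   off-frame during long occlusions.

2. **Mode selection.** The number of connected regions of inter-frame
   change (area ≥ `motion.region_change_floor`, default 2 px) with centroids
   within the appearance gate `MDT_DL` of the prediction decides the
   channel: 1–3 regions (configurable cap `max_regions_for_motion`) with a
   non-empty motion channel → background subtraction; 0 regions or more
   than the cap → the appearance detector. The cap trades speed against
   robustness: background subtraction is cheap but cannot tell the insect
   from wind-blown foliage when the neighbourhood is busy.

3. **Motion channel.** A per-pixel exponentially weighted mean/variance
   background model flags pixels deviating by more than `k·σ`
   (k = 3.5, σ floored at 5 intensity levels). Foreground pixels adapt at
   1/10 the background learning rate (α = 0.05 vs 0.005): this *selective
   update* keeps a moving or briefly resting insect from smearing itself
   into the background and leaving ghost foreground after it departs.
   During the first `warmup_frames` (default 30) masks are suppressed while
   the statistics settle. The raw mask is cleaned by a 5×5 median filter
   then a 3×3 binary erosion (kernel sizes are repository defaults; they
   are not dictated by the method), and 8-connected components with area ≥
   `motion.min_area` (default a quarter of the expected body area, so a
   partially occluded insect still qualifies) become candidate detections
   at their pixel-mean centroids. The background model is a pluggable
   contract; any implementation with the same `apply(frame) → mask`
   surface (e.g. a KNN kernel-density model) can be substituted.

4. **Association.** Detections are assigned to the prediction by minimum
   Euclidean distance (Hungarian assignment via
   `scipy.optimize.linear_sum_assignment`), rejecting any pairing beyond
   the channel's gate: `MDT_BS = max(d_int, d_max)` for motion detections
   (`d_int` = one body length; `d_max` = the largest recorded inter-frame
   displacement of this insect) and
   `MDT_DL = 2·(MDT_BS + η_level)`, `level = min(max(0, τ−τ̄)/100, 0.99)`,
   for appearance detections, where `η_q` is the empirical q-quantile of
   the insect's own speeds and τ the current run of undetected frames. The
   appearance gate widens one percentile per frame past τ̄, so a
   re-appearing insect can be re-acquired after travelling unseen; it is
   always at least twice the motion gate, reflecting the lower
   false-positive rate of the appearance channel. The speed history
   records displacements between *consecutive detected* positions only;
   carried-forward placeholders would contribute fake zeros.

5. **Disappearance inference.** At τ = τ̄ (default 15 frames, 250 ms at
   60 fps) the episode is classified:
   * **candidate exit** if the last detected position is within
     `edge_margin` (default one body length) of a frame boundary — the
     edge rule fires first because boundary clipping also shrinks the
     visible area, making the area trend uninformative there;
   * else **occluded** if the ordinary-least-squares slope of visible body
     area over the last `occlusion.window` (default 10) motion-channel
     measurements is strictly negative (m = 0 counts as unknown);
   * else **unknown**.
   The visible area is measured from the motion mask near the accepted
   position on every frame regardless of which channel detected the
   insect, so the trend window stays populated even in appearance mode.

6. **Exit confirmation.** For candidate exits the exit probability β is
   the share of the insect's empirical speed distribution fast enough to
   have covered the distance `d_e` from the disappearance point to the
   nearest boundary in the τ undetected frames: starting at quantile level
   i = 1.00 (continuing from the previous frame's level within an
   episode), the level drops in 0.01 steps while `τ·η_i > d_e`, floored at
   0, and `β = (1−i)·100 %`. β is monotone in τ and hits 100 % for a
   boundary disappearance. When β exceeds β̄ (default 85 %) the track is
   paused and the tracker searches for new insects. The quantile
   convention everywhere is the sorted sample with linear interpolation
   between order statistics (level 0 = minimum); the estimator holds the
   level in exact hundredths so no floating-point drift accumulates over
   long episodes. With an empty speed history β is undefined
   (estimation-unavailable); the tracker leaves the episode unclassified
   rather than guessing.

7. **Resume or terminate.** A paused or occluded track resumes under its
   original id if a detection appears within the resume radius — `MDT_DL`
   at the current τ, the same undetected-duration-aware radius used for
   gating — of the disappearance point before any new insect is adopted;
   otherwise the paused track is finalised as an exit and the new
   detection seeds a new track. Identity swaps during crossings are not
   detected; tracking one insect at a time is the design.

## Parameters

| key | default | meaning |
|---|---|---|
| `insect_area` | 1465 px | expected visible body area (honeybee at the reference scale) |
| `insect_length` | 42 px | expected body length; sets `gating.d_int` and `exit.edge_margin` |
| `max_regions_for_motion` | 3 | mode-switch cap on local change regions |
| `motion.min_area` | 0.25·area | minimum blob area |
| `motion.median_kernel` / `erosion_kernel` | 5 / 3 | mask denoising kernels |
| `motion.warmup_frames` | 30 | background settling period |
| `motion.region_change_floor` | 2 px | minimum area of a counted change region |
| `gating.tau_bar`, `exit.tau_bar` | 15 frames | undetected threshold triggering classification |
| `exit.beta_bar` | 85 % | exit-probability threshold pausing the track |
| `occlusion.window` | 10 | area measurements in the trend fit |
| `min_track_seconds` | 2 s | minimum duration for behavioural analysis |

Spatial calibration (pixels/mm, fps) is user input, never inferred from
pixels.

## Trajectory analytics

Speeds are finite differences between consecutive detected points
(displacement / frame gap × fps / pixels-per-mm); turn angles are signed
heading changes between successive displacement vectors, positive
counter-clockwise *on screen* (image y points down, so this is the negated
standard cross-product angle; a reversal is +180°). Heat-maps tile the
frame with square bins whose area defaults to the insect's body area; bin
counts sum exactly to the number of binned positions. The visibility
partition assigns every frame of a track's span to visible (detected),
occluded (undetected inside an episode classified occluded) or
un-estimated (episodes classified unknown or candidate-exit); undetected
gaps shorter than τ̄ were never classified and count as visible, keeping
the partition exhaustive.

## The synthetic scenes

Scenes place a correlated random walk (von Mises heading perturbations,
gamma step lengths) on a static smooth-textured background, rendered as a
filled ellipse whose area tracks the scripted visible area. Occlusion
events freeze the insect (crawling under a leaf) and ramp its visible area
linearly to zero over the ramp frames — exactly the negative-trend signal
the classifier tests for — then restore it. Exit events steer the heading
straight at a stated boundary until the insect crosses and keeps going.
Distractors are bright ellipses swaying sinusoidally (wind) with optional
flicker. Everything is bit-deterministic per seed.

Scales used in the tests and the acceptance script: 320×240 frames,
300 px insect (≈ a 1/6 linear downscale of the reference recording
geometry), 3 px/frame mean speed, 450–600-frame scenes. These sizes keep a
full run of the suite fast while leaving every ratio (body area : frame
area, speed : body length) in the regime the method targets.

What the simulator does **not** emulate: sensor noise, illumination
change, shadows, perspective, appearance variation, occluders that move,
multiple simultaneous insects (a splice fixture covers the sequential-track
case). Passing these tests therefore demonstrates the algorithmic
machinery — mode switching, gating, event inference, lifecycle — not
robustness to raw field video; the appearance channel in particular is an
oracle stand-in for a trained detector and says nothing about any real
network's accuracy.

## Numerical and degenerate-input choices

* Empirical quantiles: linear interpolation between order statistics,
  everywhere.
* Assignment ties broken toward the lower detection index (an epsilon of
  1e−9·index on the cost, far below any meaningful distance).
* A blob exactly at `min_area` is kept (≥, not >).
* An area-trend window with all frames identical raises a degenerate-fit
  error; fewer than two area measurements classify as unknown.
* `β` level floors at 0.00; the guard `d_t ≤ d_e` leaves the state (and
  the previous β, initially 0) unchanged.
* Terminal track states are absorbing; violating transitions raise.
* Grayscale conversion uses fixed BT.601 weights; channel-equal inputs are
  invariant to this choice.

## Known limitations

* The motion channel assumes a fixed camera and mostly static background;
  sustained global motion forces the (slower) appearance channel.
* A long-resting insect is slowly absorbed by the background model even
  with selective update; the appearance channel covers this.
* Occlusion classification needs the area ramp to be sampled: a
  disappearance faster than ~2 frames gives the trend fit little to work
  with and tends to classify unknown.
* One insect at a time; simultaneous multi-insect scenes require re-runs
  with different initialisations, and crossing identities are not
  disambiguated.
* Reading MP4/AVI containers requires an ffmpeg-backed imageio plugin;
  PNG sequences and in-memory arrays are always supported.
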