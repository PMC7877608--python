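# hybridtrack

Hybrid motion/appearance detection and tracking of a single unmarked
insect — a foraging honeybee, say — through fixed-camera outdoor video,
where wind-blown vegetation defeats plain background subtraction and
frame-by-frame neural detection is too slow and too gappy on its own.

It is written for behavioural ecologists and pollination researchers who
need full trajectories (positions, speeds, turn angles, time budgets) of
individual insects from tripod video of flower patches, including through
the moments when the insect crawls under foliage or leaves the frame.

## The method

Tracking-by-detection with two switched channels and adaptive gates:

* **Prediction** — constant velocity over three frames,
  `P_k = 2·D_{k−1} − D_{k−2}`.
* **Mode switch** — count the connected regions of inter-frame change near
  the prediction: 1–3 regions → background subtraction (per-pixel
  running-statistics model → median filter → erosion → area-filtered blob
  centroid); 0 or > 3 regions → the appearance detector (any trained
  object detector, plugged in as a per-frame detection stream).
* **Association** — Hungarian minimum-distance assignment, gated by
  `MDT_BS = max(d_int, d_max)` for the motion channel and
  `MDT_DL = 2·(MDT_BS + η_{min(max(0, τ−τ̄)/100, 0.99)})` for the
  appearance channel, where `d_int` is one body length, `d_max` the
  insect's largest recorded inter-frame displacement, `η_q` the empirical
  q-quantile of its speeds and τ the run of undetected frames.
* **Occlusion vs exit** — after τ̄ undetected frames, a negative
  least-squares trend `m` of visible body area signals an occlusion, unless
  the insect vanished within a body length of a frame edge, in which case
  the exit probability `β = (1−i)·100 %` is scanned down the speed
  quantiles until `τ·η_i ≤ d_e`; `β > β̄` (85 %) pauses the track.
* **Resume / terminate** — a detection near the disappearance point resumes
  the same track; otherwise the paused track is stored as an exit and a new
  track begins.

A ground-truthed scene simulator (correlated random walk, scripted
area-ramp occlusions, scripted boundary exits, wind-blown distractors)
makes every stage verifiable without field video, and a scoring harness
reports detection rates and event recall against the simulated truth.

## Worked example

Simulate a scene with a scripted under-foliage occlusion, track it, and
summarise the trajectory:

```python
import hybridtrack as ht

scene = ht.SceneConfig(width=320, height=240, n_frames=450, body_area=300,
                       body_length=26, speed_mean=3.0, seed=7,
                       occlusions=[ht.OcclusionEvent(start=180, ramp=10, duration=60)],
                       interior_margin=40.0)
truth = ht.simulate_trajectory(scene)
frames = ht.render_frames(truth, scene)
detector = ht.OracleDetector(truth, miss_rate=0.1, position_sigma=2.0, seed=7)

cfg = ht.TrackerConfig.for_insect(insect_area=300, insect_length=26)
tracks = ht.track_video(ht.ArraySource(frames, fps=60.0), detector, cfg)

track = tracks[0]
util = track.mode_utilization()
print(f"tracks: {len(tracks)}; state: {track.state}; points: {len(track.points)}")
print(f"mode utilisation: motion {util['motion']:.1%}, appearance {util['appearance']:.1%}")
for ev in track.events:
    print(f"frame {ev.frame}: {ev.event} ({ev.detail})")

cal = ht.Calibration(pixels_per_mm=0.53, fps=60.0)
vis, occ, unest = ht.visibility_partition(track, cal.fps)
print(f"visible {vis:.2f} s, occluded {occ:.2f} s, un-estimated {unest:.2f} s")
scores = ht.score_against_truth(tracks, truth)
print(f"detection rate vs ground truth: {scores.detection_rate:.1%}")
```

prints

```
tracks: 1; state: terminated_end_of_video; points: 450
mode utilisation: motion 91.4%, appearance 8.6%
frame 203: occluded (m=-23.764)
frame 240: resumed ()
visible 6.65 s, occluded 0.85 s, un-estimated 0.00 s
detection rate vs ground truth: 100.0%
```

The insect is followed through all 450 frames, 91 % of them by the cheap
motion channel despite the 10 % detector miss rate. The scripted occlusion
(frames 180–240) is recognised at frame 203 — 15 frames after the last
detection, from the negative area trend m — the position is carried
forward, and the track resumes on re-emergence; the time budget charges
0.85 s to "occluded".

The same pipeline is available from the shell:

```sh
hybridtrack simulate --out scene/ --seed 7
hybridtrack track --video frames_dir/ --detections scene/detections.csv --out run/
hybridtrack analyze --tracks run/ --out analysis/ --pixels-per-mm 0.53
```

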