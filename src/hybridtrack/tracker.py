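"""The hybrid detection-and-tracking loop.

One focal insect is followed at a time, from its first appearance to its
exit.  Each frame the tracker:

1. predicts the insect's position by the constant-velocity model;
2. counts the regions of inter-frame change within the appearance gate of
   the prediction;
3. selects the detection mode — the cheap motion channel when the local
   change is sparse (1 to ``max_regions_for_motion`` regions), the
   appearance channel when the neighbourhood is too busy or the motion
   channel sees nothing;
4. associates the chosen channel's detections to the prediction within that
   channel's gate (MDT_BS or MDT_DL);
5. on success appends a track point, updates the speed history and resets
   the undetected counter τ; on failure carries the prediction forward;
6. at τ = τ̄ classifies the disappearance (occluded / candidate exit /
   unknown) and, for candidate exits, updates the exit probability β each
   frame until β exceeds β̄ and the track is paused.

A paused track is resumed if the insect is re-detected near its
disappearance point before any new insect appears; otherwise it is
finalised as an exit and the new detection seeds a new track.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .appearance import AppearanceDetector, Detection
from .association import (
    GatingState,
    PredictedPosition,
    associate,
    mdt_bs,
    mdt_dl,
    predict_position,
)
from .config import TrackerConfig
from .events import (
    EstimationUnavailableError,
    ExitEstimatorState,
    classify_disappearance,
    distance_to_edge,
    exit_probability,
    fit_area_trend,
)
from .foreground import (
    ForegroundMask,
    RunningStatsBackground,
    count_change_regions,
    denoise_mask,
    extract_blobs,
)
from .video_io import FrameSource, open_source, to_grayscale

__all__ = [
    "TrackPoint",
    "TrackEvent",
    "Track",
    "HybridTracker",
    "select_mode",
    "initialize_track",
    "handle_reappearance",
    "track_video",
    "write_tracks",
    "read_tracks",
]

TERMINAL_STATES = {"terminated_exit", "terminated_end_of_video"}
STATES = {
    "tracking",
    "undetected",
    "occluded",
    "paused_candidate_exit",
} | TERMINAL_STATES


@dataclass
class TrackPoint:
    frame_index: int
    x: float
    y: float
    #: {"motion", "appearance", "carried_forward"}
    source: str
    visible_area: float | None = None
    gate_used: float | None = None


@dataclass
class TrackEvent:
    frame: int
    event: str  # {occluded, candidate_exit, unknown, exited, resumed}
    detail: str = ""


@dataclass
class Track:
    """The focal insect's trajectory plus its lifecycle state."""

    id: int
    gating: GatingState
    points: list[TrackPoint] = field(default_factory=list)
    events: list[TrackEvent] = field(default_factory=list)
    state: str = "tracking"
    exit_state: ExitEstimatorState | None = None
    disappearance_position: tuple[float, float] | None = None
    disappearance_frame: int | None = None
    # --- running internals -------------------------------------------------
    #: prediction for the *next* frame to process
    prediction: tuple[float, float] | None = None
    last_detected: tuple[float, float] | None = None
    last_detected_frame: int = -1
    #: recent (frame, motion-measured area) pairs feeding the area trend
    area_window: list[tuple[int, float]] = field(default_factory=list)
    _exit_candidate: bool = False

    def set_state(self, new: str) -> None:
        if new not in STATES:
            raise ValueError(f"unknown state {new!r}")
        if self.state in TERMINAL_STATES and new != self.state:
            raise ValueError(f"terminal state {self.state} is absorbing")
        self.state = new

    # --- summaries ---------------------------------------------------------
    @property
    def detected_points(self) -> list[TrackPoint]:
        return [p for p in self.points if p.source != "carried_forward"]

    @property
    def frame_span(self) -> tuple[int, int]:
        return (self.points[0].frame_index, self.points[-1].frame_index)

    def duration_seconds(self, fps: float) -> float:
        if not self.points:
            return 0.0
        a, b = self.frame_span
        return (b - a + 1) / fps

    def mode_utilization(self) -> dict[str, float]:
        """Fraction of detected points from each channel (the per-track
        'detection method utilisation')."""
        det = self.detected_points
        if not det:
            return {"motion": 0.0, "appearance": 0.0}
        n = len(det)
        n_motion = sum(1 for p in det if p.source == "motion")
        return {"motion": n_motion / n, "appearance": (n - n_motion) / n}


def select_mode(n_regions: int, motion_found: bool, cfg: TrackerConfig) -> str:
    """Choose the detection channel from the local change count.

    Motion when 1 ≤ n_regions ≤ max_regions_for_motion and the motion channel
    produced candidates; appearance when the neighbourhood is too busy
    (n_regions above the cap) or the motion channel is empty.
    """
    if 1 <= n_regions <= cfg.max_regions_for_motion and motion_found:
        return "motion"
    return "appearance"


class HybridTracker:
    """Per-frame stepping of one focal track over a fixed-geometry video."""

    def __init__(self, cfg: TrackerConfig, frame_size: tuple[int, int]):
        self.cfg = cfg
        self.frame_size = frame_size  # (width, height)
        self._next_id = 0

    # ------------------------------------------------------------------ init
    def new_track(self, detection: Detection) -> Track:
        """Seed a track from an appearance-channel detection."""
        track = Track(
            id=self._next_id,
            gating=GatingState(
                d_int=self.cfg.gating.d_int, tau_bar=self.cfg.gating.tau_bar
            ),
        )
        self._next_id += 1
        x, y = detection.centroid
        track.points.append(
            TrackPoint(
                frame_index=detection.frame_index,
                x=x,
                y=y,
                source="appearance",
                visible_area=detection.area,
            )
        )
        track.prediction = (x, y)  # first frame: prediction = current position
        track.last_detected = (x, y)
        track.last_detected_frame = detection.frame_index
        return track

    # ------------------------------------------------------------------ step
    def step(
        self,
        track: Track,
        frame_index: int,
        frame: np.ndarray,
        clean_mask: ForegroundMask,
        detector: AppearanceDetector,
    ) -> None:
        """Advance a non-terminal, non-paused track by one frame."""
        if track.state in TERMINAL_STATES or track.state == "paused_candidate_exit":
            raise ValueError(f"cannot step a track in state {track.state}")
        cfg = self.cfg
        gate_bs = mdt_bs(track.gating)
        gate_dl = mdt_dl(track.gating)
        pred = track.prediction
        n_regions = count_change_regions(clean_mask, pred, gate_dl, cfg.motion)
        blobs = extract_blobs(clean_mask, cfg.motion.min_area)
        mode = select_mode(n_regions, bool(blobs), cfg)
        if mode == "motion":
            dets = [
                Detection(
                    frame_index=frame_index,
                    centroid=b.centroid,
                    bbox=tuple(float(v) for v in b.bbox),
                    area=float(b.area),
                    source="motion",
                )
                for b in blobs
            ]
            gate = gate_bs
        else:
            dets = detector.detect(frame, frame_index)
            gate = gate_dl
        match = associate(
            [PredictedPosition(pred[0], pred[1], frame_index)], dets, gate
        )[0]
        if match is not None:
            self._accept(track, frame_index, dets[match], gate, clean_mask)
        else:
            self._miss(track, frame_index)

    # -------------------------------------------------------------- internal
    def _measure_area(
        self, clean_mask: ForegroundMask, position: tuple[float, float]
    ) -> float | None:
        """Visible body area from the motion channel: area of the changed
        component nearest the accepted position, within one body length.
        Measured regardless of which channel produced the detection, so the
        area-trend window stays populated."""
        blobs = extract_blobs(clean_mask, self.cfg.motion.region_change_floor)
        best = None
        best_d2 = self.cfg.insect_length**2
        for b in blobs:
            d2 = (b.centroid[0] - position[0]) ** 2 + (b.centroid[1] - position[1]) ** 2
            if d2 <= best_d2:
                best, best_d2 = b, d2
        return float(best.area) if best is not None else None

    def _accept(
        self,
        track: Track,
        frame_index: int,
        det: Detection,
        gate: float,
        clean_mask: ForegroundMask,
    ) -> None:
        g = track.gating
        was_lost = g.tau >= g.tau_bar
        pos = det.centroid
        consecutive = track.last_detected_frame == frame_index - 1
        if consecutive and track.last_detected is not None:
            g.record_speed(math.dist(pos, track.last_detected))
        area = det.area
        if area is None:
            area = self._measure_area(clean_mask, pos)
        if area is not None:
            track.area_window.append((frame_index, area))
            del track.area_window[: -self.cfg.occlusion.window]
        track.points.append(
            TrackPoint(
                frame_index=frame_index,
                x=pos[0],
                y=pos[1],
                source=det.source,
                visible_area=area,
                gate_used=gate,
            )
        )
        if consecutive and track.last_detected is not None:
            track.prediction = predict_position(
                pos, track.last_detected, frame_index + 1
            ).xy
        else:
            track.prediction = pos
        track.last_detected = pos
        track.last_detected_frame = frame_index
        g.tau = 0
        if was_lost:
            track.events.append(TrackEvent(frame_index, "resumed"))
        track.set_state("tracking")
        track._exit_candidate = False
        track.exit_state = None
        track.disappearance_position = None
        track.disappearance_frame = None

    def _miss(self, track: Track, frame_index: int) -> None:
        cfg = self.cfg
        g = track.gating
        g.tau += 1
        px, py = track.prediction
        track.points.append(
            TrackPoint(frame_index=frame_index, x=px, y=py, source="carried_forward")
        )
        if track.state == "tracking":
            track.set_state("undetected")
        if g.tau == g.tau_bar:
            self._classify(track, frame_index)
        if track._exit_candidate and g.tau >= g.tau_bar:
            self._update_exit(track, frame_index)

    def _classify(self, track: Track, frame_index: int) -> None:
        cfg = self.cfg
        track.disappearance_position = track.last_detected
        track.disappearance_frame = track.last_detected_frame
        fit = None
        frames = {f for f, _ in track.area_window}
        if len(track.area_window) >= 2 and len(frames) >= 2:
            fit = fit_area_trend(track.area_window)
        label = classify_disappearance(
            fit, track.last_detected, self.frame_size, cfg.edge_margin
        )
        detail = f"m={fit.m:.3f}" if fit is not None else "no area trend"
        track.events.append(TrackEvent(frame_index, label, detail))
        if label == "occluded":
            track.set_state("occluded")
        elif label == "candidate_exit":
            track._exit_candidate = True
            track.exit_state = ExitEstimatorState(
                tau=track.gating.tau,
                tau_bar=cfg.exit.tau_bar,
                beta_bar=cfg.exit.beta_bar,
                d_e=distance_to_edge(track.last_detected, self.frame_size),
            )

    def _update_exit(self, track: Track, frame_index: int) -> None:
        cfg = self.cfg
        state = replace(track.exit_state, tau=track.gating.tau)
        try:
            track.exit_state = exit_probability(state, track.gating.speed_history)
        except EstimationUnavailableError:
            return  # no speed history yet: cannot confirm the exit
        if track.exit_state.beta > cfg.exit.beta_bar:
            track.set_state("paused_candidate_exit")
            track.events.append(
                TrackEvent(frame_index, "exited", f"beta={track.exit_state.beta:.1f}")
            )


def initialize_track(
    source: FrameSource,
    detector: AppearanceDetector,
    cfg: TrackerConfig,
    start_frame: int = 0,
) -> Track:
    """Scan for the insect's first appearance using the appearance channel.

    The first frame (at or after ``start_frame``) with an appearance
    detection seeds a track in state ``tracking``; simultaneous detections
    are broken toward the highest confidence.  If no detection occurs the
    returned track has zero points and state ``terminated_end_of_video``.
    """
    tracker = HybridTracker(cfg, (source.width, source.height))
    for k, frame in enumerate(source):
        if k < start_frame:
            continue
        dets = detector.detect(frame, k)
        if dets:
            best = max(dets, key=lambda d: d.confidence)
            return tracker.new_track(best)
    empty = Track(id=-1, gating=GatingState(d_int=cfg.gating.d_int))
    empty.state = "terminated_end_of_video"
    return empty


def handle_reappearance(
    track: Track,
    detection: Detection,
    cfg: TrackerConfig,
    tracker: HybridTracker | None = None,
) -> Track:
    """Resolve a detection while the track is occluded or paused.

    Within the resume radius (the appearance gate MDT_DL at the current τ,
    which widens with undetected time) of the disappearance point the track
    resumes under the same id; beyond it the paused track is finalised as an
    exit and the detection seeds a fresh track.
    """
    if track.state not in {"occluded", "paused_candidate_exit"}:
        raise ValueError("handle_reappearance expects an occluded or paused track")
    if tracker is None:
        tracker = HybridTracker(cfg, (10**9, 10**9))
    radius = mdt_dl(track.gating)
    dist = math.dist(detection.centroid, track.disappearance_position)
    if dist <= radius:
        x, y = detection.centroid
        track.set_state("tracking")
        track.points.append(
            TrackPoint(
                frame_index=detection.frame_index,
                x=x,
                y=y,
                source=detection.source,
                visible_area=detection.area,
            )
        )
        track.events.append(TrackEvent(detection.frame_index, "resumed"))
        track.prediction = (x, y)
        track.last_detected = (x, y)
        track.last_detected_frame = detection.frame_index
        track.gating.tau = 0
        track._exit_candidate = False
        track.exit_state = None
        return track
    if track.state == "paused_candidate_exit":
        track.set_state("terminated_exit")
    return tracker.new_track(detection)


def track_video(
    source,
    detector: AppearanceDetector,
    cfg: TrackerConfig,
    background_model: RunningStatsBackground | None = None,
) -> list[Track]:
    """Run the full loop over a video; returns all finalised tracks.

    Tracks are produced sequentially: a new one starts only after the
    previous is paused or terminated.  Each returned track carries its event
    log; ``analysis_ok`` marks tracks meeting the minimum duration for
    behavioural analysis.
    """
    src = open_source(source)
    model = background_model or RunningStatsBackground(
        warmup_frames=cfg.motion.warmup_frames
    )
    tracker = HybridTracker(cfg, (src.width, src.height))
    tracks: list[Track] = []
    current: Track | None = None

    for k, frame in enumerate(src):
        gray = to_grayscale(frame)
        raw = model.apply(gray)
        clean = denoise_mask(raw, cfg.motion)

        if current is None:
            dets = detector.detect(frame, k)
            if dets:
                current = tracker.new_track(max(dets, key=lambda d: d.confidence))
        elif current.state == "paused_candidate_exit":
            current.gating.tau += 1
            dets = detector.detect(frame, k)
            if dets:
                nearest = min(
                    dets,
                    key=lambda d: math.dist(d.centroid, current.disappearance_position),
                )
                result = handle_reappearance(current, nearest, cfg, tracker)
                if result is not current:  # old track terminated, new one seeded
                    tracks.append(current)
                    current = result
        else:
            tracker.step(current, k, frame, clean, detector)

    if current is not None:
        if current.state == "paused_candidate_exit":
            current.set_state("terminated_exit")
        elif current.state not in TERMINAL_STATES:
            current.set_state("terminated_end_of_video")
        tracks.append(current)

    for tr in tracks:
        tr.analysis_ok = (
            bool(tr.points) and tr.duration_seconds(src.fps) > cfg.min_track_seconds
        )
    return tracks


# ---------------------------------------------------------------------------
# persistence: CSV track/event logs + JSON run summary


def write_tracks(tracks: list[Track], out_dir: str | Path, fps: float = 60.0) -> None:
    """Write ``tracks.csv`` (one row per frame per track), ``events.csv`` and
    ``summary.json`` (per-track mode utilisation and durations)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = ["track_id,frame,x,y,source,state,visible_area"]
    for tr in tracks:
        for p in tr.points:
            area = "" if p.visible_area is None else f"{p.visible_area:.2f}"
            rows.append(
                f"{tr.id},{p.frame_index},{p.x:.4f},{p.y:.4f},{p.source},{tr.state},{area}"
            )
    (out / "tracks.csv").write_text("\n".join(rows) + "\n")
    ev_rows = ["track_id,frame,event,detail"]
    for tr in tracks:
        for ev in tr.events:
            ev_rows.append(f"{tr.id},{ev.frame},{ev.event},{ev.detail}")
    (out / "events.csv").write_text("\n".join(ev_rows) + "\n")
    summary = {
        "tracks": [
            {
                "id": tr.id,
                "state": tr.state,
                "n_points": len(tr.points),
                "duration_seconds": tr.duration_seconds(fps) if tr.points else 0.0,
                "mode_utilization": tr.mode_utilization(),
            }
            for tr in tracks
        ]
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")


def read_tracks(out_dir: str | Path) -> list[Track]:
    """Re-load tracks written by :func:`write_tracks` (points, events and
    final state; running internals are not restored)."""
    out = Path(out_dir)
    by_id: dict[int, Track] = {}
    lines = (out / "tracks.csv").read_text().splitlines()[1:]
    for line in lines:
        tid, frame, x, y, source, state, area = line.split(",")
        tr = by_id.setdefault(
            int(tid), Track(id=int(tid), gating=GatingState(d_int=1.0), state=state)
        )
        tr.state = state
        tr.points.append(
            TrackPoint(
                frame_index=int(frame),
                x=float(x),
                y=float(y),
                source=source,
                visible_area=float(area) if area else None,
            )
        )
    ev_path = out / "events.csv"
    if ev_path.exists():
        for line in ev_path.read_text().splitlines()[1:]:
            tid, frame, event, detail = line.split(",", 3)
            if int(tid) in by_id:
                by_id[int(tid)].events.append(TrackEvent(int(frame), event, detail))
    return [by_id[k] for k in sorted(by_id)]
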