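"""Ground-truthed synthetic scenes for exercising every tracker stage.

A scene emulates the field conditions the tracker is built for: a single
insect moving over a static textured background by a correlated random walk,
optional wind-blown distractor ellipses, scripted under-foliage occlusions
(the visible body area ramps linearly to zero, the signal the occlusion
classifier keys on), and a scripted field-of-view exit driven across a stated
boundary.  The simulator emits, fully deterministically per seed:

* a ground-truth log (per-frame position, visible area, visibility flag),
* rendered grayscale frames,
* a detection stream in the CSV interchange format (via the oracle
  detector, with configurable miss/noise/false-positive corruption),
* a scoring harness comparing tracker output against the truth.

What it deliberately does not emulate: photometric noise, illumination
drift, 3-D plant structure, insect appearance variation.  Passing tests on
these scenes therefore validates the algorithmic pipeline, not robustness to
real-world imaging conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import ellipse as draw_ellipse

from .appearance import OracleDetector

__all__ = [
    "OcclusionEvent",
    "ExitEvent",
    "DistractorConfig",
    "SceneConfig",
    "GroundTruth",
    "Scores",
    "simulate_trajectory",
    "render_frames",
    "emit_detection_stream",
    "score_against_truth",
]


@dataclass
class OcclusionEvent:
    """Scripted under-foliage occlusion: the insect halts at its current
    position, its visible area ramps linearly to zero over ``ramp`` frames,
    stays zero, and is restored when the event ends after ``duration``
    frames."""

    start: int
    ramp: int = 10
    duration: int = 60


@dataclass
class ExitEvent:
    """Scripted field-of-view exit: from ``frame`` onward the heading is
    steered straight at the stated boundary until the insect crosses it."""

    frame: int
    side: str = "right"  # {"left", "right", "top", "bottom"}


@dataclass
class DistractorConfig:
    """Wind-blown clutter: ellipses oscillating sinusoidally about fixed
    anchors, optionally flickering in and out of view."""

    count: int = 0
    size_range: tuple[float, float] = (3.0, 9.0)
    amplitude: float = 4.0
    period: float = 40.0  # frames per oscillation
    flicker_rate: float = 0.0  # per-frame probability of being hidden


@dataclass
class SceneConfig:
    """Scene parameters.  Defaults mirror the honeybee recording regime the
    tracker targets (1920×1080 at 60 fps, body area 1465 px); tests use
    smaller geometries for speed, which simply scales the scene down."""

    width: int = 1920
    height: int = 1080
    fps: float = 60.0
    n_frames: int = 600
    body_area: float = 1465.0
    body_length: float = 42.0
    #: per-frame step length distribution: gamma with this mean (px/frame)...
    speed_mean: float = 4.0
    #: ...and shape parameter (larger = less variable); "constant" family
    #: available by setting speed_family
    speed_shape: float = 4.0
    speed_family: str = "gamma"  # {"gamma", "constant"}
    #: von Mises concentration of per-frame heading changes
    turning_kappa: float = 8.0
    occlusions: list[OcclusionEvent] = field(default_factory=list)
    exit: ExitEvent | None = None
    distractors: DistractorConfig = field(default_factory=DistractorConfig)
    seed: int = 0
    #: extra inset (px) from the frame border inside which the walk reflects;
    #: use > 0 to keep non-exit scenes away from the edge rule
    interior_margin: float = 0.0
    start_position: tuple[float, float] | None = None
    # rendering intensities (uint8)
    background_range: tuple[int, int] = (90, 170)
    insect_intensity: int = 25
    distractor_intensity: int = 215

    def validate(self) -> None:
        for ev in self.occlusions:
            if ev.start < 0 or ev.start + ev.duration > self.n_frames:
                raise ValueError("occlusion event outside scene duration")
            if ev.ramp < 1 or ev.ramp > ev.duration:
                raise ValueError("occlusion ramp must be in [1, duration]")
            if self.exit is not None and ev.start + ev.duration > self.exit.frame:
                raise ValueError("occlusion overlaps scripted exit")
        if self.exit is not None and not 0 <= self.exit.frame < self.n_frames:
            raise ValueError("exit frame outside scene duration")
        if self.body_area <= 0 or self.body_length <= 0:
            raise ValueError("insect dimensions must be positive")


@dataclass
class GroundTruth:
    """Per-frame truth of a simulated scene plus its event log."""

    width: int
    height: int
    fps: float
    body_area: float
    body_length: float
    positions: np.ndarray  # (n, 2) float, (x, y)
    areas: np.ndarray  # (n,) visible body area, 0 when occluded/exited
    visible: np.ndarray  # (n,) bool
    headings: np.ndarray  # (n,) radians
    occlusions: list[OcclusionEvent] = field(default_factory=list)
    exit_frame: int | None = None  # first frame with the centre out of frame
    exit_side: str | None = None

    @property
    def n_frames(self) -> int:
        return len(self.positions)

    def write_csv(self, path: str | Path) -> None:
        lines = ["frame,x,y,visible,area"]
        for k in range(self.n_frames):
            x, y = self.positions[k]
            lines.append(
                f"{k},{x:.4f},{y:.4f},{int(self.visible[k])},{self.areas[k]:.2f}"
            )
        Path(path).write_text("\n".join(lines) + "\n")

    def write_events_csv(self, path: str | Path) -> None:
        lines = ["frame,event,detail"]
        for ev in self.occlusions:
            lines.append(f"{ev.start},occlusion_start,ramp={ev.ramp}")
            lines.append(f"{ev.start + ev.duration},occlusion_end,")
        if self.exit_frame is not None:
            lines.append(f"{self.exit_frame},exit,side={self.exit_side}")
        Path(path).write_text("\n".join(lines) + "\n")


def _draw_speed(rng: np.random.Generator, cfg: SceneConfig) -> float:
    if cfg.speed_family == "constant":
        return cfg.speed_mean
    if cfg.speed_family == "gamma":
        if cfg.speed_mean == 0:
            return 0.0
        return float(rng.gamma(cfg.speed_shape, cfg.speed_mean / cfg.speed_shape))
    raise ValueError(f"unknown speed family {cfg.speed_family!r}")


def simulate_trajectory(cfg: SceneConfig) -> GroundTruth:
    """Correlated random walk with scripted occlusion and exit events.

    The heading evolves by von Mises perturbations (concentration
    ``turning_kappa``); step lengths are drawn per frame from the configured
    speed family.  The walk reflects off the frame boundary (inset by
    ``interior_margin`` plus half a body length) except during a scripted
    exit, when the heading is steered perpendicular at the stated boundary
    until the insect crosses it and keeps going.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_frames
    half = cfg.body_length / 2.0
    lo_x, hi_x = cfg.interior_margin + half, cfg.width - 1 - cfg.interior_margin - half
    lo_y, hi_y = cfg.interior_margin + half, cfg.height - 1 - cfg.interior_margin - half

    if cfg.start_position is not None:
        x, y = cfg.start_position
    else:
        x = cfg.width / 2.0 + rng.uniform(-cfg.width / 8, cfg.width / 8)
        y = cfg.height / 2.0 + rng.uniform(-cfg.height / 8, cfg.height / 8)
    heading = rng.uniform(0, 2 * math.pi)

    positions = np.zeros((n, 2))
    areas = np.zeros(n)
    visible = np.zeros(n, dtype=bool)
    headings = np.zeros(n)
    exit_frame: int | None = None
    exited = False

    occ_by_frame: dict[int, float] = {}
    for ev in cfg.occlusions:
        for t in range(ev.duration):
            k = ev.start + t
            frac = max(0.0, 1.0 - (t + 1) / ev.ramp) if t < ev.ramp else 0.0
            occ_by_frame[k] = frac

    for k in range(n):
        positions[k] = (x, y)
        headings[k] = heading
        inside = 0 <= x <= cfg.width - 1 and 0 <= y <= cfg.height - 1
        if exited or not inside:
            if exit_frame is None and not inside:
                exit_frame = k
                exited = True
            areas[k] = 0.0
            visible[k] = False
        elif k in occ_by_frame:
            areas[k] = cfg.body_area * occ_by_frame[k]
            visible[k] = areas[k] > 0
        else:
            areas[k] = cfg.body_area
            visible[k] = True

        # advance to next frame
        if k in occ_by_frame:
            continue  # halted under foliage
        steering_exit = cfg.exit is not None and k >= cfg.exit.frame and not exited
        if steering_exit or exited:
            # drive (and then keep) the heading straight at/past the boundary
            if cfg.exit is not None:
                heading = {
                    "right": 0.0,
                    "left": math.pi,
                    "bottom": math.pi / 2,
                    "top": -math.pi / 2,
                }[cfg.exit.side]
        else:
            heading += float(rng.vonmises(0.0, cfg.turning_kappa))
        step = _draw_speed(rng, cfg)
        x += step * math.cos(heading)
        y += step * math.sin(heading)
        if exited:
            continue  # keep drifting outward, no reflection
        if not steering_exit:
            if x < lo_x:
                x = 2 * lo_x - x
                heading = math.pi - heading
            elif x > hi_x:
                x = 2 * hi_x - x
                heading = math.pi - heading
            if y < lo_y:
                y = 2 * lo_y - y
                heading = -heading
            elif y > hi_y:
                y = 2 * hi_y - y
                heading = -heading

    return GroundTruth(
        width=cfg.width,
        height=cfg.height,
        fps=cfg.fps,
        body_area=cfg.body_area,
        body_length=cfg.body_length,
        positions=positions,
        areas=areas,
        visible=visible,
        headings=headings,
        occlusions=list(cfg.occlusions),
        exit_frame=exit_frame,
        exit_side=cfg.exit.side if cfg.exit is not None else None,
    )


def _make_background(cfg: SceneConfig) -> np.ndarray:
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    noise = rng.random((cfg.height, cfg.width))
    smooth = ndi.gaussian_filter(noise, sigma=4.0)
    lo, hi = cfg.background_range
    smooth -= smooth.min()
    if smooth.max() > 0:
        smooth /= smooth.max()
    return (lo + smooth * (hi - lo)).astype(np.uint8)


def _insect_axes(cfg: SceneConfig, area: float) -> tuple[float, float]:
    """Semi-axes of the insect ellipse scaled so its area matches ``area``."""
    a0 = cfg.body_length / 2.0
    b0 = cfg.body_area / (math.pi * a0)
    s = math.sqrt(area / cfg.body_area)
    return a0 * s, b0 * s


def render_frames(truth: GroundTruth, cfg: SceneConfig) -> np.ndarray:
    """Rasterise a scene as a (n, H, W) uint8 grayscale stack.

    Static textured background; the insect as a filled ellipse of the
    current visible area at the true position, aligned with its heading;
    distractors as oscillating/flickering ellipses.  Bit-identical per seed.
    """
    bg = _make_background(cfg)
    n = truth.n_frames
    frames = np.repeat(bg[None, :, :], n, axis=0)

    d = cfg.distractors
    if d.count > 0:
        drng = np.random.default_rng(cfg.seed + 2_000_003)
        anchors = np.column_stack(
            [
                drng.uniform(0, cfg.width - 1, d.count),
                drng.uniform(0, cfg.height - 1, d.count),
            ]
        )
        sizes = drng.uniform(d.size_range[0], d.size_range[1], (d.count, 2))
        phases = drng.uniform(0, 2 * math.pi, d.count)
        directions = drng.uniform(0, 2 * math.pi, d.count)
        hidden = drng.random((d.count, n)) < d.flicker_rate
    for k in range(n):
        frame = frames[k]
        if d.count > 0:
            sway = d.amplitude * np.sin(2 * math.pi * k / d.period + phases)
            cx = anchors[:, 0] + sway * np.cos(directions)
            cy = anchors[:, 1] + sway * np.sin(directions)
            for j in range(d.count):
                if hidden[j, k]:
                    continue
                rr, cc = draw_ellipse(
                    cy[j], cx[j], sizes[j, 0], sizes[j, 1], shape=frame.shape
                )
                frame[rr, cc] = cfg.distractor_intensity
        if truth.areas[k] > 0:
            x, y = truth.positions[k]
            a, b = _insect_axes(cfg, truth.areas[k])
            rr, cc = draw_ellipse(
                y, x, b, a, shape=frame.shape, rotation=-truth.headings[k]
            )
            frame[rr, cc] = cfg.insect_intensity
    return frames


def emit_detection_stream(
    truth: GroundTruth,
    noise: tuple[float, float, float] = (0.0, 0.0, 0.0),
    seed: int = 0,
    path: str | Path | None = None,
) -> str:
    """Serialize an oracle detector's output to the CSV interchange format.

    ``noise`` is (miss_rate, position_sigma, false_positive_rate).  Returns
    the CSV text; also writes it to ``path`` when given.
    """
    miss, sigma, fp = noise
    det = OracleDetector(
        truth,
        miss_rate=miss,
        position_sigma=sigma,
        false_positive_rate=fp,
        seed=seed,
        min_confidence=0.0,
    )
    lines = ["frame,x_min,y_min,x_max,y_max,confidence"]
    for k in range(truth.n_frames):
        for rec in det.detect(None, k):
            x0, y0, x1, y1 = rec.bbox
            lines.append(
                f"{k},{x0:.4f},{y0:.4f},{x1:.4f},{y1:.4f},{rec.confidence:.4f}"
            )
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


@dataclass
class Scores:
    """Tracker-vs-truth scores mirroring the field evaluation semantics:
    a frame counts as successfully detected when a recorded position falls
    within ``radius`` of the true position (≈ within the insect's body), and
    occlusion/exit episodes are scored as recorded/correct/missed events."""

    detection_rate: float
    n_visible: int
    n_hit: int
    occlusion_recorded: int
    occlusion_correct: int
    occlusion_missed: int
    exit_recorded: int
    exit_correct: int
    exit_missed: int


def score_against_truth(
    tracks, truth: GroundTruth, radius: float | None = None, event_slack: int = 30
) -> Scores:
    """Score finished tracks against the scene's ground truth.

    ``radius`` defaults to the insect's equivalent circular radius
    √(body_area/π).  An occlusion event is correct when some track logged an
    ``occluded`` classification within the event's interval (plus
    ``event_slack`` frames for the classification latency); an exit is
    correct when an ``exited`` event was logged at or after the true exit.
    """
    if radius is None:
        radius = math.sqrt(truth.body_area / math.pi)
    recorded: dict[int, list[tuple[float, float]]] = {}
    for tr in tracks:
        for p in tr.points:
            recorded.setdefault(p.frame_index, []).append((p.x, p.y))
    n_visible = int(truth.visible.sum())
    n_hit = 0
    for k in np.nonzero(truth.visible)[0]:
        tx, ty = truth.positions[k]
        for x, y in recorded.get(int(k), []):
            if (x - tx) ** 2 + (y - ty) ** 2 <= radius * radius:
                n_hit += 1
                break

    occl_events = [
        (ev.frame, ev.event) for tr in tracks for ev in tr.events if ev.event == "occluded"
    ]
    occ_correct = 0
    occ_missed = 0
    used: set[int] = set()
    for ev in truth.occlusions:
        lo, hi = ev.start, ev.start + ev.duration + event_slack
        hit = next(
            (j for j, (f, _) in enumerate(occl_events) if j not in used and lo <= f <= hi),
            None,
        )
        if hit is None:
            occ_missed += 1
        else:
            used.add(hit)
            occ_correct += 1

    exit_events = [ev.frame for tr in tracks for ev in tr.events if ev.event == "exited"]
    exit_correct = 0
    exit_missed = 0
    if truth.exit_frame is not None:
        if any(f >= truth.exit_frame for f in exit_events):
            exit_correct = 1
        else:
            exit_missed = 1

    return Scores(
        detection_rate=n_hit / n_visible if n_visible else 0.0,
        n_visible=n_visible,
        n_hit=n_hit,
        occlusion_recorded=len(occl_events),
        occlusion_correct=occ_correct,
        occlusion_missed=occ_missed,
        exit_recorded=len(exit_events),
        exit_correct=exit_correct,
        exit_missed=exit_missed,
    )
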