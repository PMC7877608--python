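"""Behavioural summaries derived from finished tracks.

Speeds (mm/s) and signed turn angles (degrees) are computed from detected
positions only — carried-forward positions are placeholders, not
measurements.  Positional heat-maps aggregate time spent per square bin
whose area defaults to the insect's average body area.  The visibility
partition divides each track's time span into visible / occluded /
un-estimated durations using the disappearance classifications in the
track's event log.

Turn-angle sign convention: positive angles are counter-clockwise turns as
seen on screen.  Image coordinates have y pointing down, so this is the
negative of the usual mathematical angle between successive displacement
vectors; a reversal maps to +180°.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import Calibration

__all__ = [
    "TrajectorySummary",
    "HeatMap",
    "compute_speeds",
    "compute_turn_angles",
    "heatmap",
    "visibility_partition",
    "summarize_track",
]


@dataclass
class TrajectorySummary:
    speeds_mm_s: list[float]
    turn_angles_deg: list[float]
    visible_duration: float  # seconds
    occluded_duration: float
    unestimated_duration: float
    total_duration: float


@dataclass
class HeatMap:
    """Aggregate position counts over square bins tiling the frame."""

    grid: np.ndarray  # (n_rows, n_cols) counts
    bin_side: float  # pixels
    extent: tuple[int, int]  # (width, height)


def compute_speeds(track, cal: Calibration) -> list[float]:
    """Finite-difference speeds (mm/s) between consecutive detected points.

    Displacement is divided by the frame gap, so speeds remain per-frame
    rates across short undetected gaps.  Fewer than two detected points
    yield an empty list.
    """
    det = [p for p in track.points if p.source != "carried_forward"]
    out: list[float] = []
    for a, b in zip(det, det[1:]):
        gap = b.frame_index - a.frame_index
        dist_px = math.dist((a.x, a.y), (b.x, b.y))
        out.append(dist_px / cal.pixels_per_mm * cal.fps / gap)
    return out


def compute_turn_angles(track, magnitude_only: bool = False) -> list[float]:
    """Signed heading change (degrees in (−180, 180]) between successive
    displacement vectors of the detected positions; zero-length segments are
    skipped.  ``magnitude_only`` returns absolute angles (the convention used
    when the sign is not of interest)."""
    det = [p for p in track.points if p.source != "carried_forward"]
    segs = []
    for a, b in zip(det, det[1:]):
        v = (b.x - a.x, b.y - a.y)
        if v != (0.0, 0.0):
            segs.append(v)
    out: list[float] = []
    for v1, v2 in zip(segs, segs[1:]):
        dot = v1[0] * v2[0] + v1[1] * v2[1]
        cross = v1[0] * v2[1] - v1[1] * v2[0]
        # y-down image coordinates: negate to make counter-clockwise-on-screen
        # turns positive
        ang = -math.degrees(math.atan2(cross, dot))
        if ang <= -180.0:
            ang += 360.0
        out.append(abs(ang) if magnitude_only else ang)
    return out


def heatmap(
    tracks,
    geometry: tuple[int, int],
    bin_area: float = 1465.0,
    include_carried_forward: bool = False,
) -> HeatMap:
    """Positional heat-map: square bins of side √bin_area tiling the frame;
    each recorded position increments its bin, so the grid sum equals the
    number of binned positions (duration in frames)."""
    if bin_area <= 0:
        raise ValueError("bin_area must be > 0")
    w, h = geometry
    side = math.sqrt(bin_area)
    n_cols = max(1, math.ceil(w / side))
    n_rows = max(1, math.ceil(h / side))
    grid = np.zeros((n_rows, n_cols), dtype=int)
    for tr in tracks:
        for p in tr.points:
            if p.source == "carried_forward" and not include_carried_forward:
                continue
            col = min(int(p.x // side), n_cols - 1)
            row = min(int(p.y // side), n_rows - 1)
            if 0 <= p.x < w and 0 <= p.y < h:
                grid[row, col] += 1
    return HeatMap(grid=grid, bin_side=side, extent=(w, h))


def visibility_partition(track, fps: float) -> tuple[float, float, float]:
    """Divide the track's span into (visible, occluded, un-estimated)
    durations in seconds.

    Frames with a detected point are visible.  Runs of carried-forward
    frames inherit the episode's classification from the event log: occluded
    episodes count as occluded, candidate-exit and unknown episodes as
    un-estimated, and gaps too short to have been classified (< τ̄ frames)
    count as visible time.  The three durations sum exactly to the frame
    span.
    """
    if not track.points:
        return (0.0, 0.0, 0.0)
    classifications = {
        ev.frame: ev.event
        for ev in track.events
        if ev.event in {"occluded", "candidate_exit", "unknown"}
    }
    n_visible = n_occluded = n_unestimated = 0
    run: list[int] = []  # frame indices of the current carried-forward run

    def flush() -> None:
        nonlocal n_visible, n_occluded, n_unestimated
        if not run:
            return
        label = next(
            (classifications[f] for f in run if f in classifications), None
        )
        if label == "occluded":
            n_occluded += len(run)
        elif label in {"candidate_exit", "unknown"}:
            n_unestimated += len(run)
        else:  # unclassified short gap
            n_visible += len(run)
        run.clear()

    for p in track.points:
        if p.source == "carried_forward":
            run.append(p.frame_index)
        else:
            flush()
            n_visible += 1
    flush()
    return (n_visible / fps, n_occluded / fps, n_unestimated / fps)


def summarize_track(track, cal: Calibration) -> TrajectorySummary:
    vis, occ, unest = visibility_partition(track, cal.fps)
    return TrajectorySummary(
        speeds_mm_s=compute_speeds(track, cal),
        turn_angles_deg=compute_turn_angles(track),
        visible_duration=vis,
        occluded_duration=occ,
        unestimated_duration=unest,
        total_duration=vis + occ + unest,
    )
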