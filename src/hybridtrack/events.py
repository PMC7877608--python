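"""Disappearance classification: occlusion versus field-of-view exit.

When the focal insect has gone undetected for τ̄ consecutive frames the
tracker must decide what happened:

* **Occlusion** — the insect crawled under foliage.  Evidence: its visible
  body area, measured by the motion channel over the frames preceding the
  disappearance, shows a negative least-squares trend (the body progressively
  slips out of view).  Slope of the ordinary least-squares line through
  (frame, area) points:

      m = (n·ΣAf − ΣA·Σf) / (n·Σf² − (Σf)²)

* **Field-of-view exit** — the insect left the frame.  If the last detected
  position lies within an edge margin of a frame boundary the disappearance
  is assigned to a possible exit and the occlusion test is not executed (the
  edge rule takes precedence: clipping at the boundary also shrinks the
  visible area, so the area trend is uninformative there).

A candidate exit is then confirmed probabilistically: the exit probability β
is the share of the insect's own empirical speed distribution fast enough to
have carried it from its last detected position to the nearest frame
boundary during the τ undetected frames.  Starting from quantile level
i = 1.00, the level is lowered in steps of 0.01 (floored at 0) while the
predicted distance travelled d_t = τ·η_i still exceeds the edge distance
d_e; then β = (1 − i) × 100 %.  β is monotone in τ and reaches 100 % when
the insect vanished on the boundary itself.  When β exceeds the threshold
β̄ the track is paused and the tracker starts looking for new insects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .association import speed_quantile

__all__ = [
    "AreaTrendFit",
    "ExitEstimatorState",
    "DegenerateFitError",
    "EstimationUnavailableError",
    "fit_area_trend",
    "classify_disappearance",
    "distance_to_edge",
    "exit_probability",
]


class DegenerateFitError(ValueError):
    """Area-trend fit requested on a window with no frame spread."""


class EstimationUnavailableError(ValueError):
    """Exit probability requested with an empty speed history."""


@dataclass
class AreaTrendFit:
    """Least-squares line through (frame, visible area) points."""

    m: float  # gradient, pixels of area per frame
    n: int  # number of points in the window
    window: list[tuple[int, float]] = field(default_factory=list)


@dataclass
class ExitEstimatorState:
    """State of the exit-probability estimator for one disappearance episode.

    d_e is fixed at the disappearance point (shortest distance from the last
    detected position to any frame boundary); i is the current quantile
    level, held internally in exact hundredths; β ∈ [0, 100] percent.
    """

    tau: int
    tau_bar: int = 15
    beta_bar: float = 85.0
    d_e: float = 0.0
    i_centi: int = 100  # quantile level × 100
    beta: float = 0.0

    @property
    def i(self) -> float:
        return self.i_centi / 100.0


def fit_area_trend(window: list[tuple[int, float]]) -> AreaTrendFit:
    """Closed-form OLS slope of visible body area against frame index.

    ``window`` holds (frame, area) pairs from the motion channel over the
    frames preceding a disappearance; requires ≥ 2 points with distinct
    frames.
    """
    n = len(window)
    if n < 2:
        raise ValueError("area-trend fit needs at least 2 points")
    f = np.array([p[0] for p in window], dtype=float)
    a = np.array([p[1] for p in window], dtype=float)
    denom = n * np.sum(f * f) - np.sum(f) ** 2
    if denom == 0:
        raise DegenerateFitError("all frame indices identical")
    m = (n * np.sum(a * f) - np.sum(a) * np.sum(f)) / denom
    return AreaTrendFit(m=float(m), n=n, window=list(window))


def distance_to_edge(position: tuple[float, float], frame_size: tuple[int, int]) -> float:
    """Shortest distance from a position to any frame boundary.

    ``frame_size`` is (width, height); boundaries are x = 0, x = width − 1,
    y = 0, y = height − 1.  Clamped at 0 for positions outside the frame.
    """
    x, y = position
    w, h = frame_size
    return max(0.0, min(x, w - 1 - x, y, h - 1 - y))


def classify_disappearance(
    fit: AreaTrendFit | None,
    last_position: tuple[float, float],
    frame_size: tuple[int, int],
    edge_margin: float,
) -> str:
    """Classify a disappearance episode once τ reaches τ̄.

    Returns ``"candidate_exit"`` when the last detected position lies within
    ``edge_margin`` of a frame boundary (edge rule, takes precedence);
    otherwise ``"occluded"`` when the area trend is strictly negative;
    otherwise ``"unknown"`` (including m = 0 exactly, and a missing or
    degenerate fit).
    """
    if distance_to_edge(last_position, frame_size) <= edge_margin:
        return "candidate_exit"
    if fit is not None and fit.m < 0:
        return "occluded"
    return "unknown"


def exit_probability(
    state: ExitEstimatorState, speed_history: list[float]
) -> ExitEstimatorState:
    """One update of the exit-probability scan; returns the new state.

    On the first call of an episode (τ = τ̄) the quantile level starts at
    1.00, otherwise it continues from the previous call.  If the predicted
    travel d_t = τ·η_i does not exceed the edge distance d_e the state is
    returned unchanged (no evidence of exit at the current level); otherwise
    the level is lowered in 0.01 steps, recomputing d_t, until d_t ≤ d_e or
    the level floors at 0, and β = (1 − i) × 100.

    Within an episode the level never rises, so β is monotone non-decreasing
    in τ.
    """
    if len(speed_history) == 0:
        raise EstimationUnavailableError("exit probability needs a speed history")
    if state.tau < state.tau_bar:
        raise ValueError("exit probability is only evaluated once tau >= tau_bar")
    i_centi = 100 if state.tau == state.tau_bar else state.i_centi
    d_t = state.tau * speed_quantile(speed_history, i_centi / 100.0)
    if d_t <= state.d_e:
        return replace(state, i_centi=i_centi)
    while d_t > state.d_e and i_centi > 0:
        i_centi -= 1
        d_t = state.tau * speed_quantile(speed_history, i_centi / 100.0)
    beta = (1.0 - i_centi / 100.0) * 100.0
    return replace(state, i_centi=i_centi, beta=beta)
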