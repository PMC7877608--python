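"""Motion model, adaptive gating and data association.

The focal insect's next position is predicted by a constant-velocity model
over three frames: P_k = 2·D_{k−1} − D_{k−2}.  Detections are assigned to
predictions by minimum total Euclidean distance (Hungarian assignment), and a
pairing is rejected when its distance exceeds a maximum detection threshold
(MDT) that adapts to the insect's own recorded speeds:

* motion channel:      MDT_BS = max(d_int, d_max)
* appearance channel:  MDT_DL = 2 × (MDT_BS + η_level),
  level = min(max(0, τ − τ̄) / 100, 0.99)

where d_int is the species' average body length in pixels, d_max the largest
recorded inter-frame displacement of the focal insect, η_q the empirical
q-quantile of its speeds, and τ the current run of consecutive undetected
frames.  The appearance gate therefore widens by one speed percentile for
every undetected frame beyond τ̄, letting the tracker re-acquire an insect
that travelled while unseen; it always exceeds the motion gate because
motion-channel detections are more prone to false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .appearance import Detection

__all__ = [
    "PredictedPosition",
    "GatingState",
    "predict_position",
    "speed_quantile",
    "mdt_bs",
    "mdt_dl",
    "associate",
]


@dataclass
class PredictedPosition:
    """Constant-velocity prediction for one frame; may lie outside the frame
    (extrapolation past a boundary is legal and meaningful)."""

    x: float
    y: float
    frame_index: int = -1

    @property
    def xy(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass
class GatingState:
    """Running statistics that drive the adaptive gates.

    speed_history holds magnitudes of displacements between consecutive
    *detected* positions only; carried-forward (predicted) positions are
    excluded so the speed distribution is not polluted with zeros.
    """

    d_int: float
    tau_bar: int = 15
    speed_history: list[float] = field(default_factory=list)
    tau: int = 0  # consecutive undetected frames

    def __post_init__(self) -> None:
        if self.d_int <= 0:
            raise ValueError("d_int must be > 0")

    @property
    def d_max(self) -> float:
        """Running maximum inter-frame displacement (0 before any speed)."""
        return max(self.speed_history, default=0.0)

    def record_speed(self, speed: float) -> None:
        self.speed_history.append(float(speed))


def predict_position(
    d_km1: tuple[float, float], d_km2: tuple[float, float], frame_index: int = -1
) -> PredictedPosition:
    """Linear extrapolation from the two preceding accepted positions.

    On the first frame after initial detection pass ``d_km2 = d_km1`` so the
    prediction equals the current position.  Exact for integer inputs.
    """
    return PredictedPosition(
        x=2.0 * d_km1[0] - d_km2[0],
        y=2.0 * d_km1[1] - d_km2[1],
        frame_index=frame_index,
    )


def speed_quantile(speed_history, level: float) -> float:
    """Empirical quantile of the speed sample.

    Convention (used consistently by the gate and the exit estimator):
    sorted sample with linear interpolation between order statistics, so
    level 0 is the minimum and level 1 the maximum.
    """
    if len(speed_history) == 0:
        raise ValueError("empty speed history")
    return float(np.quantile(np.asarray(speed_history, dtype=float), level))


def mdt_bs(state: GatingState) -> float:
    """Motion-channel gate: max(d_int, d_max); equals d_int until the first
    displacement is recorded."""
    return max(state.d_int, state.d_max)


def mdt_dl(state: GatingState) -> float:
    """Appearance-channel gate (strictly larger than the motion gate).

    The quantile level rises 0.01 per undetected frame past τ̄, capped at
    0.99; with an empty speed history the gate is simply twice the motion
    gate.  Monotone non-decreasing in τ.
    """
    bs = mdt_bs(state)
    if not state.speed_history:
        return 2.0 * bs
    level = min(max(0, state.tau - state.tau_bar) / 100.0, 0.99)
    return 2.0 * (bs + speed_quantile(state.speed_history, level))


def associate(
    predictions: list[PredictedPosition],
    detections: list[Detection],
    gate: float,
) -> list[int | None]:
    """Assign detections to predictions minimising total Euclidean distance.

    Returns, per prediction, the index of its matched detection or ``None``.
    Pairs farther apart than ``gate`` are never matched; exact-cost ties are
    broken toward the lowest detection index for determinism.
    """
    if gate <= 0:
        raise ValueError("gate must be > 0")
    out: list[int | None] = [None] * len(predictions)
    if not predictions or not detections:
        return out
    pred = np.array([p.xy for p in predictions], dtype=float)
    det = np.array([d.centroid for d in detections], dtype=float)
    cost = np.linalg.norm(pred[:, None, :] - det[None, :, :], axis=2)
    # forbid over-gate pairs with a large finite cost so the LAP stays feasible
    big = gate * (len(predictions) + len(detections) + 1) + 1.0
    gated = np.where(cost > gate, big, cost)
    # deterministic tie-break: prefer lower detection index
    gated = gated + np.arange(len(detections))[None, :] * 1e-9
    rows, cols = linear_sum_assignment(gated)
    for r, c in zip(rows, cols):
        if cost[r, c] <= gate:
            out[r] = int(c)
    return out
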