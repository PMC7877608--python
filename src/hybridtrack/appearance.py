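"""Appearance-channel detection.

The tracker treats the appearance detector as a contract: any object with a
``detect(frame, frame_index) -> list[Detection]`` method and a
``min_confidence`` attribute.  In the field this role is played by a trained
object-detection network; this package does not bundle one.  Two
implementations ship:

* :class:`StreamDetector` replays a pre-computed per-frame detection file
  (CSV with header ``frame,x_min,y_min,x_max,y_max,confidence``, or JSON
  lines with the same keys) exported from any external detector.
* :class:`OracleDetector` serves ground-truth positions from a synthetic
  scene, optionally corrupted with misses, position noise and false
  positives — the test stand-in for a trained model.

To wire a real network, wrap its per-frame inference in the same ``detect``
signature, or export its detections to the CSV interchange format and use
:class:`StreamDetector`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np

__all__ = ["Detection", "AppearanceDetector", "StreamDetector", "OracleDetector"]


@dataclass
class Detection:
    """One candidate insect location in one frame."""

    frame_index: int
    centroid: tuple[float, float]  # (x, y) pixels
    bbox: tuple[float, float, float, float] | None = None  # x_min,y_min,x_max,y_max
    area: float | None = None  # visible body area, px (motion channel only)
    confidence: float = 1.0
    source: str = "appearance"  # {"motion", "appearance"}

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")
        if self.bbox is not None:
            x0, y0, x1, y1 = self.bbox
            x, y = self.centroid
            if not (x0 <= x <= x1 and y0 <= y <= y1):
                raise ValueError("bbox does not contain centroid")


@runtime_checkable
class AppearanceDetector(Protocol):
    min_confidence: float

    def detect(self, frame, frame_index: int) -> list[Detection]: ...


_STREAM_COLUMNS = ["frame", "x_min", "y_min", "x_max", "y_max", "confidence"]


class StreamDetector:
    """Replay detections from an interchange file.

    The detector is a pure function of the file: queries for frames absent
    from the file return ``[]``, and detections below ``min_confidence`` are
    filtered out.  Centroids are bounding-box centers.
    """

    def __init__(self, detections_file: str | Path, min_confidence: float = 0.5):
        self.path = Path(detections_file)
        self.min_confidence = min_confidence
        self._by_frame: dict[int, list[Detection]] = {}
        self._parse()

    def _parse(self) -> None:
        text = self.path.read_text()
        lines = text.splitlines()
        if not lines:
            return
        json_mode = lines[0].lstrip().startswith("{")
        start = 0 if json_mode else 1
        if not json_mode:
            header = [h.strip() for h in lines[0].split(",")]
            if header != _STREAM_COLUMNS:
                raise ValueError(
                    f"{self.path}:1: expected header {','.join(_STREAM_COLUMNS)}"
                )
        for lineno, line in enumerate(lines[start:], start=start + 1):
            if not line.strip():
                continue
            try:
                if json_mode:
                    rec = json.loads(line)
                    vals = [rec[k] for k in _STREAM_COLUMNS]
                else:
                    parts = line.split(",")
                    if len(parts) != len(_STREAM_COLUMNS):
                        raise ValueError(f"expected {len(_STREAM_COLUMNS)} fields")
                    vals = [float(p) for p in parts]
                frame = int(vals[0])
                x0, y0, x1, y1, conf = map(float, vals[1:])
                det = Detection(
                    frame_index=frame,
                    centroid=((x0 + x1) / 2.0, (y0 + y1) / 2.0),
                    bbox=(x0, y0, x1, y1),
                    confidence=conf,
                )
            except (ValueError, KeyError, json.JSONDecodeError) as exc:
                raise ValueError(f"{self.path}:{lineno}: malformed record: {exc}") from exc
            self._by_frame.setdefault(frame, []).append(det)

    def detect(self, frame, frame_index: int) -> list[Detection]:
        dets = self._by_frame.get(frame_index, [])
        return [d for d in dets if d.confidence >= self.min_confidence]


@dataclass
class OracleDetector:
    """Ground-truth-backed detector for synthetic scenes.

    While the insect is visible it is reported with probability
    ``1 − miss_rate`` at its true position perturbed by isotropic Gaussian
    noise of scale ``position_sigma``; independent false positives are added
    as a Poisson(``false_positive_rate``) count per frame at positions
    uniform over the frame.  Fully deterministic given the seed.
    """

    truth: "object"  # GroundTruth from hybridtrack.synthetic
    miss_rate: float = 0.0
    position_sigma: float = 0.0
    false_positive_rate: float = 0.0
    seed: int = 0
    min_confidence: float = 0.5
    _streams: dict[int, list[Detection]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for name in ("miss_rate", "position_sigma", "false_positive_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.miss_rate > 1:
            raise ValueError("miss_rate must be <= 1")
        self._streams = self._generate()

    def _generate(self) -> dict[int, list[Detection]]:
        rng = np.random.default_rng(self.seed)
        truth = self.truth
        w, h = truth.width, truth.height
        half = truth.body_length / 2.0
        out: dict[int, list[Detection]] = {}
        for k in range(truth.n_frames):
            dets: list[Detection] = []
            if truth.visible[k] and rng.random() >= self.miss_rate:
                x, y = truth.positions[k]
                if self.position_sigma > 0:
                    x += rng.normal(0.0, self.position_sigma)
                    y += rng.normal(0.0, self.position_sigma)
                x = float(np.clip(x, 0, w - 1))
                y = float(np.clip(y, 0, h - 1))
                dets.append(
                    Detection(
                        frame_index=k,
                        centroid=(x, y),
                        bbox=(x - half, y - half, x + half, y + half),
                        confidence=0.99,
                    )
                )
            for _ in range(rng.poisson(self.false_positive_rate)):
                fx = rng.uniform(0, w - 1)
                fy = rng.uniform(0, h - 1)
                conf = rng.uniform(0.5, 0.95)
                dets.append(
                    Detection(
                        frame_index=k,
                        centroid=(float(fx), float(fy)),
                        bbox=(fx - half, fy - half, fx + half, fy + half),
                        confidence=float(conf),
                    )
                )
            if dets:
                out[k] = dets
        return out

    def detect(self, frame, frame_index: int) -> list[Detection]:
        dets = self._streams.get(frame_index, [])
        return [d for d in dets if d.confidence >= self.min_confidence]
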