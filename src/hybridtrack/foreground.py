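"""Motion-channel detection: background modelling, mask denoising and blob
extraction.

The pipeline per frame is: background model → raw binary foreground mask →
median filter → binary erosion → 8-connected components filtered by area →
blob centroids.  The centroid of an area-filtered blob is the motion
channel's candidate position for the insect.

The background model is a pluggable contract (any object with an
``apply(frame) -> mask`` method and a ``warmup_frames`` attribute).  The
shipped reference implementation, :class:`RunningStatsBackground`, keeps a
per-pixel exponentially weighted mean and variance and flags pixels deviating
from the mean by more than ``k·σ`` as foreground.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import MotionConfig

__all__ = [
    "RunningStatsBackground",
    "ForegroundMask",
    "Blob",
    "denoise_mask",
    "extract_blobs",
    "count_change_regions",
    "write_mask_png",
]

#: 8-connectivity structuring element for component labelling
_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class ForegroundMask:
    """Binary foreground mask for one frame."""

    mask: np.ndarray  # bool, same H×W as the frame
    frame_index: int

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)


@dataclass
class Blob:
    """One connected foreground component that survived area filtering."""

    area: int
    centroid: tuple[float, float]  # (x, y), sub-pixel
    bbox: tuple[int, int, int, int]  # (x_min, y_min, x_max, y_max) inclusive

    def __post_init__(self) -> None:
        x, y = self.centroid
        x0, y0, x1, y1 = self.bbox
        assert x0 <= x <= x1 and y0 <= y <= y1, "centroid outside bounding box"


class RunningStatsBackground:
    """Per-pixel exponentially weighted mean/variance background model.

    A pixel is foreground when ``|x − μ| > k·max(σ, min_sigma)``.  Statistics
    are updated every frame with learning rate ``alpha`` (so a stationary
    change is absorbed into the background with time constant ≈ 1/alpha
    frames).  During the first ``warmup_frames`` frames the statistics are
    still settling and the returned mask is forced to all-background.

    Foreground pixels update with the much smaller rate ``alpha_foreground``
    (selective update): this keeps a moving object from smearing itself into
    the background and leaving "ghost" foreground behind after it departs,
    while still letting a genuinely permanent scene change be absorbed
    eventually.  During warm-up the full rate applies everywhere so the model
    can settle from its first-frame initialisation.

    Parameters
    ----------
    alpha : learning rate of the exponential update at background pixels.
    alpha_foreground : learning rate at pixels currently flagged foreground.
    k_sigma : foreground threshold in standard deviations.
    min_sigma : floor on σ (intensity units) so that noiseless or very flat
        backgrounds do not flag foreground on rounding-level changes.
    warmup_frames : settling period during which masks are suppressed.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        alpha_foreground: float = 0.005,
        k_sigma: float = 3.5,
        min_sigma: float = 5.0,
        warmup_frames: int = 30,
    ):
        self.alpha = alpha
        self.alpha_foreground = alpha_foreground
        self.k_sigma = k_sigma
        self.min_sigma = min_sigma
        self.warmup_frames = warmup_frames
        self._mean: np.ndarray | None = None
        self._var: np.ndarray | None = None
        self._n_seen = 0

    def apply(self, frame: np.ndarray) -> ForegroundMask:
        """Update the model with one frame and return the raw (pre-denoise)
        foreground mask."""
        x = np.asarray(frame, dtype=float)
        if x.ndim != 2:
            raise ValueError("background model operates on single-channel frames")
        if self._mean is None:
            self._mean = x.copy()
            self._var = np.zeros_like(x)
        elif x.shape != self._mean.shape:
            raise ValueError(
                f"frame shape {x.shape} does not match model shape {self._mean.shape}"
            )
        sigma = np.sqrt(self._var)
        np.maximum(sigma, self.min_sigma, out=sigma)
        fg = np.abs(x - self._mean) > self.k_sigma * sigma
        in_warmup = self._n_seen < self.warmup_frames
        alpha = np.where(fg & ~in_warmup, self.alpha_foreground, self.alpha)
        delta = x - self._mean
        self._mean += alpha * delta
        self._var += alpha * (delta * delta - self._var)
        idx = self._n_seen
        self._n_seen += 1
        if idx < self.warmup_frames:
            fg = np.zeros_like(fg)
        return ForegroundMask(fg, frame_index=idx)


def denoise_mask(mask: ForegroundMask | np.ndarray, cfg: MotionConfig) -> ForegroundMask:
    """Median filter (kernel ``cfg.median_kernel``) then binary erosion
    (square element of side ``cfg.erosion_kernel``).

    The median filter removes isolated noise pixels; the erosion then trims
    component boundaries, so the output foreground set is always a subset of
    the median-filtered intermediate.
    """
    m, idx = _as_bool(mask)
    if cfg.median_kernel > 1:
        # binary median == majority vote over the window; reflect boundary
        m = ndimage.median_filter(m.astype(np.uint8), size=cfg.median_kernel, mode="reflect").astype(bool)
    if cfg.erosion_kernel > 1:
        structure = np.ones((cfg.erosion_kernel, cfg.erosion_kernel), dtype=bool)
        m = ndimage.binary_erosion(m, structure=structure, border_value=0)
    return ForegroundMask(m, frame_index=idx)


def extract_blobs(mask: ForegroundMask | np.ndarray, min_area: float) -> list[Blob]:
    """8-connected components with area ≥ ``min_area``, each reduced to its
    pixel-mean centroid and inclusive bounding box.

    A component exactly at ``min_area`` is kept.  Blobs are returned in
    labelling order (top-left first), which is deterministic.
    """
    m, _ = _as_bool(mask)
    labels, n = ndimage.label(m, structure=_EIGHT)
    if n == 0:
        return []
    areas = np.bincount(labels.ravel())[1:]
    blobs: list[Blob] = []
    slices = ndimage.find_objects(labels)
    for lab in range(1, n + 1):
        area = int(areas[lab - 1])
        if area < min_area:
            continue
        sl = slices[lab - 1]
        rows, cols = np.nonzero(labels[sl] == lab)
        cy = rows.mean() + sl[0].start
        cx = cols.mean() + sl[1].start
        bbox = (sl[1].start, sl[0].start, sl[1].stop - 1, sl[0].stop - 1)
        blobs.append(Blob(area=area, centroid=(float(cx), float(cy)), bbox=bbox))
    return blobs


def count_change_regions(
    mask: ForegroundMask | np.ndarray,
    center: tuple[float, float],
    radius: float,
    cfg: MotionConfig,
) -> int:
    """Number of connected changed regions (area ≥ ``cfg.region_change_floor``)
    whose centroid lies within Euclidean ``radius`` of ``center``.

    This is the local clutter measure that drives the motion/appearance mode
    switch: one region near the predicted position means the motion channel
    almost certainly sees the insect alone; many regions mean wind-blown
    vegetation is moving and the appearance channel is safer.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    m, _ = _as_bool(mask)
    labels, n = ndimage.label(m, structure=_EIGHT)
    if n == 0:
        return 0
    rows, cols = np.nonzero(m)
    labs = labels[rows, cols]
    areas = np.bincount(labs, minlength=n + 1)[1:]
    mean_y = np.bincount(labs, weights=rows, minlength=n + 1)[1:] / areas
    mean_x = np.bincount(labs, weights=cols, minlength=n + 1)[1:] / areas
    cx, cy = center
    dist2 = (mean_x - cx) ** 2 + (mean_y - cy) ** 2
    ok = (areas >= cfg.region_change_floor) & (dist2 <= radius * radius)
    return int(ok.sum())


def write_mask_png(mask: ForegroundMask, out_dir) -> None:
    """Export a mask for debugging as 8-bit PNG (0 background, 255 foreground),
    named ``mask_<frameindex:06d>.png``."""
    import imageio.v3 as iio
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    iio.imwrite(
        out / f"mask_{mask.frame_index:06d}.png",
        (mask.mask.astype(np.uint8) * 255),
    )


def _as_bool(mask: ForegroundMask | np.ndarray) -> tuple[np.ndarray, int]:
    if isinstance(mask, ForegroundMask):
        return mask.mask, mask.frame_index
    return np.asarray(mask).astype(bool), -1
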