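"""Frame sources: a uniform iterable abstraction over video files, PNG
image-sequence directories and in-memory synthetic frame streams.

Conventions used throughout the package: frame indices are 0-based and
delivered in strictly increasing order with no gaps; pixel (0, 0) is the
top-left corner with x increasing rightward (columns) and y downward (rows);
positions are continuous, so sub-pixel centroids are legal.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterator

import numpy as np

__all__ = [
    "FrameSource",
    "ArraySource",
    "ImageDirSource",
    "VideoFileSource",
    "open_source",
    "to_grayscale",
    "write_frames",
]

#: fixed luma weights for RGB→grayscale conversion (ITU-R BT.601)
GRAY_WEIGHTS = np.array([0.299, 0.587, 0.114])

VIDEO_EXTENSIONS = {".mp4", ".avi", ".mov", ".mkv", ".webm"}


class EmptySourceError(ValueError):
    """Raised when a frame source contains zero frames."""


class FrameSource:
    """Base class: an iterable of frames with spatial/temporal metadata.

    Subclasses set ``width``, ``height``, ``fps`` and ``frame_count``
    (``None`` when unknown a priori) and implement ``_frames``.
    """

    width: int
    height: int
    fps: float
    frame_count: int | None

    def _frames(self) -> Iterator[np.ndarray]:  # pragma: no cover - abstract
        raise NotImplementedError

    def __iter__(self) -> Iterator[np.ndarray]:
        return self._frames()

    def __len__(self) -> int:
        if self.frame_count is None:
            raise TypeError("frame count unknown for this source")
        return self.frame_count

    def _validate(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("frame dimensions must be positive")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.frame_count is not None and self.frame_count == 0:
            raise EmptySourceError("source contains zero frames")


class ArraySource(FrameSource):
    """In-memory stream: a sequence of 2-D (grayscale) or 3-D (color) arrays,
    or a single (n, H, W[, C]) stack."""

    def __init__(self, frames, fps: float = 60.0):
        frames = [np.asarray(f) for f in frames]
        if not frames:
            raise EmptySourceError("source contains zero frames")
        h, w = frames[0].shape[:2]
        for f in frames:
            if f.shape[:2] != (h, w):
                raise ValueError("all frames must share the same geometry")
        self._data = frames
        self.height, self.width = h, w
        self.fps = fps
        self.frame_count = len(frames)
        self._validate()

    def _frames(self) -> Iterator[np.ndarray]:
        return iter(self._data)


class ImageDirSource(FrameSource):
    """A directory of PNG frames; lexicographic file order is frame order."""

    def __init__(self, path: str | Path, fps: float = 60.0):
        import imageio.v3 as iio

        self.path = Path(path)
        if not self.path.is_dir():
            raise IOError(f"not a directory: {self.path}")
        self._files = sorted(self.path.glob("*.png"))
        if not self._files:
            raise EmptySourceError(f"no PNG frames in {self.path}")
        first = iio.imread(self._files[0])
        self.height, self.width = first.shape[:2]
        self.fps = fps
        self.frame_count = len(self._files)
        self._validate()

    def _frames(self) -> Iterator[np.ndarray]:
        import imageio.v3 as iio

        for f in self._files:
            yield iio.imread(f)


class VideoFileSource(FrameSource):
    """A video container file read through imageio (requires an ffmpeg-backed
    plugin for most codecs)."""

    def __init__(self, path: str | Path, fps: float | None = None):
        import imageio.v3 as iio

        self.path = Path(path)
        if not self.path.is_file():
            raise IOError(f"no such video file: {self.path}")
        try:
            meta = iio.immeta(self.path)
            props = iio.improps(self.path)
        except Exception as exc:  # plugin missing or corrupt file
            raise IOError(f"cannot read video file {self.path}: {exc}") from exc
        self.fps = float(fps if fps is not None else meta.get("fps", 0) or 0)
        shape = props.shape
        n = shape[0] if len(shape) >= 3 else None
        self.frame_count = int(n) if n and n > 0 else None
        self.height, self.width = shape[-3:-1] if len(shape) >= 3 else shape[:2]
        if self.frame_count == 0:
            raise EmptySourceError(f"zero frames in {self.path}")
        self._validate()

    def _frames(self) -> Iterator[np.ndarray]:
        import imageio.v3 as iio

        yield from iio.imiter(self.path)


def open_source(path_or_stream, fps: float = 60.0) -> FrameSource:
    """Open a frame source from a path (video file or PNG directory), an
    existing :class:`FrameSource`, or an in-memory frame sequence."""
    if isinstance(path_or_stream, FrameSource):
        return path_or_stream
    if isinstance(path_or_stream, (str, Path)):
        p = Path(path_or_stream)
        if p.is_dir():
            return ImageDirSource(p, fps=fps)
        if p.suffix.lower() in VIDEO_EXTENSIONS:
            return VideoFileSource(p, fps=fps)
        if p.exists():
            raise IOError(f"unsupported media file: {p}")
        raise IOError(f"no such path: {p}")
    return ArraySource(path_or_stream, fps=fps)


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Collapse an RGB frame to a single channel; 1-channel input is returned
    unchanged.  Uses the fixed BT.601 luma weights."""
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3 and frame.shape[2] == 1:
        return frame[:, :, 0]
    if frame.ndim == 3 and frame.shape[2] == 3:
        return frame.astype(float) @ GRAY_WEIGHTS
    raise ValueError(f"expected 1 or 3 channels, got shape {frame.shape}")


def write_frames(frames, out_dir: str | Path, prefix: str = "frame") -> list[Path]:
    """Write frames as lossless PNGs ``<prefix>_<index:06d>.png`` so the
    directory can be re-opened as an :class:`ImageDirSource`."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        p = out / f"{prefix}_{i:06d}.png"
        iio.imwrite(p, np.asarray(frame, dtype=np.uint8))
        paths.append(p)
    return paths
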