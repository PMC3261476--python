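"""Raw nv21 frame-stream I/O.

nv21 is the Android camera YUV420 semi-planar layout: per frame, a full
width x height luma (Y) plane followed by a half-height interleaved chroma
plane with V before U (2x2 subsampled).  Frames are stored back to back in
a flat ``.nv21`` file; a JSON sidecar carries width, height, fps and frame
count.  Capture rate is constant, so frame i's timestamp is simply
``start_time + i / fps``.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, replace

import numpy as np

from .errors import CorruptStreamError, InvalidMetadataError

# The acquisition settings bundle: QCIF resolution at 20 frames/s.
DEFAULT_WIDTH = 176
DEFAULT_HEIGHT = 144
DEFAULT_FPS = 20.0

__all__ = [
    "VideoMeta",
    "Frame",
    "FrameStream",
    "read_nv21",
    "write_nv21",
    "DEFAULT_WIDTH",
    "DEFAULT_HEIGHT",
    "DEFAULT_FPS",
]


@dataclass(frozen=True)
class VideoMeta:
    """Stream geometry and timing.

    Width and height must be even: YUV420 chroma is 2x2 subsampled, so odd
    dimensions cannot tile the VU plane.
    """

    width: int = DEFAULT_WIDTH
    height: int = DEFAULT_HEIGHT
    fps: float = DEFAULT_FPS
    n_frames: int = 0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise InvalidMetadataError(
                f"dimensions must be positive, got {self.width}x{self.height}"
            )
        if self.width % 2 or self.height % 2:
            raise InvalidMetadataError(
                f"nv21 requires even dimensions (2x2 chroma subsampling), "
                f"got {self.width}x{self.height}"
            )
        if self.fps <= 0:
            raise InvalidMetadataError(f"fps must be positive, got {self.fps}")
        if self.n_frames < 0:
            raise InvalidMetadataError(f"n_frames must be >= 0, got {self.n_frames}")

    @property
    def frame_bytes(self) -> int:
        """Bytes per frame: Y plane (w*h) plus interleaved VU plane (w*h/2)."""
        return self.width * self.height * 3 // 2

    @property
    def file_bytes(self) -> int:
        return self.n_frames * self.frame_bytes

    def timestamp(self, i: int) -> float:
        return self.start_time + i / self.fps

    def to_dict(self) -> dict:
        return {
            "width": self.width,
            "height": self.height,
            "fps": self.fps,
            "n_frames": self.n_frames,
            "start_time": self.start_time,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VideoMeta":
        try:
            return cls(
                width=int(d["width"]),
                height=int(d["height"]),
                fps=float(d["fps"]),
                n_frames=int(d["n_frames"]),
                start_time=float(d.get("start_time", 0.0)),
            )
        except KeyError as exc:
            raise InvalidMetadataError(f"sidecar missing key {exc}") from exc


@dataclass(frozen=True)
class Frame:
    """One nv21 frame: uint8 Y plane (h, w) and interleaved VU plane (h//2, w)."""

    y_plane: np.ndarray
    vu_plane: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.y_plane, dtype=np.uint8)
        vu = np.asarray(self.vu_plane, dtype=np.uint8)
        object.__setattr__(self, "y_plane", y)
        object.__setattr__(self, "vu_plane", vu)
        if y.ndim != 2 or vu.ndim != 2:
            raise InvalidMetadataError("planes must be 2-D")
        h, w = y.shape
        if vu.shape != (h // 2, w) or h % 2 or w % 2:
            raise InvalidMetadataError(
                f"VU plane {vu.shape} inconsistent with Y plane {y.shape}"
            )


class FrameStream:
    """Ordered nv21 frames plus metadata.

    Internally the planes live in two dense uint8 arrays — ``y`` with shape
    (n_frames, height, width) and ``vu`` with shape (n_frames, height//2,
    width) — which keeps a 5-minute QCIF stream to ~230 MB and lets the
    extraction stage vectorise over frames.  ``frames`` materialises
    per-frame views on demand.
    """

    def __init__(self, meta: VideoMeta, y: np.ndarray, vu: np.ndarray):
        y = np.ascontiguousarray(y, dtype=np.uint8)
        vu = np.ascontiguousarray(vu, dtype=np.uint8)
        if y.shape != (meta.n_frames, meta.height, meta.width):
            raise InvalidMetadataError(
                f"Y array shape {y.shape} != "
                f"({meta.n_frames}, {meta.height}, {meta.width})"
            )
        if vu.shape != (meta.n_frames, meta.height // 2, meta.width):
            raise InvalidMetadataError(
                f"VU array shape {vu.shape} != "
                f"({meta.n_frames}, {meta.height // 2}, {meta.width})"
            )
        self.meta = meta
        self.y = y
        self.vu = vu

    def __len__(self) -> int:
        return self.meta.n_frames

    def __getitem__(self, i: int) -> Frame:
        return Frame(self.y[i], self.vu[i])

    @property
    def frames(self) -> list[Frame]:
        return [self[i] for i in range(len(self))]

    @property
    def timestamps(self) -> np.ndarray:
        return self.meta.start_time + np.arange(len(self)) / self.meta.fps

    @classmethod
    def from_frames(cls, meta: VideoMeta, frames) -> "FrameStream":
        frames = list(frames)
        meta = replace(meta, n_frames=len(frames))
        if not frames:
            return cls(
                meta,
                np.empty((0, meta.height, meta.width), np.uint8),
                np.empty((0, meta.height // 2, meta.width), np.uint8),
            )
        y = np.stack([f.y_plane for f in frames])
        vu = np.stack([f.vu_plane for f in frames])
        return cls(meta, y, vu)

    def __eq__(self, other) -> bool:
        if not isinstance(other, FrameStream):
            return NotImplemented
        return (
            self.meta == other.meta
            and np.array_equal(self.y, other.y)
            and np.array_equal(self.vu, other.vu)
        )


def read_nv21(path: str | os.PathLike, meta_path: str | os.PathLike) -> FrameStream:
    """Read a raw ``.nv21`` file with its JSON sidecar.

    Raises :class:`CorruptStreamError` when the file size disagrees with the
    sidecar's ``n_frames * width * height * 3/2`` byte count.
    """
    with open(meta_path) as fh:
        meta = VideoMeta.from_dict(json.load(fh))
    expected = meta.file_bytes
    actual = os.path.getsize(path)
    if actual != expected:
        raise CorruptStreamError(
            f"{path}: expected {expected} bytes "
            f"({meta.n_frames} frames x {meta.frame_bytes} B/frame for "
            f"{meta.width}x{meta.height}), found {actual} bytes"
        )
    raw = np.fromfile(path, dtype=np.uint8)
    h, w = meta.height, meta.width
    per = raw.reshape(meta.n_frames, h * 3 // 2, w)
    return FrameStream(meta, per[:, :h, :].copy(), per[:, h:, :].copy())


def write_nv21(
    stream: FrameStream, path: str | os.PathLike, meta_path: str | os.PathLike
) -> None:
    """Write Y-then-VU planes per frame, frames concatenated, plus sidecar."""
    n = len(stream)
    h, w = stream.meta.height, stream.meta.width
    per = np.empty((n, h * 3 // 2, w), dtype=np.uint8)
    per[:, :h, :] = stream.y
    per[:, h:, :] = stream.vu
    per.tofile(path)
    with open(meta_path, "w") as fh:
        json.dump(stream.meta.to_dict(), fh, indent=2)
        fh.write("\n")
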