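"""Frame stream -> scalar photoplethysmographic intensity series.

Blood-volume change modulates how much LED light makes it through the
fingertip to the sensor, so the spatial mean of a plane tracks the pulse.
The luma (Y) plane is the default source: it is full resolution and carries
most of the transmitted-light variance.  The V chroma plane is offered as
an alternative since oxygenated blood shifts the red colour difference.

A covered lens yields a nearly uniform, mid-to-bright field; an uncovered
one yields a dark or highly structured scene.  ``assess_quality`` turns
that into a per-frame finger-presence flag from the plane mean and a
spatial standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, EmptyInputError
from .videoio import Frame, FrameStream

__all__ = [
    "SampleSeries",
    "FrameQuality",
    "QualityThresholds",
    "frame_to_sample",
    "frames_to_series",
    "assess_quality",
    "stream_quality_mask",
]

CHANNELS = ("luma", "v_chroma")


@dataclass
class SampleSeries:
    """Uniformly sampled scalar signal: timestamps ``t`` (s), values ``v``."""

    t: np.ndarray
    v: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.shape != self.v.shape:
            raise ValueError("t and v must have equal length")
        if len(self.t) > 1:
            steps = np.diff(self.t)
            if np.any(np.abs(steps - 1.0 / self.fps) > 1e-9):
                raise ValueError("timestamps must step uniformly by 1/fps")

    def __len__(self) -> int:
        return len(self.t)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"t_s": self.t, "intensity": self.v}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, fps: float | None = None) -> "SampleSeries":
        import pandas as pd

        df = pd.read_csv(path)
        t = df["t_s"].to_numpy(float)
        if fps is None:
            if len(t) < 2:
                raise EmptyInputError("cannot infer fps from fewer than 2 samples")
            fps = 1.0 / float(np.median(np.diff(t)))
        return cls(t, df["intensity"].to_numpy(float), fps)


@dataclass(frozen=True)
class QualityThresholds:
    """Finger-presence rule: mean_lo <= mean_y <= mean_hi and sd <= sd_max.

    Defaults on the 0-255 luma scale: a transilluminated fingertip sits in a
    broad mid-to-bright band (40-250) and is spatially smooth (sd <= 40);
    a removed finger gives either a near-black frame or a structured scene
    with large spatial variance.
    """

    mean_lo: float = 40.0
    mean_hi: float = 250.0
    sd_max: float = 40.0


@dataclass(frozen=True)
class FrameQuality:
    mean_y: float
    spatial_sd: float
    finger_present: bool


def _plane(frame: Frame, channel: str) -> np.ndarray:
    if channel == "luma":
        return frame.y_plane
    if channel == "v_chroma":
        # V samples sit at even columns of the interleaved VU plane.
        return frame.vu_plane[:, 0::2]
    raise ConfigurationError(
        f"unknown channel {channel!r}; expected one of {CHANNELS}"
    )


def frame_to_sample(frame: Frame, channel: str = "luma") -> float:
    """Spatial mean of the selected plane."""
    return float(_plane(frame, channel).mean())


def frames_to_series(stream: FrameStream, channel: str = "luma") -> SampleSeries:
    """Per-frame plane means as a uniformly sampled intensity series."""
    if len(stream) == 0:
        raise EmptyInputError("cannot extract a series from an empty stream")
    if channel == "luma":
        v = stream.y.mean(axis=(1, 2), dtype=np.float64)
    elif channel == "v_chroma":
        v = stream.vu[:, :, 0::2].mean(axis=(1, 2), dtype=np.float64)
    else:
        raise ConfigurationError(
            f"unknown channel {channel!r}; expected one of {CHANNELS}"
        )
    return SampleSeries(stream.timestamps, v, stream.meta.fps)


def assess_quality(
    frame: Frame,
    thresholds: QualityThresholds = QualityThresholds(),
    subsample: int = 2,
) -> FrameQuality:
    """Finger-presence decision for one frame.

    The spatial SD is computed on a regular 1-in-4 pixel subsample (every
    second row and column) for speed; pass ``subsample=1`` for the full
    frame.
    """
    mean_y = float(frame.y_plane.mean())
    sd = float(frame.y_plane[::subsample, ::subsample].std())
    present = (
        thresholds.mean_lo <= mean_y <= thresholds.mean_hi
        and sd <= thresholds.sd_max
    )
    return FrameQuality(mean_y, sd, present)


def stream_quality_mask(
    stream: FrameStream,
    thresholds: QualityThresholds = QualityThresholds(),
    subsample: int = 2,
) -> np.ndarray:
    """Vectorised per-frame finger-presence flags for a whole stream."""
    mean_y = stream.y.mean(axis=(1, 2), dtype=np.float64)
    sd = stream.y[:, ::subsample, ::subsample].std(axis=(1, 2), dtype=np.float64)
    return (
        (mean_y >= thresholds.mean_lo)
        & (mean_y <= thresholds.mean_hi)
        & (sd <= thresholds.sd_max)
    )
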