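"""Synthetic study generator: ground-truth beats, pulsatile nv21 video and
reference-device HR series.

The generator emulates the validation study this pipeline targets: subjects
hold a fingertip over the camera LED for three five-minute seated
conditions (sitting quietly, reading aloud, playing a video game), while a
4-beat rolling-average ECG monitor and a per-second pulse oximeter record
reference HR.  Each simulated subject gets a base HR drawn between
subjects, a small per-condition offset (reading and the video game raise HR
a few bpm above sitting), slow sinusoidal HR modulation and beat-to-beat RR
jitter.  Video frames carry an asymmetric pulse waveform (fast systolic
rise over 30% of the beat, slow decay over the remaining 70%) on top of
baseline luminance, slow illumination drift and per-pixel sensor noise;
optional dropout spans replace frames with uncovered-lens content so the
finger-presence rule fires.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .extract import QualityThresholds, frames_to_series, stream_quality_mask
from .pulse import (
    BeatSeries,
    HRSeries,
    PulseParams,
    analyze_series,
    per_minute_mean,
    per_second_hr,
    rolling_hr,
)
from .videoio import DEFAULT_FPS, DEFAULT_HEIGHT, DEFAULT_WIDTH, FrameStream, VideoMeta

__all__ = [
    "BeatGenConfig",
    "RenderConfig",
    "StudyConfig",
    "StudyDataset",
    "gen_beat_times",
    "render_frames",
    "emulate_ecg_hr",
    "emulate_oximeter_hr",
    "simulate_study",
    "pulse_waveform",
]

RR_FLOOR = 0.3  # s; no physiological beat interval below this
RENDER_CHUNK_FRAMES = 200  # render/extract granularity; fixed for determinism


@dataclass(frozen=True)
class BeatGenConfig:
    """Ground-truth beat schedule parameters for one recording.

    ``mean_hr`` is the subject's base HR for this recording;
    ``modulation_amp``/``modulation_period`` add slow sinusoidal HR change
    (vasomotor/attention-scale, tens of seconds); ``rr_jitter_sd`` is the
    beat-to-beat interval noise.
    """

    mean_hr: float = 72.0
    hr_sd_between_subjects: float = 12.0
    rr_jitter_sd: float = 0.02
    modulation_amp: float = 2.0
    modulation_period: float = 30.0
    duration: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (40.0 <= self.mean_hr <= 180.0):
            raise ConfigurationError(f"mean_hr {self.mean_hr} outside [40, 180] bpm")
        if self.rr_jitter_sd < 0:
            raise ConfigurationError("rr_jitter_sd must be >= 0")
        if self.duration <= 0:
            raise ConfigurationError("duration must be positive")
        peak_hr = self.mean_hr + abs(self.modulation_amp)
        if 60.0 / peak_hr <= RR_FLOOR:
            raise ConfigurationError(
                f"peak HR {peak_hr} bpm implies RR <= {RR_FLOOR} s floor"
            )


@dataclass(frozen=True)
class RenderConfig:
    """Opacity-modulation model for the fingertip video.

    More blood volume absorbs more LED light, so luma dips by
    ``pulse_amp`` at the systolic peak of each beat.  ``drift_amp`` adds
    slow illumination/pressure drift, ``pixel_noise_sd`` is per-pixel
    sensor noise, and ``dropout_spans`` lists (start, end) seconds during
    which the finger is off the lens.
    """

    baseline_y: float = 170.0
    pulse_amp: float = 8.0
    drift_amp: float = 5.0
    drift_period: float = 30.0
    pixel_noise_sd: float = 2.0
    dropout_spans: tuple = ()

    def __post_init__(self) -> None:
        if min(self.pulse_amp, self.drift_amp, self.pixel_noise_sd) < 0:
            raise ConfigurationError("render amplitudes must be >= 0")
        if self.baseline_y + self.pulse_amp + self.drift_amp > 255:
            raise ConfigurationError(
                "baseline_y + pulse_amp + drift_amp must stay within [0, 255]"
            )


@dataclass(frozen=True)
class StudyConfig:
    """Whole-study simulation: subjects x conditions x minutes."""

    n_subjects: int = 14
    conditions: tuple = (("sitting", 0.0), ("reading", 5.0), ("videogame", 2.0))
    minutes_per_condition: int = 5
    mean_hr: float = 72.0
    hr_sd_between_subjects: float = 12.0
    rr_jitter_sd: float = 0.02
    modulation_amp: float = 2.0
    modulation_period: float = 30.0
    oximeter_noise_sd: float = 0.5
    oximeter_delay: float = 1.0
    display_rounding: bool = True
    render: RenderConfig = field(default_factory=RenderConfig)
    width: int = DEFAULT_WIDTH
    height: int = DEFAULT_HEIGHT
    fps: float = DEFAULT_FPS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        if self.minutes_per_condition < 1:
            raise ConfigurationError("minutes_per_condition must be >= 1")
        if self.oximeter_noise_sd < 0:
            raise ConfigurationError("oximeter_noise_sd must be >= 0")
        # normalise nested structures coming from YAML
        object.__setattr__(
            self,
            "conditions",
            tuple((str(name), float(off)) for name, off in self.conditions),
        )
        if isinstance(self.render, dict):
            object.__setattr__(self, "render", RenderConfig(**self.render))

    @property
    def condition_names(self) -> list[str]:
        return [name for name, _ in self.conditions]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conditions"] = [list(c) for c in self.conditions]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        import dataclasses

        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown StudyConfig keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigurationError("study config YAML must be a mapping")
        return cls.from_dict(d)


def gen_beat_times(config: BeatGenConfig, rng: np.random.Generator | None = None) -> BeatSeries:
    """Accumulate beats from t=0 until ``duration``.

    Instantaneous HR(t) = mean_hr + modulation_amp * sin(2*pi*t/period);
    each RR interval is 60/HR at the current beat plus Gaussian jitter,
    floored at the physiological minimum.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    times = [0.0]
    t = 0.0
    while t < config.duration:
        hr = config.mean_hr
        if config.modulation_amp:
            hr = hr + config.modulation_amp * np.sin(
                2.0 * np.pi * t / config.modulation_period
            )
        rr = 60.0 / hr
        if config.rr_jitter_sd:
            rr += rng.normal(0.0, config.rr_jitter_sd)
        rr = max(rr, RR_FLOOR)
        t += rr
        times.append(t)
    return BeatSeries(np.array(times))


def pulse_waveform(phase: np.ndarray) -> np.ndarray:
    """Asymmetric PPG beat shape on phase in [0, 1): fast rise to a peak of
    1 at phase 0.3, slow cosine decay back to 0 at the next beat."""
    phase = np.asarray(phase, dtype=float)
    w = np.empty_like(phase)
    rise = phase < 0.3
    w[rise] = 0.5 - 0.5 * np.cos(np.pi * phase[rise] / 0.3)
    w[~rise] = 0.5 + 0.5 * np.cos(np.pi * (phase[~rise] - 0.3) / 0.7)
    return w


def _frame_means(beats: BeatSeries, t: np.ndarray, cfg: RenderConfig) -> np.ndarray:
    """Noise-free spatial-mean luma at each frame time."""
    bt = beats.times
    idx = np.searchsorted(bt, t, side="right") - 1
    idx = np.clip(idx, 0, len(bt) - 2)
    last = bt[idx]
    rr = bt[idx + 1] - last
    phase = np.clip((t - last) / rr, 0.0, 1.0 - 1e-12)
    y = cfg.baseline_y - cfg.pulse_amp * pulse_waveform(phase)
    if cfg.drift_amp:
        y = y + cfg.drift_amp * np.sin(2.0 * np.pi * t / cfg.drift_period)
    return y


def iter_render_chunks(
    beats: BeatSeries,
    meta: VideoMeta,
    cfg: RenderConfig = RenderConfig(),
    rng: np.random.Generator | None = None,
):
    """Yield the stream as FrameStream chunks of RENDER_CHUNK_FRAMES.

    A five-minute QCIF recording is ~230 MB of planes; chunking lets the
    study simulator render and extract without holding it all.  Chunk
    boundaries are fixed so the byte content is identical however the
    chunks are consumed.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    n, h, w = meta.n_frames, meta.height, meta.width
    duration = n / meta.fps
    if len(beats) < 2 or beats.times[-1] < meta.start_time + duration:
        raise ConfigurationError(
            "beat schedule must span at least the video duration"
        )
    all_t = meta.start_time + np.arange(n) / meta.fps
    base = _frame_means(beats, all_t, cfg)
    in_dropout = np.zeros(n, dtype=bool)
    for s, e in cfg.dropout_spans:
        in_dropout |= (all_t >= s) & (all_t < e)
    vu_fill = np.uint8(128)
    for i0 in range(0, n, RENDER_CHUNK_FRAMES):
        i1 = min(i0 + RENDER_CHUNK_FRAMES, n)
        m = i1 - i0
        buf = rng.standard_normal(size=(m, h, w), dtype=np.float32)
        if cfg.pixel_noise_sd:
            buf *= cfg.pixel_noise_sd
        else:
            buf[:] = 0.0
        buf += base[i0:i1, None, None].astype(np.float32)
        np.clip(buf, 0.0, 255.0, out=buf)
        y = buf.astype(np.uint8)
        drop = in_dropout[i0:i1]
        if drop.any():
            # Uncovered lens: a structured scene -> high spatial variance.
            y[drop] = rng.integers(0, 256, size=(int(drop.sum()), h, w), dtype=np.uint8)
        vu = np.full((m, h // 2, w), vu_fill, dtype=np.uint8)
        chunk_meta = VideoMeta(
            width=w, height=h, fps=meta.fps, n_frames=m,
            start_time=float(all_t[i0]),
        )
        yield FrameStream(chunk_meta, y, vu)


def render_frames(
    beats: BeatSeries,
    video_meta: VideoMeta,
    render_config: RenderConfig = RenderConfig(),
    rng: np.random.Generator | None = None,
) -> FrameStream:
    """Render the full pulsatile nv21 stream (see :func:`iter_render_chunks`)."""
    chunks = list(iter_render_chunks(beats, video_meta, render_config, rng))
    y = np.concatenate([c.y for c in chunks]) if chunks else np.empty(
        (0, video_meta.height, video_meta.width), np.uint8
    )
    vu = np.concatenate([c.vu for c in chunks]) if chunks else np.empty(
        (0, video_meta.height // 2, video_meta.width), np.uint8
    )
    return FrameStream(video_meta, y, vu)


def emulate_ecg_hr(beats: BeatSeries, duration: float, k: int = 4) -> HRSeries:
    """Error-free criterion device: k-beat rolling HR of the true beats,
    sampled-and-held once per second."""
    return per_second_hr(rolling_hr(beats, k), duration)


def emulate_oximeter_hr(
    beats: BeatSeries,
    duration: float,
    noise_sd: float = 0.5,
    delay: float = 1.0,
    rng: np.random.Generator | None = None,
    k: int = 4,
) -> HRSeries:
    """Per-second pulse-oximeter emulation.

    The displayed HR is the rolling-average HR ``delay`` seconds earlier,
    plus Gaussian measurement noise, rounded to an integer bpm as real
    finger oximeters display.
    """
    if noise_sd < 0 or delay < 0:
        raise ConfigurationError("noise_sd and delay must be >= 0")
    if rng is None:
        rng = np.random.default_rng(0)
    ecg = emulate_ecg_hr(beats, duration, k)
    seconds = ecg.t
    src = seconds - delay
    idx = np.searchsorted(seconds, src + 1e-9, side="right") - 1
    have = idx >= 0
    idx = np.clip(idx, 0, len(seconds) - 1)
    hr = ecg.hr[idx]
    quality = have & ecg.quality[idx] & np.isfinite(hr)
    if noise_sd:
        hr = hr + rng.normal(0.0, noise_sd, size=hr.shape)
    hr = np.where(np.isfinite(hr), np.round(hr), hr)
    return HRSeries(seconds, hr, quality)


@dataclass
class StudyDataset:
    """Everything the simulated study produced.

    ``per_minute`` is the long table (subject, condition, minute, device,
    hr_bpm, quality); ``subject_hr`` maps subject id to the drawn base HR;
    ``true_condition_hr`` maps (subject, condition) to the ground-truth
    mean HR of that recording.
    """

    config: StudyConfig
    per_minute: pd.DataFrame
    subject_hr: dict
    true_condition_hr: dict

    DEVICES = ("camera", "ecg", "oximeter")

    def paired_table(
        self, device_a: str, device_b: str, condition: str | None = None
    ) -> pd.DataFrame:
        """Quality-true per-minute pairs for one device pair, hr_a = criterion."""
        pm = self.per_minute[self.per_minute["quality"]]
        wide = pm.pivot_table(
            index=["subject", "condition", "minute"],
            columns="device",
            values="hr_bpm",
        ).reset_index()
        if condition is not None:
            wide = wide[wide["condition"] == condition]
        out = wide[["subject", "condition", "minute", device_a, device_b]].dropna()
        return out.rename(columns={device_a: "hr_a", device_b: "hr_b"})


def _round_displayed(hr: np.ndarray) -> np.ndarray:
    """Integer-display quantization, NaN-safe."""
    return np.where(np.isfinite(hr), np.round(hr), hr)


def _subject_condition_minutes(
    subject: int,
    condition: str,
    hr: float,
    cfg: StudyConfig,
    seeds,
) -> tuple[dict[str, HRSeries], float]:
    """Simulate one subject-condition recording; per-minute HR per device."""
    duration = cfg.minutes_per_condition * 60.0
    rng_beats, rng_render, rng_ox = (np.random.default_rng(s) for s in seeds)
    beat_cfg = BeatGenConfig(
        mean_hr=hr,
        hr_sd_between_subjects=cfg.hr_sd_between_subjects,
        rr_jitter_sd=cfg.rr_jitter_sd,
        modulation_amp=cfg.modulation_amp,
        modulation_period=cfg.modulation_period,
        duration=duration + 3.0,
    )
    beats = gen_beat_times(beat_cfg, rng_beats)

    meta = VideoMeta(
        width=cfg.width,
        height=cfg.height,
        fps=cfg.fps,
        n_frames=int(round(duration * cfg.fps)),
    )
    t_parts, v_parts, q_parts = [], [], []
    thresholds = QualityThresholds()
    for chunk in iter_render_chunks(beats, meta, cfg.render, rng_render):
        s = frames_to_series(chunk, "luma")
        t_parts.append(s.t)
        v_parts.append(s.v)
        q_parts.append(stream_quality_mask(chunk, thresholds))
    from .extract import SampleSeries

    series = SampleSeries(np.concatenate(t_parts), np.concatenate(v_parts), cfg.fps)
    mask = np.concatenate(q_parts)
    _, cam_sec, _, _ = analyze_series(
        series, mask, PulseParams(), k=4, duration=duration, n_minutes=None
    )
    ecg_sec = emulate_ecg_hr(beats, duration)
    ox_sec = emulate_oximeter_hr(
        beats, duration, cfg.oximeter_noise_sd, cfg.oximeter_delay, rng_ox
    )
    if cfg.display_rounding:
        # The study transcribed HRs shown on the devices' screens, and HR
        # displays show whole bpm; the oximeter emulator already rounds.
        cam_sec = HRSeries(cam_sec.t, _round_displayed(cam_sec.hr), cam_sec.quality)
        ecg_sec = HRSeries(ecg_sec.t, _round_displayed(ecg_sec.hr), ecg_sec.quality)
    cam_min = per_minute_mean(cam_sec, cfg.minutes_per_condition)
    ecg_min = per_minute_mean(ecg_sec, cfg.minutes_per_condition)
    ox_min = per_minute_mean(ox_sec, cfg.minutes_per_condition)

    # ground-truth mean HR over the recording (time-weighted by beats)
    in_window = beats.times <= duration
    n_b = int(in_window.sum())
    true_hr = 60.0 * (n_b - 1) / (beats.times[n_b - 1] - beats.times[0])
    return {"camera": cam_min, "ecg": ecg_min, "oximeter": ox_min}, true_hr


def simulate_study(config: StudyConfig = StudyConfig()) -> StudyDataset:
    """Run the whole simulated validation study.

    For every subject x condition the ground-truth beats drive (a) rendered
    nv21 frames pushed through the real extraction and pulse-detection
    pipeline ("camera"), (b) the error-free rolling-average criterion
    ("ecg") and (c) the noisy, delayed, integer-rounded oximeter
    ("oximeter").  Fully deterministic given ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    hr_rng = np.random.default_rng(ss.spawn(1)[0])
    subject_seeds = ss.spawn(config.n_subjects)

    rows = []
    subject_hr = {}
    true_hr_map = {}
    for s in range(1, config.n_subjects + 1):
        base = float(
            np.clip(
                hr_rng.normal(config.mean_hr, config.hr_sd_between_subjects),
                45.0,
                150.0,
            )
        )
        subject_hr[s] = base
        cond_seeds = subject_seeds[s - 1].spawn(len(config.conditions))
        for (cond, offset), cseed in zip(config.conditions, cond_seeds):
            per_device, true_hr = _subject_condition_minutes(
                s, cond, base + offset, config, cseed.spawn(3)
            )
            true_hr_map[(s, cond)] = true_hr
            for device, series in per_device.items():
                for m in range(config.minutes_per_condition):
                    rows.append(
                        {
                            "subject": s,
                            "condition": cond,
                            "minute": m + 1,
                            "device": device,
                            "hr_bpm": series.hr[m],
                            "quality": bool(series.quality[m]),
                        }
                    )
    per_minute = pd.DataFrame(rows)
    return StudyDataset(config, per_minute, subject_hr, true_hr_map)
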