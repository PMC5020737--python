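"""Stimulus-timing validation: audio-onset latency statistics and
rotation-period estimation.

Two in-silico counterparts of the hardware checks used to qualify web-based
stimulus delivery:

* **Audio**: synthesize the validation sequence (1 kHz tone for 200 ms
  followed by 800 ms of silence, repeated) with a known injected per-onset
  latency law, detect tone onsets/offsets in the waveform, and summarize the
  timing errors against the nominal schedule as a mean and SD.
* **Rotation period**: from a frame-by-frame series of (timestamp, dot
  angle) samples — emulating a 1000 FPS high-speed capture where each frame
  is one millisecond — estimate the rotation period by unwrapping the angle
  and fitting a line.

Onset detection operates on the rectified waveform: samples above a
threshold (default 10% of the global peak) are grouped into bursts by
closing sub-burst gaps, threshold crossings are located by linear
interpolation, and each edge is corrected by the carrier phase lag
``asin(threshold/amplitude) / (2*pi*f)``.  The correction assumes each burst
starts and ends at a carrier zero crossing — exactly true for procedurally
generated tones (an oscillator starts at zero phase, and 200 ms of 1 kHz is
an integer number of cycles) — and makes onset and duration estimates
accurate to a small fraction of a sample period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.io import wavfile

__all__ = [
    "ToneSchedule",
    "OnsetReport",
    "FrameSeries",
    "PeriodEstimationError",
    "synthesize_sequence",
    "detect_onsets",
    "estimate_period",
    "simulate_frame_capture",
    "write_wav",
    "read_wav",
]


class PeriodEstimationError(ValueError):
    """The frame series does not describe a forward-rotating dot."""


@dataclass
class ToneSchedule:
    """Nominal validation sequence: tone bursts separated by silence."""

    frequency_hz: float = 1000.0
    tone_ms: float = 200.0
    silence_ms: float = 800.0
    repetitions: int = 5
    sample_rate_hz: float = 44100.0

    def __post_init__(self):
        for name in ("frequency_hz", "tone_ms", "silence_ms", "sample_rate_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.repetitions < 0:
            raise ValueError("repetitions must be non-negative")

    @property
    def period_ms(self) -> float:
        return self.tone_ms + self.silence_ms

    def nominal_onsets_ms(self, start_offset_ms: float = 0.0) -> np.ndarray:
        return start_offset_ms + np.arange(self.repetitions) * self.period_ms


@dataclass
class OnsetReport:
    """Detected tone onsets and their deviation from the nominal schedule."""

    onsets_ms: np.ndarray
    durations_ms: np.ndarray
    errors_ms: np.ndarray
    mean_error_ms: float
    sd_error_ms: float

    @property
    def n_onsets(self) -> int:
        return len(self.onsets_ms)


@dataclass
class FrameSeries:
    """High-speed-capture analogue: (timestamp, dot angle) per frame."""

    timestamps_ms: np.ndarray
    angles_deg: np.ndarray
    frame_interval_ms: float = 1.0

    def __post_init__(self):
        self.timestamps_ms = np.asarray(self.timestamps_ms, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.timestamps_ms.shape != self.angles_deg.shape:
            raise ValueError("timestamps and angles must have equal length")
        if len(self.timestamps_ms) >= 2 and np.any(np.diff(self.timestamps_ms) <= 0):
            raise ValueError("timestamps must be strictly increasing")


def synthesize_sequence(schedule: ToneSchedule,
                        latency_mean_ms: float = 0.0,
                        latency_sd_ms: float = 0.0,
                        seed=None,
                        pad_ms: float = 0.0) -> np.ndarray:
    """Render the validation sequence with a per-onset injected latency.

    Each burst k is a unit-amplitude sine starting at ``pad_ms + k*period +
    latency_k`` where latency_k is constant (``latency_sd_ms=0``) or
    Gaussian.  ``pad_ms`` adds leading silence so negative latencies stay
    inside the waveform.  Zero repetitions yield an empty waveform.
    """
    sr = schedule.sample_rate_hz
    if schedule.repetitions == 0:
        return np.zeros(0)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    latencies = latency_mean_ms + (latency_sd_ms * rng.standard_normal(schedule.repetitions)
                                   if latency_sd_ms > 0 else np.zeros(schedule.repetitions))
    total_ms = pad_ms + schedule.repetitions * schedule.period_ms
    n = int(round(total_ms / 1000.0 * sr))
    x = np.zeros(n)
    for k in range(schedule.repetitions):
        onset = pad_ms + k * schedule.period_ms + latencies[k]
        # first sample with t >= onset .. last sample with t < onset+tone
        lo = max(0, int(math.ceil(onset / 1000.0 * sr - 1e-9)))
        hi = min(n, int(math.ceil((onset + schedule.tone_ms) / 1000.0 * sr - 1e-9)))
        if hi <= lo:
            continue
        t_ms = np.arange(lo, hi) / sr * 1000.0
        x[lo:hi] = np.sin(2.0 * math.pi * schedule.frequency_hz * (t_ms - onset) / 1000.0)
    peak = np.abs(x).max()
    if peak > 0:
        x = x / peak
    return x


def _edge_correction(x: np.ndarray, ax: np.ndarray, s: int, e: int,
                     thr: float, sr: float) -> float:
    """Carrier phase lag (samples) between zero crossing and threshold crossing."""
    seg = x[s:e + 1]
    zc = int(np.count_nonzero(np.signbit(seg[:-1]) != np.signbit(seg[1:])))
    dur_s = (e - s) / sr
    if zc == 0 or dur_s <= 0:
        return 0.0
    f_est = zc / (2.0 * dur_s)
    amp = float(ax[s:e + 1].max())
    return math.asin(min(thr / amp, 1.0)) / (2.0 * math.pi * f_est) * sr


def detect_onsets(waveform: np.ndarray, sample_rate: float,
                  threshold_fraction: float = 0.1,
                  schedule: Optional[ToneSchedule] = None,
                  start_offset_ms: float = 0.0,
                  min_gap_ms: float = 10.0) -> OnsetReport:
    """Locate tone bursts and summarize their timing against the schedule.

    Pure silence (no samples above threshold) yields an empty report.  When
    ``schedule`` is given, each detected onset in order is compared with the
    nominal onset ``start_offset_ms + k*period``; the mean and SD of those
    errors are the summary statistics of the validation procedure.
    """
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    x = np.asarray(waveform, dtype=float)
    ax = np.abs(x)
    empty = OnsetReport(np.zeros(0), np.zeros(0), np.zeros(0), math.nan, math.nan)
    if x.size == 0 or ax.max() == 0:
        return empty
    thr = threshold_fraction * float(ax.max())
    idx = np.flatnonzero(ax >= thr)
    if idx.size == 0:
        return empty

    gap = max(1, int(min_gap_ms / 1000.0 * sample_rate))
    splits = np.flatnonzero(np.diff(idx) > gap)
    starts = np.r_[idx[0], idx[splits + 1]]
    ends = np.r_[idx[splits], idx[-1]]

    onsets, offsets = [], []
    for s, e in zip(starts, ends):
        if s > 0 and ax[s] > ax[s - 1]:
            t_on = (s - 1) + (thr - ax[s - 1]) / (ax[s] - ax[s - 1])
        else:
            t_on = float(s)
        if e + 1 < ax.size and ax[e] > ax[e + 1]:
            t_off = e + (ax[e] - thr) / (ax[e] - ax[e + 1])
        else:
            t_off = float(e)
        delta = _edge_correction(x, ax, int(s), int(e), thr, sample_rate)
        onsets.append((t_on - delta) / sample_rate * 1000.0)
        offsets.append((t_off + delta) / sample_rate * 1000.0)

    onsets = np.array(onsets)
    offsets = np.array(offsets)
    durations = offsets - onsets
    if schedule is not None:
        nominal = schedule.nominal_onsets_ms(start_offset_ms)
        k = min(len(onsets), len(nominal))
        errors = onsets[:k] - nominal[:k]
    else:
        errors = np.zeros(0)
    mean_err = float(np.mean(errors)) if errors.size else math.nan
    sd_err = float(np.std(errors, ddof=1)) if errors.size > 1 else math.nan
    return OnsetReport(onsets_ms=onsets, durations_ms=durations, errors_ms=errors,
                       mean_error_ms=mean_err, sd_error_ms=sd_err)


def estimate_period(series: FrameSeries) -> float:
    """Rotation period (ms) from a frame series by unwrap-and-fit.

    Unwraps the angle across 360-degree boundaries (assumes < 180 degrees of
    motion between consecutive frames, guaranteed at millisecond sampling of
    a multi-second rotation), fits ``angle = slope*t + intercept`` by least
    squares, and returns ``360/slope``.  A non-positive slope — the dot not
    rotating forward — is an estimation error.
    """
    t = series.timestamps_ms
    if len(t) < 3:
        raise PeriodEstimationError("need at least 3 frame samples")
    unwrapped = np.unwrap(series.angles_deg, period=360.0)
    if unwrapped[-1] - unwrapped[0] <= 180.0:
        raise PeriodEstimationError("series spans half a rotation or less")
    slope, _ = np.polyfit(t, unwrapped, 1)
    if slope <= 0:
        raise PeriodEstimationError(f"non-positive angular velocity ({slope} deg/ms)")
    return 360.0 / float(slope)


def simulate_frame_capture(cycle_ms: float, duration_ms: float,
                           frame_interval_ms: float = 1.0,
                           angle_noise_deg: float = 0.0,
                           angle_origin_deg: float = 0.0,
                           seed=None) -> FrameSeries:
    """Noiseless-or-noisy frame series of a constant-speed rotating dot.

    Emulates a 1000 FPS capture at the default 1 ms frame interval; optional
    uniform angle noise (+- ``angle_noise_deg``) models frame-labelling
    error.
    """
    if cycle_ms <= 0:
        raise ValueError("cycle_ms must be positive")
    t = np.arange(0.0, duration_ms, frame_interval_ms)
    angles = np.mod(angle_origin_deg + t / cycle_ms * 360.0, 360.0)
    if angle_noise_deg > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        angles = np.mod(angles + rng.uniform(-angle_noise_deg, angle_noise_deg, t.size), 360.0)
    return FrameSeries(timestamps_ms=t, angles_deg=angles,
                       frame_interval_ms=frame_interval_ms)


def write_wav(path, waveform: np.ndarray, sample_rate: float) -> None:
    """Write a waveform as 32-bit float WAV."""
    wavfile.write(path, int(sample_rate), np.asarray(waveform, dtype=np.float32))


def read_wav(path) -> tuple[np.ndarray, float]:
    """Read a WAV file, returning (float waveform, sample rate)."""
    sr, data = wavfile.read(path)
    data = np.asarray(data)
    if data.dtype.kind == "i":
        data = data / float(np.iinfo(data.dtype).max)
    return data.astype(float), float(sr)
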