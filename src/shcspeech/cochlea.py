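"""Cochlear front end: sound waves to reduced 6-channel firing rates.

A passive cochlear filterbank in the style of Lyon's classical model: a
cascade of second-order resonant low-pass stages whose center
frequencies march from the Nyquist frequency downwards, each stage
tapped to give one output channel (channel 1 = highest frequency).  Tap
outputs are half-wave rectified, compressed by an automatic gain control
and decimated, giving a cochleagram of simulated auditory-nerve firing
rates normalized to [0, 1].

For the hierarchical model the 86-channel cochleagram (16 kHz, default
design) is reduced to 6 channels by block-averaging 14 channels each
(discarding the last two) and each channel is resampled to 100 model
time units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal
from scipy.io import wavfile

from .gridio import save_grid, load_grid

__all__ = [
    "Waveform",
    "Cochleagram",
    "ReducedStimulus",
    "CochlearParams",
    "Filterbank",
    "design_filterbank",
    "cochleagram",
    "reduce_channels",
    "rescale_time",
    "denoise",
    "time_compress",
    "read_wav",
]

STANDARD_RATE = 16000
MIN_RATE, MAX_RATE = 8000, 48000
REDUCED_CHANNELS = 6
BLOCK = 14
MODEL_SAMPLES = 100


@dataclass
class Waveform:
    """Mono audio: dimensionless amplitude samples at a given rate."""

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


@dataclass
class Cochleagram:
    """Channels x frames firing-rate grid; channel 1 = highest frequency."""

    values: np.ndarray
    frame_rate: float
    center_freqs: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("cochleagram must be 2-D (channels x frames)")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def duration(self) -> float:
        return self.values.shape[1] / self.frame_rate

    def save_csv(self, path) -> None:
        save_grid(path, self.values, {"frame_rate": self.frame_rate})

    @classmethod
    def load_csv(cls, path) -> "Cochleagram":
        values, meta = load_grid(path)
        return cls(values=values, frame_rate=float(meta.get("frame_rate", 1.0)))


@dataclass
class ReducedStimulus:
    """The 6 x 100 model input z(t); original duration kept as metadata."""

    values: np.ndarray
    source_duration: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("reduced stimulus must be 2-D")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def T(self) -> int:
        return self.values.shape[1]

    def save_csv(self, path) -> None:
        meta = {}
        if self.source_duration is not None:
            meta["source_duration"] = self.source_duration
        save_grid(path, self.values, meta)

    @classmethod
    def load_csv(cls, path) -> "ReducedStimulus":
        values, meta = load_grid(path)
        return cls(values=values, source_duration=meta.get("source_duration"))


@dataclass
class CochlearParams:
    """Design settings of the passive filterbank (documented defaults).

    ear_q sets filter bandwidth (BW = sqrt(f^2 + break_freq^2)/ear_q),
    step_factor the spacing between stage center frequencies in units of
    the local bandwidth, decimation the output frame step in samples.
    """

    ear_q: float = 8.0
    step_factor: float = 0.25
    break_freq: float = 1000.0
    zero_offset: float = 1.5
    stage_q: float = 0.9
    decimation: int = 64
    agc: bool = True
    agc_target: float = 0.05
    agc_tau: float = 0.02  # seconds


@dataclass
class Filterbank:
    """Ordered cascade of second-order stages, high to low frequency.

    Each channel taps the cascade after its stage through a second-order
    resonator at the stage center frequency (the band-emphasis the full
    model realizes with per-stage zeros), normalized to unit gain at the
    center frequency.
    """

    rate: float
    center_freqs: np.ndarray
    sos: np.ndarray  # (n_channels, 6) cascade stages
    tap_sos: np.ndarray  # (n_channels, 6) band-emphasis resonators
    tap_gain: np.ndarray  # per-channel normalization at the tap CF
    params: CochlearParams = field(default_factory=CochlearParams)

    @property
    def n_channels(self) -> int:
        return len(self.center_freqs)


def _bandwidth(f: np.ndarray, p: CochlearParams) -> np.ndarray:
    return np.sqrt(f**2 + p.break_freq**2) / p.ear_q


def design_filterbank(rate: float, params: Optional[CochlearParams] = None) -> Filterbank:
    """Design the cascade for a sampling rate in [8, 48] kHz.

    Stage center frequencies start just below Nyquist and march downward
    in steps of ``step_factor`` local bandwidths, stopping when the step
    would overshoot zero (cf <= step * BW(cf)).  At 16 kHz with default
    parameters this yields 86 channels (~7.6 kHz down to ~40 Hz).
    Deterministic: identical inputs give identical coefficients.
    """
    p = params or CochlearParams()
    if not (MIN_RATE <= rate <= MAX_RATE):
        raise ValueError(
            f"sampling rate {rate} outside supported range "
            f"[{MIN_RATE}, {MAX_RATE}] Hz"
        )
    cfs = []
    cf = rate / 2 - p.zero_offset * p.step_factor * _bandwidth(np.array(rate / 2), p)
    while cf > p.step_factor * _bandwidth(np.array(cf), p):
        cfs.append(float(cf))
        cf = cf - p.step_factor * _bandwidth(np.array(cf), p)
    cfs = np.asarray(cfs)

    sos = np.empty((len(cfs), 6))
    tap_sos = np.empty((len(cfs), 6))
    for i, f in enumerate(cfs):
        # prewarped analog frequency so the bilinear transform lands the
        # resonance at f even near Nyquist
        w = 2 * rate * np.tan(np.pi * f / rate)
        b, a = signal.bilinear([w**2], [1.0, w / p.stage_q, w**2], fs=rate)
        sos[i] = np.concatenate([b, a])
        q_local = max(f / float(_bandwidth(np.array(f), p)), 0.3)
        bt, at = signal.iirpeak(f, q_local, fs=rate)
        tap_sos[i] = np.concatenate([bt, at])

    # per-tap gain: normalize the cascade response at each tap's CF to 1
    # (the resonator itself has unit gain at its center frequency)
    tap_gain = np.empty(len(cfs))
    acc = np.ones(len(cfs), dtype=complex)
    zexp = np.exp(-1j * 2 * np.pi * cfs / rate)
    for i in range(len(cfs)):
        b, a = sos[i, :3], sos[i, 3:]
        resp = np.polyval(b[::-1], 1 / zexp) / np.polyval(a[::-1], 1 / zexp)
        acc = acc * resp
        tap_gain[i] = 1.0 / max(abs(acc[i]), 1e-12)
    return Filterbank(
        rate=rate,
        center_freqs=cfs,
        sos=sos,
        tap_sos=tap_sos,
        tap_gain=tap_gain,
        params=p,
    )


def _agc(x: np.ndarray, p: CochlearParams, rate: float) -> np.ndarray:
    """Divisive automatic gain control with a smoothed envelope."""
    alpha = 1.0 / max(p.agc_tau * rate, 1.0)
    env = signal.lfilter([alpha], [1.0, -(1.0 - alpha)], x, axis=-1)
    return x / (1.0 + env / p.agc_target)


def cochleagram(w: Waveform, params: Optional[CochlearParams] = None) -> Cochleagram:
    """Filter cascade + half-wave rectification + AGC + decimation.

    Input at rates other than 16 kHz is resampled to 16 kHz first so the
    channel count is pinned to the 86-channel default design.  The
    output is normalized by its global maximum and clipped to [0, 1]; an
    all-zero (silent) input yields a valid all-zero cochleagram.
    """
    p = params or CochlearParams()
    if len(w.samples) == 0:
        raise ValueError("empty waveform")
    x = w.samples
    if w.rate != STANDARD_RATE:
        if not (MIN_RATE <= w.rate <= MAX_RATE):
            raise ValueError(
                f"sampling rate {w.rate} outside supported range "
                f"[{MIN_RATE}, {MAX_RATE}] Hz"
            )
        n_out = int(round(len(x) * STANDARD_RATE / w.rate))
        x = signal.resample_poly(x, STANDARD_RATE, int(w.rate), padtype="line")[
            : max(n_out, 1)
        ]
    fb = design_filterbank(STANDARD_RATE, p)
    rows = []
    stage_in = x
    for i in range(fb.n_channels):
        stage_in = signal.sosfilt(fb.sos[i][None, :], stage_in)
        tap = signal.sosfilt(fb.tap_sos[i][None, :], stage_in)
        rows.append(fb.tap_gain[i] * tap)
    out = np.maximum(np.asarray(rows), 0.0)  # half-wave rectification
    if p.agc:
        out = _agc(out, p, STANDARD_RATE)
    # smoothed decimation: moving average over one decimation window
    frames = out.shape[1] // p.decimation
    if frames == 0:
        frames = 1
        pad = p.decimation - out.shape[1]
        out = np.pad(out, ((0, 0), (0, pad)))
    out = out[:, : frames * p.decimation].reshape(out.shape[0], frames, p.decimation)
    out = out.mean(axis=2)
    peak = out.max()
    if peak > 0:
        out = out / peak
    out = np.clip(out, 0.0, 1.0)
    return Cochleagram(
        values=out,
        frame_rate=STANDARD_RATE / p.decimation,
        center_freqs=fb.center_freqs,
    )


def reduce_channels(c: Cochleagram) -> np.ndarray:
    """Average 14-channel blocks into 6 channels; drop trailing channels."""
    needed = BLOCK * REDUCED_CHANNELS
    if c.n_channels < needed:
        raise ValueError(
            f"need at least {needed} channels to reduce, got {c.n_channels}"
        )
    blocks = c.values[:needed].reshape(REDUCED_CHANNELS, BLOCK, -1)
    return blocks.mean(axis=1)


def rescale_time(
    g: np.ndarray,
    T_target: int = MODEL_SAMPLES,
    source_duration: Optional[float] = None,
) -> ReducedStimulus:
    """Resample each channel to T_target samples by linear interpolation."""
    g = np.asarray(g, dtype=float)
    if g.ndim != 2 or g.shape[1] < 2:
        raise ValueError("grid must be 2-D with at least 2 frames")
    src = np.linspace(0.0, 1.0, g.shape[1])
    dst = np.linspace(0.0, 1.0, T_target)
    out = np.vstack([np.interp(dst, src, row) for row in g])
    out = np.clip(out, 0.0, 1.0)
    return ReducedStimulus(values=out, source_duration=source_duration)


def denoise(c, floor_quantile: float):
    """Per-channel quantile floor: values below the threshold go to zero.

    Idempotent (zeroed entries only lower the quantile threshold);
    floor_quantile 0 is the identity.  Accepts a Cochleagram, a
    ReducedStimulus or a bare array and returns the same type.
    """
    if not (0 <= floor_quantile < 1):
        raise ValueError("floor_quantile must lie in [0, 1)")
    values = np.asarray(getattr(c, "values", c), dtype=float).copy()
    if floor_quantile > 0:
        thresh = np.quantile(values, floor_quantile, axis=1, keepdims=True)
        values[values < thresh] = 0.0
    return _same_type(c, values)


def time_compress(c, factor: float):
    """Resample the frame axis to factor x original length (pitch fixed).

    Only the time axis changes; the spectral (channel) axis is untouched,
    so compression cannot change pitch by construction.
    """
    if not (0 < factor <= 1):
        raise ValueError("compression factor must lie in (0, 1]")
    values = np.asarray(getattr(c, "values", c), dtype=float)
    frames = values.shape[1]
    new_frames = max(int(round(frames * factor)), 2)
    if new_frames == frames:
        return _same_type(c, values.copy())
    src = np.linspace(0.0, 1.0, frames)
    dst = np.linspace(0.0, 1.0, new_frames)
    out = np.vstack([np.interp(dst, src, row) for row in values])
    return _same_type(c, out)


def _same_type(c, values: np.ndarray):
    if isinstance(c, Cochleagram):
        return Cochleagram(
            values=values, frame_rate=c.frame_rate, center_freqs=c.center_freqs
        )
    if isinstance(c, ReducedStimulus):
        return ReducedStimulus(values=values, source_duration=c.source_duration)
    return values


def read_wav(path) -> Waveform:
    """Read a mono WAV file (PCM 16/24/32-bit or float)."""
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        raise ValueError(
            f"{path}: expected mono audio, got {data.shape[1]} channels"
        )
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    return Waveform(samples=data, rate=float(rate))
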