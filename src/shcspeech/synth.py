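"""Seeded generator of word-like stimuli and experimental manipulations.

Emulates the structure of isolated-word corpora (digits spoken by
several speakers) without external data: each word class is a sequence
of 8 spectral segments over 6 channels with values in [0, 1]; speakers
impose multiplicative spectral tilt and rate variation; tokens jitter
segment boundaries.  Additional manipulations cover additive noise at a
target SNR, linear mixtures of concurrent "speakers", time compression
(see :mod:`shcspeech.cochlea`) and accent-like perturbations of the
spectral profiles.

The defaults mirror a 10-word x 5-speaker x 10-token layout (500
stimuli).  Every stimulus is a valid 6 x 100 ReducedStimulus and is
fully reproducible from the seeds recorded in the dataset manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .cochlea import ReducedStimulus, Waveform, rescale_time, MODEL_SAMPLES

__all__ = [
    "SyntheticWordSpec",
    "SpeakerProfile",
    "DatasetSpec",
    "Token",
    "make_class_specs",
    "make_speakers",
    "make_word",
    "make_waveform",
    "add_noise",
    "mix_speakers",
    "accent_perturb",
    "make_dataset",
]

N_SEGMENTS = 8
N_CHANNELS = 6

# Frequency bands (Hz) assigned to the 6 reduced channels when rendering
# a waveform realization: median center frequencies of the 14-channel
# blocks of the default 86-channel filterbank, high to low.
BAND_CENTERS = (6188.0, 3931.0, 2464.0, 1492.0, 819.0, 311.0)


@dataclass
class SyntheticWordSpec:
    """One word class: segment profiles over 6 channels in [0, 1].

    Words have 8 segments (aligned with the default N = 8 sequencer);
    longer sequences (e.g. 16-segment "sentences" for cocktail-party
    runs) are allowed and pair with a matching N.
    """

    label: str
    segment_profiles: np.ndarray  # n_segments x N_CHANNELS
    boundary_jitter: float = 0.1  # fraction of a segment length
    smoothness: float = 1.5  # first-order smoothing time constant, model units

    def __post_init__(self) -> None:
        self.segment_profiles = np.asarray(self.segment_profiles, dtype=float)
        if (
            self.segment_profiles.ndim != 2
            or self.segment_profiles.shape[0] < 2
            or self.segment_profiles.shape[1] != N_CHANNELS
        ):
            raise ValueError(
                f"segment profiles must be n_segments x {N_CHANNELS} "
                "with at least 2 segments"
            )
        if np.any(self.segment_profiles < 0) or np.any(self.segment_profiles > 1):
            raise ValueError("segment profiles must lie in [0, 1]")
        if not (0 <= self.boundary_jitter < 0.5):
            raise ValueError("boundary jitter must lie in [0, 0.5)")

    @property
    def n_segments(self) -> int:
        return self.segment_profiles.shape[0]


@dataclass
class SpeakerProfile:
    """Speaker variability: spectral tilt, speaking rate, jitter stream."""

    tilt: np.ndarray  # per-channel multiplicative gain
    rate_factor: float = 1.0
    jitter_seed: int = 0

    def __post_init__(self) -> None:
        self.tilt = np.asarray(self.tilt, dtype=float)
        if self.tilt.shape != (N_CHANNELS,):
            raise ValueError(f"tilt must have {N_CHANNELS} entries")
        if np.any(self.tilt < 0.5) or np.any(self.tilt > 1.5):
            raise ValueError("tilt gains must lie in [0.5, 1.5]")
        if not (0.75 <= self.rate_factor <= 1.25):
            raise ValueError("rate factor must lie in [0.75, 1.25]")

    @classmethod
    def neutral(cls) -> "SpeakerProfile":
        return cls(tilt=np.ones(N_CHANNELS))


@dataclass
class DatasetSpec:
    """Layout of a synthetic word corpus (defaults: 500 stimuli)."""

    n_classes: int = 10
    n_speakers: int = 5
    tokens_per_speaker: int = 10
    master_seed: int = 0


@dataclass
class Token:
    """One labeled stimulus of a dataset."""

    label: str
    class_index: int
    speaker: int
    token: int
    seed: int
    stimulus: ReducedStimulus


def make_class_specs(
    n_classes: int,
    seed: int = 0,
    min_distance: float = 0.25,
    max_tries: int = 2000,
) -> list:
    """Draw well-separated class profiles from a seeded uniform law.

    Candidate 8 x 6 profiles are drawn from U(0.05, 0.95) and accepted
    only if their mean absolute distance to every accepted class exceeds
    ``min_distance``, guaranteeing a learnable task without hand-designed
    phonetics.
    """
    rng = np.random.default_rng(seed)
    specs: list[SyntheticWordSpec] = []
    tries = 0
    while len(specs) < n_classes:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                "could not draw sufficiently separated class profiles; "
                "lower min_distance or n_classes"
            )
        cand = rng.uniform(0.05, 0.95, size=(N_SEGMENTS, N_CHANNELS))
        if all(
            np.mean(np.abs(cand - s.segment_profiles)) > min_distance
            for s in specs
        ):
            specs.append(
                SyntheticWordSpec(label=str(len(specs)), segment_profiles=cand)
            )
    return specs


def make_speakers(n_speakers: int, seed: int = 0) -> list:
    """Draw speaker tilt/rate profiles from a seeded uniform law."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_speakers):
        tilt = rng.uniform(0.8, 1.2, size=N_CHANNELS)
        rate = rng.uniform(0.85, 1.15)
        out.append(
            SpeakerProfile(tilt=tilt, rate_factor=rate, jitter_seed=int(rng.integers(2**31)))
        )
    return out


def _segment_trace(spec: SyntheticWordSpec, length: int, rng) -> np.ndarray:
    """Piecewise-constant profile trace with jittered boundaries."""
    n_seg = spec.n_segments
    seg_len = length / n_seg
    bounds = [0.0]
    for s in range(1, n_seg):
        jitter = rng.uniform(-1, 1) * spec.boundary_jitter * seg_len
        bounds.append(np.clip(s * seg_len + jitter, bounds[-1] + 1, length - 1))
    bounds.append(float(length))
    trace = np.empty((N_CHANNELS, length))
    for s in range(n_seg):
        i0, i1 = int(round(bounds[s])), int(round(bounds[s + 1]))
        trace[:, i0:i1] = spec.segment_profiles[s][:, None]
    return trace


def _smooth(trace: np.ndarray, tau: float) -> np.ndarray:
    """Causal first-order (exponential) smoothing along time."""
    if tau <= 0:
        return trace
    alpha = 1.0 / (1.0 + tau)
    out = np.empty_like(trace)
    acc = trace[:, 0]
    for t in range(trace.shape[1]):
        acc = acc + alpha * (trace[:, t] - acc)
        out[:, t] = acc
    return out


def make_word(
    spec: SyntheticWordSpec,
    speaker: Optional[SpeakerProfile] = None,
    token_seed: int = 0,
) -> ReducedStimulus:
    """Render one token of a word class as a 6 x 100 reduced stimulus.

    The 8-segment profile is laid out over ``100 * rate_factor`` samples
    with jittered boundaries, smoothed by a first-order filter, scaled
    by the speaker tilt, clipped to [0, 1] and resampled to 100 samples.
    Identical seeds give identical stimuli.
    """
    speaker = speaker or SpeakerProfile.neutral()
    rng = np.random.default_rng((token_seed, speaker.jitter_seed))
    length = int(round(MODEL_SAMPLES * speaker.rate_factor))
    trace = _segment_trace(spec, length, rng)
    trace = _smooth(trace, spec.smoothness)
    trace = trace * speaker.tilt[:, None]
    trace = np.clip(trace, 0.0, 1.0)
    z = rescale_time(trace, MODEL_SAMPLES, source_duration=length / MODEL_SAMPLES)
    return z


def make_waveform(
    spec: SyntheticWordSpec,
    speaker: Optional[SpeakerProfile] = None,
    token_seed: int = 0,
    rate: int = 16000,
    duration: float = 0.5,
) -> Waveform:
    """Waveform realization: band-centered tones, amplitude-modulated.

    Each reduced channel contributes a tone at its band center whose
    envelope follows the channel's profile trace, so the cochlear module
    can be exercised end-to-end on synthetic words.
    """
    z = make_word(spec, speaker, token_seed)
    n_samp = int(rate * duration)
    t = np.arange(n_samp) / rate
    env_t = np.linspace(0, 1, n_samp)
    src = np.linspace(0, 1, MODEL_SAMPLES)
    x = np.zeros(n_samp)
    for ch in range(N_CHANNELS):
        env = np.interp(env_t, src, z.values[ch])
        x += env * np.sin(2 * np.pi * BAND_CENTERS[ch] * t)
    x /= N_CHANNELS
    return Waveform(samples=x, rate=float(rate))


def add_noise(z: ReducedStimulus, snr_db: float, seed: int = 0) -> ReducedStimulus:
    """Additive Gaussian channel noise at a target signal-to-noise ratio.

    Noise power is scaled so 10 log10(P_signal / P_noise) = snr_db
    before the final clipping to [0, 1].  ``snr_db = inf`` is the
    identity; an all-zero signal has no defined SNR and raises.
    """
    if not np.isfinite(snr_db):
        if snr_db > 0:
            return ReducedStimulus(
                values=z.values.copy(), source_duration=z.source_duration
            )
        raise ValueError("snr_db must be finite or +inf")
    p_sig = float(np.mean(z.values**2))
    if p_sig == 0:
        raise ValueError("SNR undefined for an all-zero signal")
    sd = np.sqrt(p_sig / 10 ** (snr_db / 10))
    rng = np.random.default_rng(seed)
    noisy = z.values + sd * rng.standard_normal(z.values.shape)
    return ReducedStimulus(
        values=np.clip(noisy, 0.0, 1.0), source_duration=z.source_duration
    )


def mix_speakers(
    target: ReducedStimulus,
    distractors,
    gains=None,
) -> ReducedStimulus:
    """Linear mixture of a target with concurrent-speaker distractors.

    Default distractor gain 0.5 corresponds to sources twice as far from
    the listener (inverse-distance loudness).  Result is clipped to
    [0, 1].
    """
    out = target.values.copy()
    distractors = list(distractors)
    if gains is None:
        gains = [0.5] * len(distractors)
    if len(gains) != len(distractors):
        raise ValueError("one gain per distractor required")
    for d, g in zip(distractors, gains):
        dv = getattr(d, "values", d)
        if dv.shape != out.shape:
            raise ValueError(f"distractor shape {dv.shape} != target {out.shape}")
        out = out + g * dv
    return ReducedStimulus(
        values=np.clip(out, 0.0, 1.0), source_duration=target.source_duration
    )


def accent_perturb(
    spec: SyntheticWordSpec, magnitude: float, seed: int = 0
) -> SyntheticWordSpec:
    """Accent-like variant: smooth random offsets of the segment profiles.

    Offsets are drawn per segment/channel, smoothed across neighboring
    segments and rescaled so their largest absolute value equals
    ``magnitude``; the label (word identity) is preserved.
    """
    if not (0 <= magnitude <= 0.5):
        raise ValueError("accent magnitude must lie in [0, 0.5]")
    if magnitude == 0:
        return replace(spec, segment_profiles=spec.segment_profiles.copy())
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((spec.n_segments, N_CHANNELS))
    kernel = np.array([0.25, 0.5, 0.25])
    smooth = np.empty_like(raw)
    for c in range(N_CHANNELS):
        smooth[:, c] = np.convolve(raw[:, c], kernel, mode="same")
    smooth *= magnitude / np.max(np.abs(smooth))
    perturbed = np.clip(spec.segment_profiles + smooth, 0.0, 1.0)
    return replace(spec, segment_profiles=perturbed)


def make_dataset(ds: DatasetSpec):
    """Generate the full labeled corpus plus a manifest.

    Returns ``(tokens, manifest)`` where ``tokens`` is a list of
    :class:`Token` and ``manifest`` a list of dict rows (token id, label,
    speaker, seed) suitable for CSV export.  Fully determined by the
    master seed.
    """
    specs = make_class_specs(ds.n_classes, seed=ds.master_seed)
    speakers = make_speakers(ds.n_speakers, seed=ds.master_seed + 1)
    rng = np.random.default_rng(ds.master_seed + 2)
    tokens, manifest = [], []
    for ci, spec in enumerate(specs):
        for si, spk in enumerate(speakers):
            for ti in range(ds.tokens_per_speaker):
                seed = int(rng.integers(2**31))
                z = make_word(spec, spk, token_seed=seed)
                tokens.append(
                    Token(
                        label=spec.label,
                        class_index=ci,
                        speaker=si,
                        token=ti,
                        seed=seed,
                        stimulus=z,
                    )
                )
                manifest.append(
                    {
                        "token_id": len(tokens) - 1,
                        "label": spec.label,
                        "speaker": si,
                        "token": ti,
                        "seed": seed,
                    }
                )
    return tokens, manifest
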