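"""Synthetic EEG with a known interictal/preictal structure.

Real seizure-prediction corpora are either access-restricted or too large to
ship with a test suite, so every downstream stage of the pipeline is exercised
on simulated recordings with a *known* preictal signature: 1/f background
noise plus a per-channel alpha-band oscillator, and, in a configurable window
before each annotated onset, extra band-limited power in a chosen frequency
band that ramps linearly up to a chosen multiplicative effect size.

Two data regimes are emulated:

* a continuous annotated recording (:class:`Recording`), mirroring long-term
  monitoring data where seizure onset times are known; and
* a shuffled set of fixed-duration labeled clips (:class:`SegmentedDataset`),
  mirroring competition-style releases in which files are labeled
  interictal/preictal, grouped by seizure, and carry no absolute timestamps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .exceptions import ConfigurationError, DataError

#: Named frequency bands (Hz). The four gamma sub-bands leave gaps at the
#: 50 and 100 Hz mains harmonics; ``gamma_broad`` is their composite.
NAMED_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma1": (30.0, 47.0),
    "gamma2": (53.0, 75.0),
    "gamma3": (75.0, 97.0),
    "gamma4": (103.0, 128.0),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic patient.

    Parameters
    ----------
    duration:
        Total recording length in seconds.
    seizure_onsets:
        Strictly increasing onset times in seconds, separated by at least
        ``min_seizure_gap`` (independent-seizure rule; clinically 4.5 h, kept
        configurable for desk-scale experiments).
    preictal_duration:
        True length in seconds of the injected preictal signature before each
        onset.
    effect_band, effect_size:
        Band whose power is multiplied and the multiplicative factor reached
        at onset (the multiplier ramps linearly from 1 at the start of the
        preictal window). ``effect_size=1`` yields a null patient whose
        preictal and interictal windows share the same generating
        distribution.
    noise_exponent:
        Slope of the 1/f background noise spectrum.
    noise_scale, oscillator_amplitude:
        Standard deviation of the background noise and amplitude of the
        per-channel alpha oscillator, in microvolts.
    """

    duration: float
    seizure_onsets: tuple[float, ...]
    n_channels: int = 2
    fs: float = 256.0
    min_seizure_gap: float = 3600.0
    preictal_duration: float = 2400.0
    effect_band: str = "alpha"
    effect_size: float = 1.0
    noise_exponent: float = 1.0
    noise_scale: float = 10.0
    oscillator_amplitude: float = 8.0
    seizure_length: float = 30.0
    ictal_blackout: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "seizure_onsets", tuple(float(t) for t in self.seizure_onsets))
        self.validate()

    def validate(self) -> None:
        if self.fs <= 0 or self.duration <= 0:
            raise ConfigurationError("fs and duration must be positive")
        if self.n_channels < 1:
            raise ConfigurationError("need at least one channel")
        if self.effect_size < 1:
            raise ConfigurationError("effect_size must be >= 1")
        if self.effect_band not in NAMED_BANDS:
            raise ConfigurationError(
                f"unknown effect_band {self.effect_band!r}; choose from {sorted(NAMED_BANDS)}"
            )
        if self.preictal_duration <= 0:
            raise ConfigurationError("preictal_duration must be positive")
        onsets = np.asarray(self.seizure_onsets, dtype=float)
        if onsets.size:
            if np.any(np.diff(onsets) <= 0):
                raise ConfigurationError("seizure onsets must be strictly increasing")
            if np.any(np.diff(onsets) < self.min_seizure_gap):
                raise ConfigurationError(
                    f"consecutive onsets closer than min_seizure_gap={self.min_seizure_gap} s"
                )
            if onsets[0] < 0 or onsets[-1] > self.duration:
                raise ConfigurationError("onsets must lie within [0, duration]")


@dataclass
class Recording:
    """A continuous multichannel signal with seizure-onset annotations.

    ``signal`` is channels x samples in microvolts; annotations are in
    seconds from the recording start (epoch origin 0).
    """

    signal: np.ndarray
    fs: float
    channel_names: list[str]
    seizure_onsets: np.ndarray
    seizure_offsets: np.ndarray | None = None
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        self.seizure_onsets = np.asarray(self.seizure_onsets, dtype=float)
        if self.seizure_offsets is not None:
            self.seizure_offsets = np.asarray(self.seizure_offsets, dtype=float)
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")
        if not np.isfinite(self.signal).all():
            raise DataError("signal contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def duration(self) -> float:
        return self.signal.shape[1] / self.fs


@dataclass
class Segment:
    """One fixed-duration clip with a class label and a seizure/block group id."""

    data: np.ndarray  # channels x samples
    label: str  # "interictal" | "preictal"
    group_id: int


@dataclass
class SegmentedDataset:
    """Timestamp-free labeled clips grouped by seizure (or interictal block).

    Emulates file-based releases: every clip has the same duration, preictal
    clips carry the index of the seizure they precede, and absolute times are
    deliberately absent.
    """

    segments: list[Segment]
    fs: float
    segment_duration: float

    def __len__(self) -> int:
        return len(self.segments)

    def labels(self) -> list[str]:
        return [s.label for s in self.segments]

    def count(self, label: str) -> int:
        return sum(1 for s in self.segments if s.label == label)


def _one_over_f_noise(rng: np.random.Generator, n: int, fs: float, exponent: float) -> np.ndarray:
    """Gaussian noise with a |f|^-exponent power spectrum, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.ones_like(freqs)
    nonzero = freqs > 0
    shape[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC drift
    x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _band_sos(band: tuple[float, float], fs: float):
    low, high = band
    nyq = fs / 2.0
    high = min(high, 0.99 * nyq)
    return sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")


def generate_recording(config: SimulationConfig) -> Recording:
    """Simulate a continuous recording with an injectable preictal signature.

    The background of each channel is 1/f-shaped noise plus a random-phase
    alpha-band oscillator (9-11 Hz), which gives spectral-edge and band-ratio
    features a realistic, non-flat spectrum. During the ``preictal_duration``
    window before each onset, power in ``effect_band`` is multiplied by a
    factor ramping linearly from 1 to ``effect_size``: band-limited Gaussian
    noise with local variance ``(m(t)-1) * P_band`` is added, where ``P_band``
    is the channel's baseline power in that band. Deterministic given
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration * config.fs))
    t = np.arange(n) / config.fs
    signal = np.empty((config.n_channels, n))

    inject = config.effect_size > 1 and len(config.seizure_onsets) > 0
    if inject:
        sos = _band_sos(NAMED_BANDS[config.effect_band], config.fs)
        envelope_sq = np.zeros(n)  # (m(t) - 1), the excess power multiplier
        for onset in config.seizure_onsets:
            lo = max(0.0, onset - config.preictal_duration)
            i0, i1 = int(round(lo * config.fs)), int(round(onset * config.fs))
            if i1 <= i0:
                continue
            ramp = (t[i0:i1] - (onset - config.preictal_duration)) / config.preictal_duration
            envelope_sq[i0:i1] = np.maximum(envelope_sq[i0:i1], ramp * (config.effect_size - 1.0))

    for ch in range(config.n_channels):
        noise = config.noise_scale * _one_over_f_noise(rng, n, config.fs, config.noise_exponent)
        f0 = rng.uniform(9.0, 11.0)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        background = noise + config.oscillator_amplitude * np.sin(2.0 * np.pi * f0 * t + phase)
        if inject:
            # causal single-pass filtering is sufficient here: only the power
            # content of the band matters, and measurement and injection use
            # the same filter so their bandwidths match
            band_power = float(np.var(sps.sosfilt(sos, background)))
            extra = sps.sosfilt(sos, rng.standard_normal(n))
            extra /= extra.std()
            background = background + extra * np.sqrt(envelope_sq * band_power)
        signal[ch] = background

    onsets = np.asarray(config.seizure_onsets, dtype=float)
    offsets = onsets + config.seizure_length
    return Recording(
        signal=signal,
        fs=config.fs,
        channel_names=[f"SIM{c + 1}" for c in range(config.n_channels)],
        seizure_onsets=onsets,
        seizure_offsets=offsets,
    )


def segment_recording(
    recording: Recording,
    segment_duration: float,
    preictal_duration: float,
    shuffle_seed: int = 0,
    ictal_blackout: float = 120.0,
) -> SegmentedDataset:
    """Cut a continuous recording into shuffled, timestamp-free labeled clips.

    Clips fully inside ``[onset - preictal_duration, onset)`` are labeled
    preictal with the seizure index as group id; clips wholly outside every
    preictal/ictal/blackout span are labeled interictal with a contiguous
    block index as group id. Clips straddling a class boundary are discarded,
    mirroring the clean class separation of file-based releases. Absolute
    times are not retained.
    """
    if recording.duration < segment_duration:
        raise DataError("recording shorter than one segment")
    k = preictal_duration / segment_duration
    if abs(k - round(k)) > 1e-9:
        raise ConfigurationError("segment_duration must divide preictal_duration")

    fs = recording.fs
    spw = int(round(segment_duration * fs))
    onsets = recording.seizure_onsets
    offsets = (
        recording.seizure_offsets if recording.seizure_offsets is not None else onsets
    )

    segments: list[Segment] = []
    # Preictal clips, tiled backward-aligned so the last clip ends at onset.
    for gid, onset in enumerate(onsets):
        start0 = onset - preictal_duration
        for j in range(int(round(k))):
            lo = start0 + j * segment_duration
            if lo < 0:
                continue
            i0 = int(round(lo * fs))
            if i0 + spw > recording.signal.shape[1]:
                continue
            segments.append(
                Segment(recording.signal[:, i0 : i0 + spw].copy(), "preictal", gid)
            )

    # Forbidden spans for interictal clips: preictal + ictal + blackout.
    forbidden = [
        (onset - preictal_duration, off + ictal_blackout)
        for onset, off in zip(onsets, offsets)
    ]
    n_tiles = int(recording.duration // segment_duration)
    block = 0
    in_block = False
    for j in range(n_tiles):
        lo, hi = j * segment_duration, (j + 1) * segment_duration
        if any(lo < f_hi and hi > f_lo for f_lo, f_hi in forbidden):
            in_block = False
            continue
        if not in_block:
            block += 1
            in_block = True
        i0 = int(round(lo * fs))
        segments.append(
            Segment(recording.signal[:, i0 : i0 + spw].copy(), "interictal", block - 1)
        )

    rng = np.random.default_rng(shuffle_seed)
    order = rng.permutation(len(segments))
    return SegmentedDataset(
        segments=[segments[i] for i in order], fs=fs, segment_duration=segment_duration
    )
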