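"""Filtering, resampling to the common 256 Hz rate, and 5-second windowing.

The filter path mirrors standard scalp/intracranial EEG conditioning: a
0.5 Hz high-pass removes drift, and (for scalp data) a 60 Hz low-pass removes
high-frequency noise. Filters are 4th-order Butterworth applied
forward-backward, so band-power features see no phase distortion. No separate
mains notch is applied: the gamma band definitions already leave gaps at
47-53 and 97-103 Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .exceptions import ConfigurationError
from .simulate import Recording, SegmentedDataset

DEFAULT_TARGET_FS = 256.0
DEFAULT_WINDOW_LENGTH = 5.0


@dataclass
class WindowSet:
    """Non-overlapping, contiguous analysis windows.

    ``windows`` is n_windows x channels x samples_per_window. For continuous
    data ``start_times`` holds each window's start in seconds; for segmented
    data it is ``None`` and ``keys`` holds ``(segment_index, window_index)``
    pairs instead.
    """

    windows: np.ndarray
    fs: float
    window_length: float
    start_times: np.ndarray | None = None
    keys: list[tuple[int, int]] | None = None

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]


def design_filters(fs: float, highpass_hz: float, lowpass_hz: float | None):
    """Second-order sections for the high-pass and optional low-pass stages."""
    nyq = fs / 2.0
    if highpass_hz >= nyq:
        raise ConfigurationError(f"high-pass cutoff {highpass_hz} Hz >= Nyquist {nyq} Hz")
    stages = [sps.butter(4, highpass_hz, btype="highpass", fs=fs, output="sos")]
    if lowpass_hz is not None:
        if lowpass_hz >= nyq:
            raise ConfigurationError(f"low-pass cutoff {lowpass_hz} Hz >= Nyquist {nyq} Hz")
        stages.append(sps.butter(4, lowpass_hz, btype="lowpass", fs=fs, output="sos"))
    return stages


def apply_filters(
    recording: Recording, highpass_hz: float = 0.5, lowpass_hz: float | None = None
) -> Recording:
    """Zero-phase Butterworth filtering; high-pass always, low-pass on request."""
    out = recording.signal
    for sos in design_filters(recording.fs, highpass_hz, lowpass_hz):
        out = sps.sosfiltfilt(sos, out, axis=-1)
    return Recording(
        signal=out,
        fs=recording.fs,
        channel_names=list(recording.channel_names),
        seizure_onsets=recording.seizure_onsets.copy(),
        seizure_offsets=None if recording.seizure_offsets is None else recording.seizure_offsets.copy(),
        start_time=recording.start_time,
    )


def resample_to(recording: Recording, target_fs: float = DEFAULT_TARGET_FS) -> Recording:
    """Anti-aliased polyphase resampling to ``target_fs``.

    Annotations are in seconds and are untouched. A recording already at the
    target rate passes through bit-equal; upsampling is out of scope.
    """
    if target_fs > recording.fs:
        raise ConfigurationError("upsampling is not supported")
    if target_fs == recording.fs:
        return recording
    frac = Fraction(target_fs / recording.fs).limit_denominator(1000)
    out = sps.resample_poly(recording.signal, frac.numerator, frac.denominator, axis=-1)
    return Recording(
        signal=out,
        fs=target_fs,
        channel_names=list(recording.channel_names),
        seizure_onsets=recording.seizure_onsets.copy(),
        seizure_offsets=None if recording.seizure_offsets is None else recording.seizure_offsets.copy(),
        start_time=recording.start_time,
    )


def make_windows(recording: Recording, window_length: float = DEFAULT_WINDOW_LENGTH) -> WindowSet:
    """Cut a continuous recording into non-overlapping windows.

    The trailing remainder shorter than one window is discarded. A recording
    shorter than one window yields an empty WindowSet with a warning.
    """
    spw = int(round(recording.fs * window_length))
    n_win = recording.signal.shape[1] // spw
    if n_win == 0:
        warnings.warn("recording shorter than one window; empty WindowSet", stacklevel=2)
        return WindowSet(
            windows=np.empty((0, recording.n_channels, spw)),
            fs=recording.fs,
            window_length=window_length,
            start_times=np.empty(0),
        )
    trimmed = recording.signal[:, : n_win * spw]
    windows = trimmed.reshape(recording.n_channels, n_win, spw).transpose(1, 0, 2)
    start_times = recording.start_time + np.arange(n_win) * window_length
    return WindowSet(
        windows=windows, fs=recording.fs, window_length=window_length, start_times=start_times
    )


def windows_from_segments(
    dataset: SegmentedDataset, window_length: float = DEFAULT_WINDOW_LENGTH
) -> tuple[WindowSet, np.ndarray, np.ndarray]:
    """Window every clip of a segmented dataset.

    Returns the WindowSet (keyed by ``(segment_index, window_index)``), the
    per-window 0/1 labels inherited from the clip labels, and the per-window
    seizure/block group ids.
    """
    spw = int(round(dataset.fs * window_length))
    all_windows, labels, groups, keys = [], [], [], []
    for si, seg in enumerate(dataset.segments):
        n_win = seg.data.shape[1] // spw
        trimmed = seg.data[:, : n_win * spw]
        w = trimmed.reshape(seg.data.shape[0], n_win, spw).transpose(1, 0, 2)
        all_windows.append(w)
        lab = 1 if seg.label == "preictal" else 0
        labels.extend([lab] * n_win)
        groups.extend([seg.group_id] * n_win)
        keys.extend((si, j) for j in range(n_win))
    windows = (
        np.concatenate(all_windows, axis=0)
        if all_windows
        else np.empty((0, 0, spw))
    )
    ws = WindowSet(windows=windows, fs=dataset.fs, window_length=window_length, keys=keys)
    return ws, np.asarray(labels, dtype=int), np.asarray(groups, dtype=int)
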