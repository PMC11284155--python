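"""The 59 univariate linear features computed per channel per 5-s window.

The feature set covers four families that are standard in EEG seizure
prediction:

* frequency domain: relative spectral power in eight bands (delta, theta,
  alpha, beta and four gamma sub-bands with gaps at the mains harmonics),
  the pairwise ratios of those band powers (including a broadband-gamma
  composite, 36 unordered pairs over 9 bands), the 50% spectral edge
  frequency and the cumulative power at that edge;
* time domain: the first four statistical moments (mean, variance, skewness,
  Pearson kurtosis), the three Hjorth parameters (activity, mobility,
  complexity), and the decorrelation time (first zero-crossing lag of the
  autocorrelation);
* time-frequency: the energies of the five finest detail levels of a db4
  discrete wavelet decomposition.

That decomposition totals exactly 59 features per channel
(8 + 36 + 2 + 4 + 3 + 1 + 5). The registry is an ordered, replaceable
configuration object so an alternative decomposition can be swapped in
without code change.

Conventions chosen so closed-form oracles are exact: the power spectrum is
a Welch estimate (1-s Hann segments, 50% overlap); skewness/kurtosis use
biased moment estimators; Hjorth mobility uses unscaled first differences
(rad/sample); the autocorrelation is computed circularly via the FFT; the
DWT uses periodization boundaries (orthogonal, energy-conserving).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pywt
from scipy import signal as sps

from .exceptions import DataError
from .preprocess import WindowSet
from .simulate import NAMED_BANDS

RATIO_EPS = 1e-12
#: total-power integration range lower edge (Hz)
SPECTRUM_FLOOR = 0.5
SPECTRUM_CEIL = 128.0
#: a normalized autocorrelation at or below this counts as a zero-crossing
_ACORR_ZERO_TOL = 1e-10


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low: float
    high: float

    def __post_init__(self):
        if not (0 < self.low < self.high <= 128):
            raise ValueError(f"invalid band {self.name}: ({self.low}, {self.high})")


DEFAULT_BANDS: list[BandDefinition] = [
    BandDefinition(name, lo, hi) for name, (lo, hi) in NAMED_BANDS.items()
]
#: bands entering the pairwise ratios: the 8 sub-bands plus broadband gamma
RATIO_BANDS: list[BandDefinition] = DEFAULT_BANDS + [BandDefinition("gamma_broad", 30.0, 128.0)]


@dataclass(frozen=True)
class FeatureDescriptor:
    name: str
    family: str  # spectral | ratio | edge | moment | hjorth | decorrelation | wavelet
    parameters: dict = field(default_factory=dict)


@dataclass(frozen=True)
class FeatureRegistry:
    """Ordered list of feature descriptors; the default has exactly 59 entries."""

    descriptors: tuple[FeatureDescriptor, ...]

    def __len__(self) -> int:
        return len(self.descriptors)

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.descriptors]

    def family_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for d in self.descriptors:
            counts[d.family] = counts.get(d.family, 0) + 1
        return counts


def default_registry() -> FeatureRegistry:
    """The fixed default registry of 59 univariate linear features."""
    desc: list[FeatureDescriptor] = []
    for b in DEFAULT_BANDS:
        desc.append(FeatureDescriptor(f"rsp_{b.name}", "spectral", {"band": b.name}))
    for a, b in combinations(RATIO_BANDS, 2):
        desc.append(
            FeatureDescriptor(f"ratio_{a.name}_{b.name}", "ratio", {"num": a.name, "den": b.name})
        )
    desc.append(FeatureDescriptor("sef50", "edge", {"fraction": 0.5}))
    desc.append(FeatureDescriptor("sef50_power", "edge", {"fraction": 0.5}))
    for m in ("mean", "variance", "skewness", "kurtosis"):
        desc.append(FeatureDescriptor(m, "moment"))
    for h in ("hjorth_activity", "hjorth_mobility", "hjorth_complexity"):
        desc.append(FeatureDescriptor(h, "hjorth"))
    desc.append(FeatureDescriptor("decorrelation_time", "decorrelation"))
    for d in range(1, 6):
        desc.append(FeatureDescriptor(f"wavelet_d{d}_energy", "wavelet", {"level": d, "wavelet": "db4"}))
    return FeatureRegistry(tuple(desc))


@dataclass
class FeatureMatrix:
    """Windows x (channels x features) matrix with channel-qualified names."""

    values: np.ndarray
    feature_names: list[str]
    window_times: np.ndarray | None = None
    window_keys: list[tuple[int, int]] | None = None
    labels: np.ndarray | None = None

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.values, columns=self.feature_names)
        if self.window_times is not None:
            df.insert(0, "time_s", self.window_times)
        if self.labels is not None:
            df["label"] = self.labels
        return df


# ---------------------------------------------------------------------------
# family computations (vectorized over a stack of windows)
# ---------------------------------------------------------------------------

def _welch_psd(windows: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    nperseg = min(int(round(fs)), windows.shape[-1])
    # detrend is skipped: the 0 Hz bin never enters a band (floor is 0.5 Hz)
    freqs, psd = sps.welch(
        windows, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2,
        detrend=False, axis=-1,
    )
    return freqs, psd


def _band_mask(freqs: np.ndarray, low: float, high: float) -> np.ndarray:
    mask = (freqs >= low) & (freqs < high)
    if high >= freqs[-1]:  # include the top edge (Nyquist) in the last band
        mask |= freqs == freqs[-1]
    return mask


def spectral_features(
    windows: np.ndarray, fs: float, bands: list[BandDefinition] | None = None
) -> dict[str, np.ndarray]:
    """Relative band powers, pairwise ratios, SEF50 and the power at the edge.

    Relative power = band power / total power over 0.5 Hz to min(128, Nyquist).
    The gamma gaps (47-53, 97-103 Hz) are excluded from the numerators but
    included in the denominator, so the eight relative powers sum to <= 1.
    The spectral edge frequency is the smallest frequency below which at
    least 50% of the total power lies; the companion feature is the
    cumulative (absolute) power up to that edge. All-zero windows yield zero
    powers and the 0.5 Hz floor for the edge.
    """
    bands = bands if bands is not None else DEFAULT_BANDS
    windows = np.atleast_2d(windows)
    freqs, psd = _welch_psd(windows, fs)
    df = freqs[1] - freqs[0]
    total_mask = (freqs >= SPECTRUM_FLOOR) & (freqs <= min(SPECTRUM_CEIL, freqs[-1]))
    total = psd[..., total_mask].sum(axis=-1) * df
    safe_total = np.where(total > 0, total, 1.0)

    out: dict[str, np.ndarray] = {}
    rsp: dict[str, np.ndarray] = {}
    for b in RATIO_BANDS:
        power = psd[..., _band_mask(freqs, b.low, b.high)].sum(axis=-1) * df
        rsp[b.name] = np.where(total > 0, power / safe_total, 0.0)
    for b in bands:
        out[f"rsp_{b.name}"] = rsp[b.name]
    for a, b in combinations(RATIO_BANDS, 2):
        out[f"ratio_{a.name}_{b.name}"] = rsp[a.name] / (rsp[b.name] + RATIO_EPS)

    in_range = psd[..., total_mask] * df
    cum = np.cumsum(in_range, axis=-1)
    target = 0.5 * total[..., None]
    idx = np.argmax(cum >= target, axis=-1)
    sef = freqs[total_mask][idx]
    edge_power = np.take_along_axis(cum, idx[..., None], axis=-1)[..., 0]
    zero = total <= 0
    out["sef50"] = np.where(zero, SPECTRUM_FLOOR, sef)
    out["sef50_power"] = np.where(zero, 0.0, edge_power)
    return out


def temporal_features(windows: np.ndarray, fs: float) -> dict[str, np.ndarray]:
    """Moments, Hjorth parameters, and decorrelation time.

    Degenerate (zero-variance) windows get zeros for the scale-free features.
    Decorrelation time is the first integer lag (converted to seconds) at
    which the circular normalized autocorrelation is <= 0 to numerical
    precision; if it never crosses within half the window, the window length
    is returned.
    """
    windows = np.atleast_2d(windows)
    n = windows.shape[-1]
    if n < 3:
        raise DataError("temporal features need windows of at least 3 samples")
    mean = windows.mean(axis=-1)
    centered = windows - mean[..., None]
    var = (centered**2).mean(axis=-1)
    sd = np.sqrt(var)
    safe_sd = np.where(sd > 0, sd, 1.0)
    zero_var = var <= 0

    c2 = centered * centered
    c3 = c2 * centered
    skew = np.where(zero_var, 0.0, c3.mean(axis=-1) / safe_sd**3)
    kurt = np.where(zero_var, 0.0, (c2 * c2).mean(axis=-1) / safe_sd**4)
    del c2, c3

    dx = np.diff(windows, axis=-1)
    ddx = np.diff(dx, axis=-1)
    var_dx = dx.var(axis=-1)
    var_ddx = ddx.var(axis=-1)
    mobility = np.where(zero_var, 0.0, np.sqrt(var_dx / np.where(zero_var, 1.0, var)))
    mob_dx = np.sqrt(np.divide(var_ddx, var_dx, out=np.zeros_like(var_dx), where=var_dx > 0))
    complexity = np.where(
        (mobility > 0) & (var_dx > 0), np.divide(mob_dx, mobility, out=np.zeros_like(mobility), where=mobility > 0), 0.0
    )

    # circular autocorrelation via the FFT (exact cosines for whole-cycle sines)
    spec = np.fft.rfft(centered, axis=-1)
    acorr = np.fft.irfft(spec * np.conj(spec), n=n, axis=-1)
    r0 = acorr[..., 0]
    max_lag = n // 2
    norm = acorr[..., 1 : max_lag + 1] / np.where(r0 > 0, r0, 1.0)[..., None]
    crossed = norm <= _ACORR_ZERO_TOL
    first = np.argmax(crossed, axis=-1) + 1  # lag index, 1-based
    never = ~crossed.any(axis=-1)
    decorr = np.where(never, n, first) / fs
    decorr = np.where(zero_var, 0.0, decorr)

    return {
        "mean": mean,
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "hjorth_activity": var,
        "hjorth_mobility": mobility,
        "hjorth_complexity": complexity,
        "decorrelation_time": decorr,
    }


def wavelet_features(windows: np.ndarray, wavelet: str = "db4", levels: int = 5) -> dict[str, np.ndarray]:
    """Energies of the detail coefficients D1..D5 of an orthogonal db4 DWT.

    Periodization boundaries keep the transform orthogonal, so the detail
    energies plus the approximation energy equal the window energy exactly.
    """
    windows = np.atleast_2d(windows)
    if windows.shape[-1] < 2**levels:
        raise DataError(f"window shorter than 2^{levels} samples")
    coeffs = pywt.wavedec(windows, wavelet, mode="periodization", level=levels, axis=-1)
    # coeffs = [cA5, cD5, cD4, cD3, cD2, cD1]
    out: dict[str, np.ndarray] = {}
    for d in range(1, levels + 1):
        out[f"wavelet_d{d}_energy"] = (coeffs[-d] ** 2).sum(axis=-1)
    return out


def _compute_all(windows: np.ndarray, fs: float) -> dict[str, np.ndarray]:
    cols: dict[str, np.ndarray] = {}
    cols.update(spectral_features(windows, fs))
    cols.update(temporal_features(windows, fs))
    cols.update(wavelet_features(windows))
    return cols


def extract_features(
    window_set: WindowSet, registry: FeatureRegistry | None = None
) -> FeatureMatrix:
    """Compute the registry's features for every window and channel.

    Columns are ordered channel block by channel block, each block in
    registry order, and named ``"<channel>::<feature>"`` (channels are
    numbered ``ch0, ch1, ...``). Windows containing non-finite samples are
    dropped with a warning.
    """
    registry = registry if registry is not None else default_registry()
    w = window_set.windows
    n_win, n_ch, _ = w.shape

    finite = np.isfinite(w).all(axis=(1, 2))
    if not finite.all():
        warnings.warn(f"dropping {int((~finite).sum())} windows with non-finite samples", stacklevel=2)
    w = w[finite]

    names = [f"ch{c}::{feat}" for c in range(n_ch) for feat in registry.names]
    if w.shape[0] == 0:
        values = np.empty((0, n_ch * len(registry)))
    else:
        blocks = []
        for c in range(n_ch):
            cols = _compute_all(w[:, c, :], window_set.fs)
            missing = [nm for nm in registry.names if nm not in cols]
            if missing:
                raise DataError(f"registry requests unknown features: {missing}")
            blocks.append(np.column_stack([cols[nm] for nm in registry.names]))
        values = np.hstack(blocks)

    times = None
    keys = None
    if window_set.start_times is not None:
        times = window_set.start_times[finite]
    if window_set.keys is not None:
        keys = [k for k, ok in zip(window_set.keys, finite) if ok]
    return FeatureMatrix(values=values, feature_names=names, window_times=times, window_keys=keys)
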