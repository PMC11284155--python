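"""Feature oracles: registry structure, closed-form sinusoid values,
flat-spectrum edge frequency, wavelet energy conservation, and the
brute-force periodogram cross-check of the Welch band powers."""

import numpy as np
import pytest
import pywt
from scipy import signal as sps

import preictal as p
from preictal import features as F
from preictal.exceptions import DataError

FS = 256.0


def _window(x):
    return np.atleast_2d(x)


@pytest.fixture()
def noise_windows():
    rng = np.random.default_rng(0)
    return rng.standard_normal((200, 1280))


class TestRegistry:
    def test_default_has_59_unique_ordered_features(self):
        reg = p.default_registry()
        assert len(reg) == 59
        assert len(set(reg.names)) == 59
        assert reg.names == p.default_registry().names  # deterministic ordering

    def test_family_decomposition(self):
        assert p.default_registry().family_counts() == {
            "spectral": 8, "ratio": 36, "edge": 2, "moment": 4,
            "hjorth": 3, "decorrelation": 1, "wavelet": 5,
        }


class TestSpectral:
    def test_pure_alpha_sine_concentrates_in_alpha(self, sine):
        sp = F.spectral_features(_window(sine(10.0)), FS)
        assert sp["rsp_alpha"][0] > 0.95
        for b in F.DEFAULT_BANDS:
            if b.name != "alpha":
                assert sp[f"rsp_{b.name}"][0] < 0.05

    def test_white_noise_edge_frequency_at_spectrum_midpoint(self, noise_windows):
        sef = F.spectral_features(noise_windows, FS)["sef50"]
        assert sef.mean() == pytest.approx(64.25, abs=2.0)

    def test_relative_powers_bounded_and_subadditive(self, noise_windows):
        sp = F.spectral_features(noise_windows, FS)
        total = np.zeros(noise_windows.shape[0])
        for b in F.DEFAULT_BANDS:
            rsp = sp[f"rsp_{b.name}"]
            assert ((rsp >= 0) & (rsp <= 1)).all()
            total += rsp
        # gamma gaps are in the denominator but in no numerator
        assert (total <= 1 + 1e-9).all()

    def test_scale_invariance_and_power_scaling(self, sine):
        x = sine(10.0) + 0.1 * np.cos(2 * np.pi * 27.0 * np.arange(1280) / FS)
        a, b = F.spectral_features(_window(x), FS), F.spectral_features(_window(5.0 * x), FS)
        assert a["rsp_alpha"][0] == pytest.approx(b["rsp_alpha"][0], rel=1e-9)
        assert a["ratio_alpha_beta"][0] == pytest.approx(b["ratio_alpha_beta"][0], rel=1e-6)
        assert b["sef50_power"][0] == pytest.approx(25.0 * a["sef50_power"][0], rel=1e-9)

    def test_all_zero_window_flagged_floor(self):
        sp = F.spectral_features(np.zeros((1, 1280)), FS)
        assert sp["rsp_alpha"][0] == 0.0
        assert sp["sef50"][0] == 0.5
        assert sp["sef50_power"][0] == 0.0

    @pytest.mark.parametrize("make", ["sine20", "broadband"])
    def test_welch_band_powers_match_periodogram_oracle(self, make, sine):
        """Brute-force oracle: rectangular-rule integration of the raw
        periodogram agrees with the Welch path within 10% on relative power."""
        if make == "sine20":
            x = sine(20.0)  # 100 cycles in the window
        else:
            x = np.random.default_rng(3).standard_normal(1280)
        freqs, psd = sps.periodogram(x, fs=FS)
        df = freqs[1] - freqs[0]
        total_mask = (freqs >= 0.5) & (freqs <= 128.0)
        total = psd[total_mask].sum() * df
        sp = F.spectral_features(_window(x), FS)
        for b in F.DEFAULT_BANDS:
            oracle = psd[(freqs >= b.low) & (freqs < b.high)].sum() * df / total
            if oracle > 0.02:  # below that, both estimates are noise-dominated
                assert sp[f"rsp_{b.name}"][0] == pytest.approx(oracle, rel=0.10, abs=0.01)


class TestTemporal:
    def test_sine_closed_forms(self, sine):
        tf = F.temporal_features(_window(sine(10.0)), FS)
        assert tf["hjorth_activity"][0] == pytest.approx(0.5, rel=0.05)
        assert tf["hjorth_mobility"][0] == pytest.approx(2 * np.sin(np.pi * 10 / FS), rel=0.05)
        assert tf["hjorth_complexity"][0] == pytest.approx(1.0, rel=0.05)
        assert tf["mean"][0] == pytest.approx(0.0, abs=1e-12)

    def test_decorrelation_time_of_8hz_sine(self, sine):
        # autocorrelation cos(2 pi 8 lag / 256) first touches zero at lag fs/(4f) = 8
        tf = F.temporal_features(_window(sine(8.0)), FS)
        assert tf["decorrelation_time"][0] == pytest.approx(0.03125, abs=1e-12)

    def test_moment_conventions_on_known_distribution(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((1, 12800))
        tf = F.temporal_features(x, FS)
        assert tf["skewness"][0] == pytest.approx(0.0, abs=0.1)
        assert tf["kurtosis"][0] == pytest.approx(3.0, abs=0.2)  # Pearson convention

    def test_constant_window_degenerates_to_zero(self):
        tf = F.temporal_features(np.full((1, 1280), 7.0), FS)
        assert tf["mean"][0] == 7.0
        assert tf["variance"][0] == 0.0
        for name in ("skewness", "kurtosis", "hjorth_mobility", "hjorth_complexity",
                     "decorrelation_time"):
            assert tf[name][0] == 0.0


class TestWavelet:
    def test_zero_window_zero_energies(self):
        wf = F.wavelet_features(np.zeros((1, 1280)))
        assert all(wf[f"wavelet_d{d}_energy"][0] == 0.0 for d in range(1, 6))

    def test_orthogonal_energy_conservation(self, sine):
        x = sine(10.0) + 0.3 * np.random.default_rng(5).standard_normal(1280)
        wf = F.wavelet_features(_window(x))
        approx = pywt.wavedec(x, "db4", mode="periodization", level=5)[0]
        total = sum(wf[f"wavelet_d{d}_energy"][0] for d in range(1, 6)) + (approx**2).sum()
        assert total == pytest.approx((x**2).sum(), rel=1e-6)

    def test_alternating_signal_concentrates_in_d1(self):
        alt = np.tile([1.0, -1.0], 640)
        wf = F.wavelet_features(_window(alt))
        assert wf["wavelet_d1_energy"][0] / (alt**2).sum() > 0.9

    def test_window_too_short_rejected(self):
        with pytest.raises(DataError):
            F.wavelet_features(np.zeros((1, 16)))


class TestExtract:
    def _window_set(self, windows):
        return p.WindowSet(windows=windows, fs=FS, window_length=5.0,
                           start_times=np.arange(windows.shape[0]) * 5.0)

    def test_shape_and_names(self):
        rng = np.random.default_rng(6)
        fm = p.extract_features(self._window_set(rng.standard_normal((12, 2, 1280))))
        assert fm.values.shape == (12, 118)
        assert fm.feature_names[0] == "ch0::rsp_delta"
        assert fm.feature_names[59] == "ch1::rsp_delta"
        assert np.isfinite(fm.values).all()

    def test_single_channel_yields_59_columns(self):
        fm = p.extract_features(self._window_set(np.random.default_rng(7).standard_normal((3, 1, 1280))))
        assert fm.values.shape == (3, 59)

    def test_channel_permutation_permutes_blocks_not_values(self):
        rng = np.random.default_rng(8)
        w = rng.standard_normal((4, 2, 1280))
        a = p.extract_features(self._window_set(w))
        b = p.extract_features(self._window_set(w[:, ::-1, :]))
        np.testing.assert_allclose(a.values[:, :59], b.values[:, 59:])
        np.testing.assert_allclose(a.values[:, 59:], b.values[:, :59])

    def test_nonfinite_windows_dropped_with_warning(self):
        rng = np.random.default_rng(9)
        w = rng.standard_normal((5, 1, 1280))
        w[2, 0, 100] = np.nan
        with pytest.warns(UserWarning, match="non-finite"):
            fm = p.extract_features(self._window_set(w))
        assert fm.values.shape[0] == 4
        assert fm.window_times.tolist() == [0.0, 5.0, 15.0, 20.0]
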