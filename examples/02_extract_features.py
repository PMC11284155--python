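"""Filter, window, and extract the 59-feature vector from a short recording.

Shows the preprocessing path (0.5 Hz high-pass; optionally a 60 Hz low-pass
for scalp data), 5-s non-overlapping windowing, and the per-channel feature
families: relative band powers, band ratios, spectral edge, moments, Hjorth
parameters, decorrelation time, and wavelet detail energies.
"""

import numpy as np

import preictal as p

config = p.SimulationConfig(duration=300.0, seizure_onsets=(), n_channels=2, seed=1)
recording = p.generate_recording(config)

filtered = p.apply_filters(recording, highpass_hz=0.5, lowpass_hz=60.0)
windows = p.make_windows(filtered, window_length=5.0)
print(f"{windows.n_windows} windows of {windows.windows.shape[-1]} samples "
      f"({windows.window_length:.0f} s at {windows.fs:.0f} Hz)")

registry = p.default_registry()
print(f"registry: {len(registry)} features per channel, by family: {registry.family_counts()}")

fm = p.extract_features(windows, registry)
print(f"feature matrix: {fm.values.shape[0]} windows x {fm.values.shape[1]} columns")

df = fm.to_dataframe()
cols = ["ch0::rsp_alpha", "ch0::sef50", "ch0::hjorth_mobility", "ch0::decorrelation_time"]
print(df[cols].describe().loc[["mean", "std"]].round(4))
print("(alpha relative power ~0.5: the simulated background carries an "
      "alpha oscillator on top of 1/f noise; SEF50 sits in the alpha band "
      "for the same reason — half the spectral power lies below it)")
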