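"""Shared fixtures: synthetic study patients at the desk-scale conditions.

The heavy session fixtures run the full pipeline on simulated patients:

* ``strong_reports`` — 20 seeded strong-effect patients (alpha-band power
  quadrupled over a signature spanning the 30-min occurrence period plus the
  10-min horizon before each of 6 seizures, 2 h apart);
* ``null_reports`` — 6 seeded null patients (effect size 1: preictal and
  interictal windows share one generating distribution);
* ``segmented_reports`` — 10 seeded segmented-regime patients (5-min clips,
  30-min preictal span per seizure).
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import preictal as p

STRONG_ONSETS = tuple(4000.0 + 7200.0 * i for i in range(6))
#: signature spans SOP_true (30 min) + SPH (10 min), so the recoverable SOP is 30
STRONG_SIGNATURE_S = 2400.0
SEGMENTED_SIGNATURE_S = 1800.0
SEGMENT_DURATION_S = 300.0


def simulation_config(seed: int, effect_size: float = 4.0,
                      preictal_duration: float = STRONG_SIGNATURE_S) -> p.SimulationConfig:
    return p.SimulationConfig(
        duration=STRONG_ONSETS[-1] + 600.0,
        seizure_onsets=STRONG_ONSETS,
        min_seizure_gap=3600.0,
        preictal_duration=preictal_duration,
        effect_band="alpha",
        effect_size=effect_size,
        seed=seed,
    )


def run_continuous(seed: int, effect_size: float = 4.0) -> p.PatientReport:
    rec = p.generate_recording(simulation_config(seed, effect_size))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return p.run_continuous_experiment(rec, p.ExperimentConfig(seed=seed), f"sim{seed}")


def run_segmented(seed: int, effect_size: float = 4.0) -> p.PatientReport:
    rec = p.generate_recording(
        simulation_config(seed, effect_size, preictal_duration=SEGMENTED_SIGNATURE_S)
    )
    ds = p.segment_recording(
        rec, SEGMENT_DURATION_S, SEGMENTED_SIGNATURE_S, shuffle_seed=seed
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return p.run_segmented_experiment(ds, p.ExperimentConfig(seed=seed), f"seg{seed}")


@pytest.fixture(scope="session")
def strong_reports() -> list[p.PatientReport]:
    return [run_continuous(seed) for seed in range(20)]


@pytest.fixture(scope="session")
def null_reports() -> list[p.PatientReport]:
    return [run_continuous(100 + seed, effect_size=1.0) for seed in range(6)]


@pytest.fixture(scope="session")
def segmented_reports() -> list[p.PatientReport]:
    return [run_segmented(200 + seed) for seed in range(10)]


@pytest.fixture()
def sine():
    """5-s windows of unit sinusoids at 256 Hz."""

    def _make(freq: float, fs: float = 256.0, seconds: float = 5.0) -> np.ndarray:
        t = np.arange(int(fs * seconds)) / fs
        return np.sin(2.0 * np.pi * freq * t)

    return _make
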