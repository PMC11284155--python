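"""End-to-end experiment runner for both data regimes.

``run_continuous_experiment`` executes the full patient-specific chain on an
annotated recording: filtering, resampling to 256 Hz, 5-s windowing, feature
extraction, chronological split, seizure-wise grid search over (SOP, feature
count), final classifier training, prediction on the test timeline, Firing
Power regularization and alarm generation, alarm- and sample-based metrics,
and both surrogate tests.

``run_segmented_experiment`` runs the same chain on timestamp-free labeled
clips, minus everything that needs a timeline: the preictal period is fixed
by the file labels (no SOP grid), there is no alarm generation and no alarm
metrics — only sample metrics and the sample surrogate test, mirroring how
competition-style datasets can be evaluated.

Every random draw is routed through seeds derived from ``config.seed``, so a
rerun with the same configuration reproduces the report exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .alarms import firing_power, raise_alarms
from .assembly import (
    chronological_split,
    compute_class_weights,
    label_windows,
    segmented_split,
    zscore_apply,
    zscore_fit,
)
from .exceptions import ConfigurationError, DataError
from .features import FeatureRegistry, default_registry, extract_features
from .metrics import AlarmMetrics, SampleMetrics, alarm_metrics, sample_metrics
from .model import (
    DEFAULT_K_GRID,
    DEFAULT_SOP_GRID,
    CVResult,
    cv_grid_search,
    cv_select_k,
    predict,
    rank_features,
    train_classifier,
)
from .preprocess import apply_filters, make_windows, resample_to, windows_from_segments
from .simulate import Recording, SegmentedDataset
from .surrogate import SurrogateResult, surrogate_test_alarm, surrogate_test_sample


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything one experiment needs, in one place.

    Defaults follow the standard alert-device settings: 10-min SPH, SOP grid
    10..55 min in 5-min steps (the preictal period is capped at one hour),
    Firing Power threshold 0.7, three training seizures, 30 surrogates at
    alpha 0.05, 5-s windows at 256 Hz.
    """

    sph_min: float = 10.0
    sop_grid: tuple[float, ...] = DEFAULT_SOP_GRID
    preictal_cap_min: float = 60.0
    k_grid: tuple[int, ...] = DEFAULT_K_GRID
    fp_threshold: float = 0.7
    n_train_seizures: int = 3
    n_surrogates: int = 30
    alpha: float = 0.05
    window_length: float = 5.0
    target_fs: float = 256.0
    highpass_hz: float = 0.5
    lowpass_hz: float | None = None
    ictal_blackout: float = 120.0
    train_fraction: float = 0.7
    surrogate_method: str = "rank"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sph_min <= 0:
            raise ConfigurationError("sph_min must be positive")
        if not 0 < self.fp_threshold < 1:
            raise ConfigurationError("fp_threshold must lie strictly between 0 and 1")
        for sop in self.sop_grid:
            if sop < 10 or sop > self.preictal_cap_min:
                raise ConfigurationError(
                    f"SOP {sop} min outside [10, preictal cap {self.preictal_cap_min}] min"
                )


@dataclass
class PatientReport:
    """Per-patient results row: selected parameters, metrics, and validation."""

    patient_id: str
    regime: str  # "continuous" | "segmented"
    sop_star: float | None
    k_star: int
    sample: SampleMetrics
    surrogate_sample: SurrogateResult | None
    alarm: AlarmMetrics | None = None
    surrogate_alarm: SurrogateResult | None = None
    cv: CVResult | None = None
    n_train_windows: int = 0
    n_test_windows: int = 0

    def to_row(self) -> dict:
        row = {
            "patient_id": self.patient_id,
            "regime": self.regime,
            "sop_star": self.sop_star,
            "k_star": self.k_star,
            "ss_alarm": None if self.alarm is None else self.alarm.ss_alarm,
            "fpr_per_hour": None if self.alarm is None else self.alarm.fpr_per_hour,
            "ss_sample": self.sample.ss_sample,
            "sp_sample": self.sample.sp_sample,
            "auc": self.sample.auc,
            "validated_alarm": None if self.surrogate_alarm is None else self.surrogate_alarm.validated,
            "validated_sample": None if self.surrogate_sample is None else self.surrogate_sample.validated,
        }
        return row


def run_continuous_experiment(
    recording: Recording,
    config: ExperimentConfig = ExperimentConfig(),
    patient_id: str = "patient",
    registry: FeatureRegistry | None = None,
) -> PatientReport:
    """Run the full alarm-regime pipeline on one annotated recording."""
    registry = registry if registry is not None else default_registry()
    rec = apply_filters(recording, config.highpass_hz, config.lowpass_hz)
    if rec.fs > config.target_fs:
        rec = resample_to(rec, config.target_fs)
    ws = make_windows(rec, config.window_length)
    fm = extract_features(ws, registry)

    # the split is computed once; grid search relabels the training timeline
    split = chronological_split(
        fm.values,
        fm.window_times,
        rec.seizure_onsets,
        config.n_train_seizures,
        sop_min=config.sop_grid[0],
        sph_min=config.sph_min,
        offsets=rec.seizure_offsets,
        ictal_blackout=config.ictal_blackout,
    )
    n_tr = config.n_train_seizures
    train_offsets = None if rec.seizure_offsets is None else rec.seizure_offsets[:n_tr]
    test_offsets = None if rec.seizure_offsets is None else rec.seizure_offsets[n_tr:]

    cv = cv_grid_search(
        split.X_train,
        split.t_train,
        split.train_onsets,
        sop_grid=config.sop_grid,
        k_grid=config.k_grid,
        sph_min=config.sph_min,
        offsets=train_offsets,
        ictal_blackout=config.ictal_blackout,
    )
    sop_star, k_star = cv.sop_star, cv.k_star

    # final model at the selected parameters, on all training windows
    y_train = label_windows(
        split.t_train, split.train_onsets, sop_star, config.sph_min,
        offsets=train_offsets, ictal_blackout=config.ictal_blackout,
    )
    usable = y_train >= 0
    norm = zscore_fit(split.X_train[usable])
    Xn_train = zscore_apply(norm, split.X_train[usable])
    weights = compute_class_weights(y_train[usable])
    order = rank_features(Xn_train, y_train[usable])
    model = train_classifier(
        Xn_train, y_train[usable], order[:k_star], norm, weights,
        sop_min=sop_star, feature_names=fm.feature_names,
    )

    # test-set prediction over the full timeline (alarms need every window)
    y_test = label_windows(
        split.t_test, split.test_onsets, sop_star, config.sph_min,
        offsets=test_offsets, ictal_blackout=config.ictal_blackout,
    )
    Xn_test = zscore_apply(norm, split.X_test)
    proba, binary = predict(model, Xn_test)
    valid = y_test >= 0
    sm = sample_metrics(y_test[valid], binary[valid], proba[valid])

    tau = int(round((sop_star + config.sph_min) * 60.0 / config.window_length))
    fp = firing_power(binary, tau)
    alarms = raise_alarms(fp, config.fp_threshold, tau)
    alarm_times = alarms.times(split.t_test)
    test_start = float(split.t_test[0])
    test_end = float(split.t_test[-1] + config.window_length)
    am = alarm_metrics(
        alarm_times, split.test_onsets, sop_star, config.sph_min, test_start, test_end,
        offsets=test_offsets, ictal_blackout=config.ictal_blackout,
    )

    sur_alarm = surrogate_test_alarm(
        alarm_times, split.test_onsets, test_start, test_end, sop_star, config.sph_min,
        n_surrogates=config.n_surrogates, alpha=config.alpha,
        method=config.surrogate_method, seed=config.seed + 1,
    )
    sur_sample = surrogate_test_sample(
        y_test[valid], binary[valid],
        n_surrogates=config.n_surrogates, alpha=config.alpha,
        method=config.surrogate_method, seed=config.seed + 2,
    )
    return PatientReport(
        patient_id=patient_id,
        regime="continuous",
        sop_star=sop_star,
        k_star=k_star,
        sample=sm,
        surrogate_sample=sur_sample,
        alarm=am,
        surrogate_alarm=sur_alarm,
        cv=cv,
        n_train_windows=int(usable.sum()),
        n_test_windows=int(valid.sum()),
    )


def run_segmented_experiment(
    dataset: SegmentedDataset,
    config: ExperimentConfig = ExperimentConfig(),
    patient_id: str = "patient",
    registry: FeatureRegistry | None = None,
) -> PatientReport:
    """Run the sample-regime pipeline on timestamp-free labeled clips.

    The report deliberately carries no alarm metrics and no alarm surrogate:
    without absolute times there is no alarm view.
    """
    registry = registry if registry is not None else default_registry()
    ws, _, _ = windows_from_segments(dataset, config.window_length)
    if ws.fs != config.target_fs:
        raise ConfigurationError(
            f"segmented data must arrive at the target rate ({config.target_fs} Hz); "
            "resample the clips first"
        )
    fm = extract_features(ws, registry)
    split = segmented_split(dataset, fm.values, fm.window_keys, config.train_fraction, config.seed)
    cv = cv_select_k(
        split.X_train,
        split.y_train,
        split.train_groups,
        k_grid=config.k_grid,
        seed=config.seed + 3,
    )
    k_star = cv.k_star

    norm = zscore_fit(split.X_train)
    Xn_train = zscore_apply(norm, split.X_train)
    weights = compute_class_weights(split.y_train)
    order = rank_features(Xn_train, split.y_train)
    model = train_classifier(
        Xn_train, split.y_train, order[:k_star], norm, weights, feature_names=fm.feature_names
    )
    Xn_test = zscore_apply(norm, split.X_test)
    proba, binary = predict(model, Xn_test)
    sm = sample_metrics(split.y_test, binary, proba)
    sur_sample = surrogate_test_sample(
        split.y_test, binary,
        n_surrogates=config.n_surrogates, alpha=config.alpha,
        method=config.surrogate_method, seed=config.seed + 4,
    )
    return PatientReport(
        patient_id=patient_id,
        regime="segmented",
        sop_star=None,
        k_star=k_star,
        sample=sm,
        surrogate_sample=sur_sample,
        alarm=None,
        surrogate_alarm=None,
        cv=cv,
        n_train_windows=int(split.y_train.size),
        n_test_windows=int(split.y_test.size),
    )


def summarize(reports: list[PatientReport]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-patient table plus a dataset-level summary row.

    The summary holds the arithmetic mean of each metric over the patients
    that have it (regime-absent metrics are excluded, mirroring the dashes in
    alarm-regime tables) and the count and percentage of surrogate-validated
    patients under each approach.
    """
    if not reports:
        raise DataError("summarize needs at least one patient report")
    per_patient = pd.DataFrame([r.to_row() for r in reports])
    means = per_patient[["ss_alarm", "fpr_per_hour", "ss_sample", "sp_sample", "auc"]].astype(float).mean(
        skipna=True
    )
    val_alarm = per_patient["validated_alarm"].dropna()
    val_sample = per_patient["validated_sample"].dropna()
    summary = pd.DataFrame(
        [
            {
                "n_patients": len(reports),
                **{k: means[k] for k in means.index},
                "validated_alarm": int(val_alarm.sum()) if len(val_alarm) else None,
                "pct_validated_alarm": 100.0 * val_alarm.mean() if len(val_alarm) else None,
                "validated_sample": int(val_sample.sum()) if len(val_sample) else None,
                "pct_validated_sample": 100.0 * val_sample.mean() if len(val_sample) else None,
            }
        ]
    )
    return per_patient, summary
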