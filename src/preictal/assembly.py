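"""SOP/SPH labeling, chronological and file-based splitting, and scaling.

The positive (preictal) class of a window starting at time ``t`` is defined
by the alarm-device parameters: ``t`` lies within ``(SOP + SPH) * 60``
seconds before a seizure onset. SPH (seizure prediction horizon) is the
intervention lead time; SOP (seizure occurrence period) is the interval in
which the seizure is expected. Windows inside ictal spans or the post-onset
blackout are excluded from both classes.

Two splitting regimes mirror how real corpora are released: a chronological
split (first seizures train, later seizures test — no test window precedes a
training window), and a file-based split for timestamp-free segmented data
(preictal files grouped by seizure are assigned whole to one side, at the
closest possible 70/30 ratio, with the training interictal file count
balanced to the training preictal count).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, DataError, PatientExclusionError
from .simulate import SegmentedDataset

MIN_SEIZURES = 4  # patient-inclusion floor for the chronological regime
EXCLUDED = -1  # label value for ictal/blackout windows


def label_windows(
    window_times: np.ndarray,
    onsets: np.ndarray,
    sop_min: float,
    sph_min: float,
    *,
    offsets: np.ndarray | None = None,
    ictal_blackout: float = 120.0,
) -> np.ndarray:
    """Label window start times: 1 preictal, 0 interictal, -1 excluded.

    A window is preictal iff its start lies in ``[onset - (sop+sph)*60,
    onset)`` for some onset; windows starting inside ``[onset, offset +
    blackout)`` are excluded. Preictal spans are truncated at the recording
    start implicitly (no windows exist before time 0).
    """
    times = np.asarray(window_times, dtype=float)
    onsets = np.asarray(onsets, dtype=float)
    offsets = onsets if offsets is None else np.asarray(offsets, dtype=float)
    labels = np.zeros(times.shape, dtype=int)
    span = (sop_min + sph_min) * 60.0
    for onset, offset in zip(onsets, offsets):
        labels[(times >= onset - span) & (times < onset)] = 1
    for onset, offset in zip(onsets, offsets):
        labels[(times >= onset) & (times < offset + ictal_blackout)] = EXCLUDED
    return labels


@dataclass
class LabeledSplit:
    """Train/test feature matrices with labels and the test timeline."""

    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    train_seizure_ids: list[int]
    test_seizure_ids: list[int]
    t_train: np.ndarray | None = None
    t_test: np.ndarray | None = None
    train_onsets: np.ndarray | None = None
    test_onsets: np.ndarray | None = None
    cut_time: float | None = None
    test_groups: np.ndarray | None = None  # segmented regime: per-window group id
    train_mask: np.ndarray | None = None  # segmented regime: window-level masks
    test_mask: np.ndarray | None = None
    train_groups: np.ndarray | None = None


def chronological_split(
    X: np.ndarray,
    window_times: np.ndarray,
    onsets: np.ndarray,
    n_train_seizures: int = 3,
    *,
    sop_min: float,
    sph_min: float = 10.0,
    offsets: np.ndarray | None = None,
    ictal_blackout: float = 120.0,
    cut_after_min: float = 60.0,
) -> LabeledSplit:
    """First ``n_train_seizures`` seizures (and all windows up to a cut point
    one hour after the last of them) go to training; the rest to test.

    Patients with fewer than four seizures are excluded, matching the
    inclusion floor of clinical evaluations. Every training window time is
    strictly earlier than every test window time.
    """
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size < MIN_SEIZURES:
        raise PatientExclusionError(
            f"patient has {onsets.size} seizures; at least {MIN_SEIZURES} required"
        )
    if not 1 <= n_train_seizures < onsets.size:
        raise ConfigurationError("n_train_seizures must leave at least one test seizure")
    times = np.asarray(window_times, dtype=float)
    cut = onsets[n_train_seizures - 1] + cut_after_min * 60.0
    train_mask = times < cut
    test_mask = ~train_mask
    train_onsets = onsets[:n_train_seizures]
    test_onsets = onsets[n_train_seizures:]
    off = None if offsets is None else np.asarray(offsets, dtype=float)
    y_train = label_windows(
        times[train_mask], train_onsets, sop_min, sph_min,
        offsets=None if off is None else off[:n_train_seizures], ictal_blackout=ictal_blackout,
    )
    y_test = label_windows(
        times[test_mask], test_onsets, sop_min, sph_min,
        offsets=None if off is None else off[n_train_seizures:], ictal_blackout=ictal_blackout,
    )
    return LabeledSplit(
        X_train=X[train_mask],
        y_train=y_train,
        X_test=X[test_mask],
        y_test=y_test,
        train_seizure_ids=list(range(n_train_seizures)),
        test_seizure_ids=list(range(n_train_seizures, onsets.size)),
        t_train=times[train_mask],
        t_test=times[test_mask],
        train_onsets=train_onsets,
        test_onsets=test_onsets,
        cut_time=cut,
    )


def segmented_split(
    dataset: SegmentedDataset,
    X: np.ndarray,
    window_keys: list[tuple[int, int]],
    train_fraction: float = 0.7,
    seed: int = 0,
) -> LabeledSplit:
    """File-based split for timestamp-free data.

    Preictal files are assigned whole, per seizure group, with
    ``round(train_fraction * n_groups)`` groups in training (closest possible
    70/30 ratio); no group spans both sets. Training interictal files are
    drawn to match the training preictal file count exactly (class balancing
    by file selection); the remaining interictal files go to test. The
    assignment is deterministic given ``seed``.
    """
    pre_groups = sorted({s.group_id for s in dataset.segments if s.label == "preictal"})
    if len(pre_groups) < 2:
        raise DataError("cannot split: need at least 2 preictal seizure groups")
    rng = np.random.default_rng(seed)
    order = [pre_groups[i] for i in rng.permutation(len(pre_groups))]
    n_train_groups = int(round(train_fraction * len(pre_groups)))
    n_train_groups = min(max(n_train_groups, 1), len(pre_groups) - 1)
    train_groups = set(order[:n_train_groups])

    pre_train = [i for i, s in enumerate(dataset.segments)
                 if s.label == "preictal" and s.group_id in train_groups]
    pre_test = [i for i, s in enumerate(dataset.segments)
                if s.label == "preictal" and s.group_id not in train_groups]
    inter = [i for i, s in enumerate(dataset.segments) if s.label == "interictal"]
    if len(inter) < len(pre_train):
        raise DataError("not enough interictal files to balance the training set")
    inter_shuffled = [inter[i] for i in rng.permutation(len(inter))]
    inter_train = set(inter_shuffled[: len(pre_train)])
    inter_test = [i for i in inter if i not in inter_train]

    train_set = set(pre_train) | inter_train
    test_set = set(pre_test) | set(inter_test)

    keys = window_keys
    w_train = np.array([k[0] in train_set for k in keys])
    w_test = np.array([k[0] in test_set for k in keys])
    seg_label = np.array([1 if dataset.segments[k[0]].label == "preictal" else 0 for k in keys])
    seg_group = np.array([dataset.segments[k[0]].group_id for k in keys])

    return LabeledSplit(
        X_train=X[w_train],
        y_train=seg_label[w_train],
        X_test=X[w_test],
        y_test=seg_label[w_test],
        train_seizure_ids=sorted(train_groups),
        test_seizure_ids=sorted(set(pre_groups) - train_groups),
        test_groups=seg_group[w_test],
        train_mask=w_train,
        test_mask=w_test,
        train_groups=seg_group[w_train],
    )


@dataclass(frozen=True)
class ClassWeights:
    """Inverse-frequency class weights; the weighted class masses are equal."""

    weight_interictal: float
    weight_preictal: float

    def as_dict(self) -> dict[int, float]:
        return {0: self.weight_interictal, 1: self.weight_preictal}


def compute_class_weights(labels: np.ndarray) -> ClassWeights:
    """``w_c = N_total / (2 * N_c)`` for the two classes present in ``labels``."""
    y = np.asarray(labels)
    y = y[y >= 0]
    n0 = int((y == 0).sum())
    n1 = int((y == 1).sum())
    if n0 == 0 or n1 == 0:
        raise DataError("both classes must be present to compute class weights")
    total = n0 + n1
    return ClassWeights(total / (2.0 * n0), total / (2.0 * n1))


@dataclass
class NormalizationParams:
    """Per-feature z-score parameters estimated on training data only."""

    mean: np.ndarray
    std: np.ndarray
    zero_variance: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))


def zscore_fit(X_train: np.ndarray) -> NormalizationParams:
    mean = X_train.mean(axis=0)
    std = X_train.std(axis=0)
    # constant columns carry roundoff-level spread; flag them relative to scale
    zero_variance = std <= 1e-12 * (np.abs(mean) + 1.0)
    return NormalizationParams(mean=mean, std=std, zero_variance=zero_variance)


def zscore_apply(params: NormalizationParams, X: np.ndarray) -> np.ndarray:
    """Standardize with training parameters; constant columns map to zero."""
    safe = np.where(params.std > 0, params.std, 1.0)
    out = (X - params.mean) / safe
    out[:, params.zero_variance] = 0.0
    return out
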