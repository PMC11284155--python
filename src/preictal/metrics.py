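"""Alarm-based and sample-based performance evaluation.

The two evaluation views answer different questions. The alarm view scores
the device behaviour on a continuous timeline: an alarm at time ``t`` is a
true prediction iff a seizure onset falls inside its occurrence window
``[t + SPH, t + SPH + SOP]`` (the seizure must not arrive during the
intervention horizon, and must arrive within the occurrence period);
sensitivity is the fraction of seizures predicted, and the false prediction
rate is false alarms per hour of interictal monitoring. The sample view
ignores time and scores windows like an ordinary classification problem
(sensitivity, specificity, AUC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .exceptions import DataError


@dataclass
class AlarmMetrics:
    """Seizure-wise sensitivity and false-alarm rate of an alarm series."""

    ss_alarm: float | None  # None when the test period contains no seizures
    fpr_per_hour: float
    n_true_alarms: int
    n_false_alarms: int
    n_seizures: int
    interictal_hours: float


@dataclass
class SampleMetrics:
    """Window-wise sensitivity, specificity, and AUC."""

    ss_sample: float
    sp_sample: float
    auc: float | None


def _union_length(intervals: list[tuple[float, float]], lo: float, hi: float) -> float:
    """Total length of the union of intervals clipped to [lo, hi]."""
    clipped = sorted(
        (max(a, lo), min(b, hi)) for a, b in intervals if min(b, hi) > max(a, lo)
    )
    total, cur_lo, cur_hi = 0.0, None, None
    for a, b in clipped:
        if cur_lo is None:
            cur_lo, cur_hi = a, b
        elif a <= cur_hi:
            cur_hi = max(cur_hi, b)
        else:
            total += cur_hi - cur_lo
            cur_lo, cur_hi = a, b
    if cur_lo is not None:
        total += cur_hi - cur_lo
    return total


def alarm_sensitivity(
    alarm_times: np.ndarray,
    onsets: np.ndarray,
    sop_min: float,
    sph_min: float,
    *,
    count_multiple: bool = True,
) -> tuple[float | None, int, int]:
    """Match alarms to onsets; returns (sensitivity, true alarms, false alarms).

    Each seizure counts as predicted at most once. A single alarm whose
    occurrence window contains several onsets predicts each of them when
    ``count_multiple`` (the refractory period makes this rare).
    """
    alarm_times = np.asarray(alarm_times, dtype=float)
    onsets = np.asarray(onsets, dtype=float)
    sph_s, sop_s = sph_min * 60.0, sop_min * 60.0
    predicted: set[int] = set()
    n_true = n_false = 0
    for t in alarm_times:
        hits = np.flatnonzero((onsets >= t + sph_s) & (onsets <= t + sph_s + sop_s))
        if hits.size:
            n_true += 1
            if count_multiple:
                predicted.update(int(i) for i in hits)
            else:
                unseen = [int(i) for i in hits if int(i) not in predicted]
                if unseen:
                    predicted.add(unseen[0])
        else:
            n_false += 1
    ss = len(predicted) / onsets.size if onsets.size else None
    return ss, n_true, n_false


def alarm_metrics(
    alarm_times: np.ndarray,
    onsets: np.ndarray,
    sop_min: float,
    sph_min: float,
    test_start: float,
    test_end: float,
    *,
    offsets: np.ndarray | None = None,
    ictal_blackout: float = 120.0,
    count_multiple: bool = True,
    interictal_denominator: bool = True,
) -> AlarmMetrics:
    """Alarm-view evaluation on a continuous test timeline.

    The FPR/h denominator is interictal time by default: the test duration
    minus the union of the per-seizure preictal spans ``(SOP+SPH)`` and
    ictal+blackout spans (refractory spans are deliberately not excluded —
    conservative). ``interictal_denominator=False`` divides by the full test
    duration instead.
    """
    onsets = np.asarray(onsets, dtype=float)
    offsets = onsets if offsets is None else np.asarray(offsets, dtype=float)
    ss, n_true, n_false = alarm_sensitivity(
        alarm_times, onsets, sop_min, sph_min, count_multiple=count_multiple
    )
    duration = test_end - test_start
    if duration <= 0:
        raise DataError("empty test period")
    if interictal_denominator:
        span = (sop_min + sph_min) * 60.0
        excluded = [(o - span, off + ictal_blackout) for o, off in zip(onsets, offsets)]
        interictal_s = duration - _union_length(excluded, test_start, test_end)
    else:
        interictal_s = duration
    if interictal_s <= 0:
        raise DataError("no interictal time in the test period; FPR/h undefined")
    hours = interictal_s / 3600.0
    return AlarmMetrics(
        ss_alarm=ss,
        fpr_per_hour=n_false / hours,
        n_true_alarms=n_true,
        n_false_alarms=n_false,
        n_seizures=int(onsets.size),
        interictal_hours=hours,
    )


def sample_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, scores: np.ndarray | None = None
) -> SampleMetrics:
    """Window-wise SS, SP from binary outputs; AUC from continuous scores."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if set(np.unique(y_true)) != {0, 1}:
        raise DataError("sample metrics need both classes in the truth labels")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    auc = None if scores is None else float(roc_auc_score(y_true, np.asarray(scores, dtype=float)))
    return SampleMetrics(ss_sample=tp / (tp + fn), sp_sample=tn / (tn + fp), auc=auc)
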