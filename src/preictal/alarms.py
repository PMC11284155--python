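"""Firing Power regularization and refractory-governed alarm generation.

Raw per-window classifier outputs are too noisy to drive an alert device.
The Firing Power statistic smooths them with a causal moving average over
``tau`` windows — the number of windows spanning one preictal period
(SOP+SPH) — so it reads as "fraction of the last preictal-length span
classified preictal". An alarm is raised when the series crosses a threshold
(0.7 by default) from below; after an alarm, a refractory period equal to
the preictal duration suppresses redundant alerts.

Two behaviours the underlying method leaves open are exposed as flags:
whether an alarm requires an upward threshold crossing (default yes), and
whether a still-elevated Firing Power retriggers immediately once the
refractory period expires (default yes, matching sustained-alert device
behaviour).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, DataError

DEFAULT_FP_THRESHOLD = 0.7


@dataclass
class FiringPowerSeries:
    """Moving-average fraction of preictal outputs over the last ``tau`` windows."""

    values: np.ndarray
    tau: int

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class AlarmSeries:
    """Alarm window indices plus the refractory length that governed them."""

    indices: np.ndarray  # window indices into the firing-power series
    refractory_windows: int

    @property
    def n_alarms(self) -> int:
        return len(self.indices)

    def times(self, window_times: np.ndarray) -> np.ndarray:
        """Map alarm window indices onto a timeline of window start times."""
        return np.asarray(window_times, dtype=float)[self.indices]


def firing_power(binary_outputs: np.ndarray, tau: int) -> FiringPowerSeries:
    """Causal moving average of binary outputs with zero-padded warm-up.

    ``fp[n] = (1/tau) * sum_{k=n-tau+1..n} O[k]`` with ``O[k] = 0`` before the
    series starts, so early values ramp up from zero (conservative: the
    warm-up cannot raise alarms by itself). Values lie in [0, 1] and move by
    at most ``1/tau`` per step.
    """
    if tau < 1:
        raise ConfigurationError("tau must be >= 1")
    o = np.asarray(binary_outputs)
    if o.ndim != 1:
        raise DataError("binary outputs must be a 1-D sequence")
    if not np.isin(o, (0, 1)).all():
        raise DataError("firing power expects binary 0/1 outputs")
    cpad = np.concatenate(([0.0], np.cumsum(o, dtype=float)))
    n = len(o)
    lo = np.maximum(0, np.arange(1, n + 1) - tau)
    fp = (cpad[1:] - cpad[lo]) / tau
    return FiringPowerSeries(values=fp, tau=int(tau))


def raise_alarms(
    fp: FiringPowerSeries | np.ndarray,
    threshold: float = DEFAULT_FP_THRESHOLD,
    refractory_windows: int | None = None,
    *,
    require_crossing: bool = True,
    retrigger_after_refractory: bool = True,
) -> AlarmSeries:
    """Threshold the Firing Power series into refractory-respecting alarms.

    An alarm fires at window ``n`` when the series is at or above
    ``threshold``, the previous non-refractory value was below it (upward
    crossing; the value before the series is taken as 0), and ``n`` is
    outside the refractory span of the previous alarm. With
    ``retrigger_after_refractory`` a series still above threshold when the
    refractory period expires fires again immediately. Consecutive alarms are
    always separated by at least ``refractory_windows``.
    """
    if not 0.0 < threshold < 1.0:
        raise ConfigurationError("threshold must lie strictly between 0 and 1")
    values = fp.values if isinstance(fp, FiringPowerSeries) else np.asarray(fp, dtype=float)
    if refractory_windows is None:
        if not isinstance(fp, FiringPowerSeries):
            raise ConfigurationError("refractory_windows required when passing a bare array")
        refractory_windows = fp.tau
    r = int(refractory_windows)

    alarms: list[int] = []
    last: int | None = None
    prev_below = True  # implicit fp[-1] = 0
    for n, v in enumerate(values):
        if last is not None and n < last + r:
            prev_below = v < threshold
            continue
        above = v >= threshold
        exited = last is not None and n == last + r
        crossing = above and prev_below
        if above and (not require_crossing or crossing or (retrigger_after_refractory and exited)):
            alarms.append(n)
            last = n
        prev_below = v < threshold
    return AlarmSeries(indices=np.asarray(alarms, dtype=int), refractory_windows=r)
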