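"""The three epoch noise detectors.

Criterion 1 — sudden amplitude change with recovery failure: consecutive
0.1-s sample differences above a threshold mark an event; the signal base
level over a 1-s window before the event onset is compared with the base
level after its end, and a shift above 0.2 mM·mm means the signal failed to
recover (motion artifact).

Criterion 2 — drifting baseline: the least-squares slope over the 13-s
prestimulus (10-s rest + 3-s instruction); slow physiological oscillations
produce over-threshold slopes.

Criterion 3 — low inter-epoch correlation: each epoch's summed Pearson
correlation with every other retained epoch; epochs whose sum falls below the
one-sided boxplot fence ``Q1 - k·IQR`` are outliers. Unlike criteria 1 and 2
(fixed, per-epoch thresholds), this criterion adapts to the individual
epoch set.

Severity units differ across criteria (mM·mm, mM·mm/s, correlation units);
cross-criterion comparisons must use within-criterion ranks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Criterion1Config",
    "Criterion2Config",
    "Criterion3Config",
    "NoiseFlag",
    "detect_amplitude_jump",
    "detect_baseline_drift",
    "detect_low_correlation",
]


@dataclass(frozen=True)
class Criterion1Config:
    """Sudden amplitude change with recovery failure."""

    jump_threshold: float = 0.047  # mM·mm per consecutive sample pair
    base_window_s: float = 1.0
    recovery_threshold: float = 0.2  # mM·mm base-level shift
    merge_gap: int = 2  # runs separated by < this many samples are one event

    def __post_init__(self) -> None:
        if not (self.jump_threshold > 0 and self.base_window_s > 0
                and self.recovery_threshold > 0):
            raise ValueError("criterion-1 thresholds must be positive")

    criterion = 1


@dataclass(frozen=True)
class Criterion2Config:
    """Excessive prestimulus baseline slope (absolute value)."""

    slope_threshold: float = 0.029  # mM·mm/s

    def __post_init__(self) -> None:
        if not self.slope_threshold > 0:
            raise ValueError("slope_threshold must be > 0")

    criterion = 2


@dataclass(frozen=True)
class Criterion3Config:
    """Inter-epoch correlation-sum outlier fence ``Q1 - k_iqr * IQR``."""

    k_iqr: float = 0.6

    def __post_init__(self) -> None:
        if self.k_iqr < 0:
            raise ValueError("k_iqr must be >= 0")

    criterion = 3


@dataclass(frozen=True)
class NoiseFlag:
    """One (epoch, criterion) detection with a criterion-specific severity."""

    epoch_index: int
    criterion: int
    severity: float
    details: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.severity > 0:
            raise ValueError("flag severity must be > 0")


def _runs_over_threshold(over: np.ndarray, merge_gap: int) -> list[tuple[int, int]]:
    """Contiguous True runs in ``over`` (diff indices), merging gaps < merge_gap.

    Returns (first_diff_index, last_diff_index) pairs.
    """
    idx = np.flatnonzero(over)
    if idx.size == 0:
        return []
    runs: list[tuple[int, int]] = []
    start = prev = int(idx[0])
    for i in idx[1:]:
        i = int(i)
        if i - prev - 1 < merge_gap:  # gap of sub-threshold diffs shorter than merge_gap
            prev = i
        else:
            runs.append((start, prev))
            start = prev = i
    runs.append((start, prev))
    return runs


def detect_amplitude_jump(values: np.ndarray, dt: float,
                          cfg: Criterion1Config = Criterion1Config(),
                          epoch_index: int = 0) -> list[NoiseFlag]:
    """Criterion 1 on one epoch; returns zero or one flag.

    An epoch is flagged when at least one over-threshold amplitude-change
    event fails to recover its base level; severity is the largest absolute
    base-level shift among such events.
    """
    values = np.asarray(values, dtype=float)
    w = max(int(round(cfg.base_window_s / dt)), 1)
    min_w = max(int(round(0.3 / dt)), 1)
    if values.size <= 2 * w:
        raise ValueError("epoch shorter than twice the base window")
    diffs = np.diff(values)
    events = []
    for first, last in _runs_over_threshold(np.abs(diffs) > cfg.jump_threshold,
                                            cfg.merge_gap):
        onset = first          # sample index where the change starts
        ending = last + 1      # first sample after the change
        before = values[max(onset - w, 0):onset]
        after = values[ending:ending + w]
        if before.size < min_w or after.size < min_w:
            logger.warning(
                "epoch %d: criterion-1 base window truncated to %d/%d samples "
                "at epoch edge", epoch_index, min(before.size, after.size), w)
        if before.size == 0:
            before = values[onset:onset + 1]
        if after.size == 0:
            after = values[ending - 1:ending]
        shift = abs(float(after.mean()) - float(before.mean()))
        events.append({"onset": onset, "ending": ending, "base_shift": shift})
    noise_events = [e for e in events if e["base_shift"] > cfg.recovery_threshold]
    if not noise_events:
        return []
    severity = max(e["base_shift"] for e in noise_events)
    return [NoiseFlag(epoch_index=epoch_index, criterion=1, severity=severity,
                      details={"events": noise_events})]


def detect_baseline_drift(values: np.ndarray, times: np.ndarray,
                          cfg: Criterion2Config = Criterion2Config(),
                          epoch_index: int = 0) -> list[NoiseFlag]:
    """Criterion 2 on one epoch: least-squares slope over the prestimulus."""
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    mask = times < -1e-9
    if mask.sum() < 2:
        raise ValueError("prestimulus interval absent or too short")
    slope = float(np.polyfit(times[mask], values[mask], 1)[0])
    if abs(slope) > cfg.slope_threshold:
        return [NoiseFlag(epoch_index=epoch_index, criterion=2,
                          severity=abs(slope), details={"slope": slope})]
    return []


def correlation_sums(values: np.ndarray) -> np.ndarray:
    """Σ over partners of the Pearson correlation, per epoch (row).

    Rows with zero variance correlate 0 with every partner — a flat-lined
    segment is maximally non-similar under the sum statistic rather than
    undefined.
    """
    values = np.asarray(values, dtype=float)
    m = values.shape[0]
    sd = values.std(axis=1)
    ok = sd > 0
    corr = np.zeros((m, m))
    if ok.sum() >= 2:
        sub = np.corrcoef(values[ok])
        corr[np.ix_(ok, ok)] = np.atleast_2d(sub)
    np.fill_diagonal(corr, 0.0)
    return corr.sum(axis=1)


def detect_low_correlation(values: np.ndarray,
                           cfg: Criterion3Config = Criterion3Config(),
                           epoch_indices: Sequence[int] | None = None
                           ) -> list[NoiseFlag]:
    """Criterion 3 on a set of (retained) epochs.

    ``values`` is ``(n_epochs, n_times)``; ``epoch_indices`` maps rows back to
    original epoch numbers. With fewer than 3 epochs the criterion is skipped
    (logged). Quartiles use linear interpolation between order statistics;
    the fence is one-sided low and the comparison strict, so a degenerate
    IQR of 0 flags nothing when all sums are equal.
    """
    values = np.asarray(values, dtype=float)
    m = values.shape[0]
    if epoch_indices is None:
        epoch_indices = list(range(m))
    if m < 3:
        logger.info("criterion 3 skipped: only %d epochs (need >= 3)", m)
        return []
    sums = correlation_sums(values)
    q1, q3 = np.percentile(sums, [25, 75], method="linear")
    fence = q1 - cfg.k_iqr * (q3 - q1)
    flags = []
    for row, s in enumerate(sums):
        if s < fence:
            flags.append(NoiseFlag(epoch_index=int(epoch_indices[row]), criterion=3,
                                   severity=float(fence - s),
                                   details={"sum": float(s), "fence": float(fence)}))
    return flags
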