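"""Core domain types for block-design fNIRS recordings.

A recording lives on a uniform sampling grid (10 Hz by convention for the
continuous-wave instruments this package targets). A session follows a block
design: repeated baseline–instruction–stimulus cycles, each of which yields one
*epoch* — the time-locked segment that is the unit of rejection and averaging.

Epoch windows are half-open ``[onset - pre_s, onset + stim_s + post_s)`` in
samples, so non-overlapping windows concatenate back to the original samples
exactly. Trial onsets are snapped to the nearest grid sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "SamplingGrid",
    "BlockDesign",
    "ContinuousRecording",
    "Epoch",
    "EpochSet",
    "time_index",
    "SIGNAL_TYPES",
]

SIGNAL_TYPES = ("O2Hb", "HHb", "HbTotal")


@dataclass(frozen=True)
class SamplingGrid:
    """Uniform time grid: sample ``i`` sits at ``i * dt`` seconds."""

    dt: float = 0.1
    n_samples: int = 1

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.n_samples < 1:
            raise ValueError(f"n_samples must be >= 1, got {self.n_samples}")

    @property
    def duration(self) -> float:
        """Time of the last sample, ``(n_samples - 1) * dt``."""
        return (self.n_samples - 1) * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt

    @property
    def fs(self) -> float:
        return 1.0 / self.dt


def time_index(grid: SamplingGrid, t: float) -> int:
    """Nearest-sample index of time ``t`` on ``grid``.

    Ties (t exactly between two samples) resolve round-half-even. Raises
    :class:`ValueError` when ``t`` lies outside ``[0, (n_samples-1)*dt]``
    beyond float tolerance.
    """
    if t < -1e-9 or t > grid.duration + 1e-9:
        raise ValueError(
            f"t={t} outside grid range [0, {grid.duration}]"
        )
    # round the ratio first to kill float-division dust (0.45/0.1 -> 4.5 exactly)
    ratio = np.round(t / grid.dt, 9)
    idx = int(np.rint(ratio))
    return min(max(idx, 0), grid.n_samples - 1)


@dataclass(frozen=True)
class BlockDesign:
    """Timing grammar of one block-design session.

    Parameters
    ----------
    n_trials:
        Number of baseline–instruction–stimulus repetitions (epochs).
    pre_s:
        Prestimulus seconds included in each epoch window; by convention
        13 s = 10 s baseline + 3 s instruction.
    baseline_s:
        Leading portion of the prestimulus used for baseline zeroing and as
        the reference interval of the SNR statistic.
    stim_s:
        Stimulus duration.
    post_s:
        Poststimulus seconds included in each epoch window.
    sim_pre_post_s:
        Inter-trial spacing used when *synthesising* recordings (the gap
        between one stimulus end and the next stimulus onset). 26 s keeps
        adjacent 13 s post + 13 s pre windows exactly abutting.
    """

    n_trials: int = 6
    pre_s: float = 13.0
    baseline_s: float = 10.0
    stim_s: float = 24.0
    post_s: float = 13.0
    sim_pre_post_s: float = 26.0
    activation_onset_s: float = 4.0  # activation interval starts this long after stimulus onset

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        for name in ("pre_s", "baseline_s", "stim_s", "post_s", "sim_pre_post_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.baseline_s > self.pre_s:
            raise ValueError("baseline_s must not exceed pre_s")
        if not 0 <= self.activation_onset_s < self.stim_s:
            raise ValueError("activation_onset_s must lie within the stimulus")

    @property
    def epoch_duration(self) -> float:
        return self.pre_s + self.stim_s + self.post_s

    def epoch_n_samples(self, dt: float) -> int:
        return int(round(self.epoch_duration / dt))

    def sim_onsets(self) -> np.ndarray:
        """Stimulus-onset times used by the synthetic generator."""
        period = self.stim_s + self.sim_pre_post_s
        return self.sim_pre_post_s + period * np.arange(self.n_trials)

    def sim_grid(self, dt: float = 0.1) -> SamplingGrid:
        """Grid long enough to hold ``n_trials`` blocks plus trailing window."""
        total = self.sim_pre_post_s + self.n_trials * (self.stim_s + self.sim_pre_post_s)
        return SamplingGrid(dt=dt, n_samples=int(round(total / dt)))


@dataclass
class ContinuousRecording:
    """Multichannel hemoglobin time series (mM·mm) with trial onsets."""

    grid: SamplingGrid
    channels: list[str]
    signal_type: str
    values: np.ndarray  # (n_channels, n_samples)
    trial_onsets: np.ndarray  # seconds

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.trial_onsets = np.asarray(self.trial_onsets, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a channel x time matrix")
        if self.values.shape != (len(self.channels), self.grid.n_samples):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.channels)} channels x {self.grid.n_samples} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if self.signal_type not in SIGNAL_TYPES:
            raise ValueError(f"signal_type must be one of {SIGNAL_TYPES}")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def channel_values(self, channel: str) -> np.ndarray:
        return self.values[self.channels.index(channel)]

    def replace_values(self, values: np.ndarray) -> "ContinuousRecording":
        return ContinuousRecording(
            grid=self.grid,
            channels=list(self.channels),
            signal_type=self.signal_type,
            values=values,
            trial_onsets=self.trial_onsets.copy(),
        )


@dataclass(frozen=True)
class Epoch:
    """One trial's time-locked segment for a single channel."""

    index: int
    channel: str
    times: np.ndarray  # seconds relative to stimulus onset
    values: np.ndarray


@dataclass
class EpochSet:
    """All epochs of one channel / signal type, with a retained mask.

    ``values`` is an ``(n_epochs, n_times)`` matrix; ``times`` is the shared
    axis in seconds relative to stimulus onset (from ``-pre_s``).
    """

    design: BlockDesign
    channel: str
    signal_type: str
    times: np.ndarray
    values: np.ndarray
    retained: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != self.times.size:
            raise ValueError("values must be (n_epochs, n_times) matching times")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if self.retained is None:
            self.retained = np.ones(self.values.shape[0], dtype=bool)
        else:
            self.retained = np.asarray(self.retained, dtype=bool)
            if self.retained.shape != (self.values.shape[0],):
                raise ValueError("retained mask must have one entry per epoch")

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else 0.1

    @property
    def retained_indices(self) -> np.ndarray:
        return np.flatnonzero(self.retained)

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    def epochs(self) -> Iterator[Epoch]:
        for i in range(self.n_epochs):
            yield Epoch(index=i, channel=self.channel, times=self.times,
                        values=self.values[i])

    def retained_values(self) -> np.ndarray:
        return self.values[self.retained]

    def copy(self) -> "EpochSet":
        return EpochSet(
            design=self.design,
            channel=self.channel,
            signal_type=self.signal_type,
            times=self.times.copy(),
            values=self.values.copy(),
            retained=self.retained.copy(),
        )

    def with_retained(self, retained: Sequence[int] | np.ndarray) -> "EpochSet":
        out = self.copy()
        mask = np.zeros(self.n_epochs, dtype=bool)
        mask[np.asarray(retained, dtype=int)] = True
        out.retained = mask
        return out
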