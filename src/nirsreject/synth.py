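"""Synthetic block-design fNIRS signal generator with ground-truth annotations.

The clean ("noise-free model") signal is the sum of three components:

* a task response: a gamma-function hemodynamic response ``h(t)`` convolved
  with a six-trial boxcar whose amplitude is a Gaussian draw,
* band-limited physiological noise: zero-mean Gaussian, SD 1/6, shaped by a
  fourth-order Butterworth band-pass at 0.08–0.15 Hz (slow oscillations /
  Mayer-wave band),
* white machine noise whose SD is set so the 20·log10(μ/σ) signal-to-noise
  ratio matches a requested value in dB.

The "noise model" variant additionally injects motion-like events with
per-trial ground truth: recovered spikes (rebound step convolved with the HRF
first derivative), non-recovery spikes (same, with the derivative kernel
modified so its tail settles at a negative offset), and prestimulus baseline
shifts (a ramp over the 13-s prestimulus that holds its end value).

All randomness flows through a single :class:`numpy.random.Generator`;
identical parameters and seed give bit-identical recordings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .design import BlockDesign, ContinuousRecording, SamplingGrid

__all__ = [
    "HRFParams",
    "BoxcarParams",
    "NoiseModelParams",
    "NoiseEvent",
    "GroundTruth",
    "gamma_hrf",
    "gamma_hrf_derivative",
    "first_derivative_nonrecovery",
    "spike_kernel",
    "task_response",
    "physiological_noise",
    "machine_noise",
    "generate_recording",
]

EVENT_TYPES = ("spike", "nonrecovery_spike", "baseline_shift")
# spike vs shift equally likely; recovered/non-recovered split the spike half
_EVENT_WEIGHTS = {"spike": 0.25, "nonrecovery_spike": 0.25, "baseline_shift": 0.5}


def _rng(seed: int | np.random.Generator | np.random.SeedSequence | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class HRFParams:
    """Gamma-function HRF: ``h(t) = (t/tau)^(n-1) e^(-t/tau) / ((n-1)! tau)``."""

    tau: float = 1.08
    n: int = 3

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("tau must be > 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")

    @property
    def peak_time(self) -> float:
        """Analytic argmax, ``tau * (n - 1)``."""
        return self.tau * (self.n - 1)

    @property
    def support(self) -> float:
        """Duration after which the kernel is numerically negligible."""
        return 6.0 * self.tau * self.n


@dataclass(frozen=True)
class BoxcarParams:
    """Per-trial stimulus amplitude model.

    ``mean_amp`` reflects the activation scale observed in real data
    (0.14–0.30 mM·mm); ``sd_amp`` its dispersion. When ``ratio`` is given,
    ``sd_amp`` is derived as ``mean_amp / ratio``. By default one amplitude
    draw is shared by all trials of a signal (``per_trial=False``); the
    ratio μ/σ is then the asymptotic detectability of the signal.
    """

    mean_amp: float = 0.22
    sd_amp: float = 0.0
    ratio: float | None = None
    per_trial: bool = False

    def __post_init__(self) -> None:
        if self.mean_amp < 0:
            raise ValueError("mean_amp must be >= 0")
        if self.ratio is not None:
            if not self.ratio > 0:
                raise ValueError("ratio must be > 0")
            object.__setattr__(self, "sd_amp", self.mean_amp / self.ratio)
        if self.sd_amp < 0:
            raise ValueError("sd_amp must be >= 0")


@dataclass(frozen=True)
class NoiseModelParams:
    """Configuration of the physiological, machine, and event noise models."""

    spike_peak: tuple[float, float] | float = (0.14, 0.48)  # mM·mm, uniform draw
    shift_slope_mean: float = 0.025  # mM·mm/s
    shift_slope_sd: float = 0.0125
    max_noise_events: int = 6
    phys_sd: float = 1.0 / 6.0
    phys_band: tuple[float, float] = (0.08, 0.15)
    phys_order: int = 4
    snr_db: float = 10.0
    snr_reference_amp: float = 0.22  # SNR calibration scale when mean_amp == 0
    rebound_width_s: float = 1.0
    event_margin_s: float = 2.0
    event_types: tuple[str, ...] = EVENT_TYPES

    def __post_init__(self) -> None:
        peak = self.spike_peak
        if np.isscalar(peak):
            object.__setattr__(self, "spike_peak", (float(peak), float(peak)))
        lo, hi = self.spike_peak
        if not (0 < lo <= hi):
            raise ValueError("spike_peak range must be positive and ordered")
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")
        if self.max_noise_events < 0:
            raise ValueError("max_noise_events must be >= 0")
        for t in self.event_types:
            if t not in EVENT_TYPES:
                raise ValueError(f"unknown event type {t!r}")


@dataclass(frozen=True)
class NoiseEvent:
    """One injected artifact, annotated in ground truth."""

    trial: int
    type: str
    time_s: float  # event onset in recording time
    magnitude: float  # spike extremum (signed) or baseline slope (signed)


@dataclass
class GroundTruth:
    """Per-trial annotations plus the noise-free task component."""

    events: list[NoiseEvent]
    clean: np.ndarray  # bool per trial
    amplitudes: np.ndarray  # drawn boxcar amplitude per trial
    task_signal: np.ndarray  # noise-free h*b component on the recording grid

    @property
    def n_events(self) -> int:
        return len(self.events)

    def noisy_trials(self) -> np.ndarray:
        return np.flatnonzero(~self.clean)


# ---------------------------------------------------------------------------
# kernels


def gamma_hrf(grid: SamplingGrid, params: HRFParams = HRFParams()) -> np.ndarray:
    """Sample the gamma-function HRF on ``grid``.

    Nonnegative with a single interior maximum at ``tau*(n-1)`` (0 at the
    origin for n > 1). Requires the grid to cover the kernel support
    (``6*tau*n`` seconds) so convolutions do not truncate it.
    """
    if grid.duration < params.support - 1e-9:
        raise ValueError(
            f"grid covers {grid.duration:.2f}s < kernel support {params.support:.2f}s"
        )
    t = grid.times
    n, tau = params.n, params.tau
    return (t / tau) ** (n - 1) * np.exp(-t / tau) / (math.factorial(n - 1) * tau)


def gamma_hrf_derivative(grid: SamplingGrid, params: HRFParams = HRFParams()) -> np.ndarray:
    """Analytic first derivative of the gamma HRF."""
    if grid.duration < params.support - 1e-9:
        raise ValueError("grid shorter than kernel support")
    t = grid.times
    n, tau = params.n, params.tau
    norm = math.factorial(n - 1) * tau
    with np.errstate(divide="ignore", invalid="ignore"):
        poly = (n - 1) * (t / tau) ** (n - 2) / tau - (t / tau) ** (n - 1) / tau
    if n >= 2:
        poly = np.where(t == 0, (n - 1) / tau if n == 2 else 0.0, poly)
    return poly * np.exp(-t / tau) / norm


def first_derivative_nonrecovery(
    grid: SamplingGrid, params: HRFParams = HRFParams()
) -> np.ndarray:
    """HRF first derivative modified to model a non-recovery spike.

    Up to its maximum the kernel equals ``h'(t)``; beyond it the kernel is
    ``2*h'(t) - max h'``, so it is continuous at the splice and settles at
    ``-max h'`` as ``h' -> 0``. Convolving a rebound step with this kernel
    leaves a lasting baseline offset instead of recovering.
    """
    d = gamma_hrf_derivative(grid, params)
    i_max = int(np.argmax(d))
    peak = d[i_max]
    out = d.copy()
    out[i_max:] = 2.0 * d[i_max:] - peak
    return out


def spike_kernel(
    dt: float,
    params: HRFParams = HRFParams(),
    *,
    recovers: bool = True,
    rebound_width_s: float = 1.0,
) -> np.ndarray:
    """Spike waveform: rebound step convolved with (modified) ``h'``.

    Returned with unit extremum (max |value| = 1); callers scale by the
    signed peak. For ``recovers=False`` the tail holds a negative offset.
    """
    kgrid = SamplingGrid(dt=dt, n_samples=int(np.ceil(params.support / dt)) + 1)
    deriv = (
        gamma_hrf_derivative(kgrid, params)
        if recovers
        else first_derivative_nonrecovery(kgrid, params)
    )
    step = np.ones(max(int(round(rebound_width_s / dt)), 1))
    # truncate the trailing partial overlap so the last sample is the
    # settled value (0 recovered, the lasting offset non-recovered)
    k = (np.convolve(step, deriv) * dt)[: deriv.size]
    extremum = np.max(np.abs(k))
    if extremum == 0:
        raise ValueError("degenerate spike kernel")
    return k / extremum


# ---------------------------------------------------------------------------
# signal components


def _hrf_convolution_kernel(dt: float, params: HRFParams) -> np.ndarray:
    """Discrete HRF kernel normalized to unit sum.

    Unit-sum normalization makes the convolution of a long boxcar of
    amplitude ``a`` plateau at exactly ``a``, so the drawn amplitude is the
    activation scale entering the SNR and power calculations.
    """
    kgrid = SamplingGrid(dt=dt, n_samples=int(np.ceil(params.support / dt)) + 1)
    h = gamma_hrf(kgrid, params)
    return h / h.sum()


def task_response(
    design: BlockDesign,
    box: BoxcarParams = BoxcarParams(),
    hrf: HRFParams = HRFParams(),
    seed: int | np.random.Generator | None = None,
    *,
    dt: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Task-related signal: boxcar convolved with the unit-sum HRF kernel.

    Returns ``(signal, amplitudes)`` where ``amplitudes`` holds the per-trial
    boxcar amplitudes actually drawn (a single shared draw unless
    ``box.per_trial``).
    """
    rng = _rng(seed)
    grid = design.sim_grid(dt)
    if box.per_trial:
        amps = rng.normal(box.mean_amp, box.sd_amp, size=design.n_trials)
    else:
        amps = np.full(design.n_trials, rng.normal(box.mean_amp, box.sd_amp))
    boxcar = np.zeros(grid.n_samples)
    n_stim = int(round(design.stim_s / dt))
    for i, onset in enumerate(design.sim_onsets()):
        i0 = int(round(onset / dt))
        boxcar[i0 : i0 + n_stim] = amps[i]
    kernel = _hrf_convolution_kernel(dt, hrf)
    sig = np.convolve(boxcar, kernel)[: grid.n_samples]
    return sig, amps


def physiological_noise(
    grid: SamplingGrid,
    phys_sd: float = 1.0 / 6.0,
    band: tuple[float, float] = (0.08, 0.15),
    order: int = 4,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Band-limited Gaussian noise emulating slow physiological oscillations.

    White zero-mean Gaussian noise (SD ``phys_sd``) shaped by a causal
    Butterworth band-pass (``order`` given to the design call).
    """
    lo, hi = band
    nyq = 0.5 / grid.dt
    if not 0 < lo < hi < nyq:
        raise ValueError(f"band {band} must satisfy 0 < low < high < Nyquist={nyq}")
    rng = _rng(seed)
    white = rng.normal(0.0, phys_sd, size=grid.n_samples)
    if phys_sd == 0:
        return white
    sos = sps.butter(order, band, btype="bandpass", fs=grid.fs, output="sos")
    return sps.sosfilt(sos, white)


def machine_noise(
    grid: SamplingGrid,
    snr_db: float,
    activation_mean: float,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """White Gaussian instrument noise calibrated to a target SNR.

    The SD solves ``snr_db = 20 log10(activation_mean / sd)``, i.e. the SNR
    statistic evaluated with the activation scale as μ and this noise as σ.
    """
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite")
    if not activation_mean > 0:
        raise ValueError("activation_mean must be > 0")
    sd = activation_mean / 10.0 ** (snr_db / 20.0)
    return _rng(seed).normal(0.0, sd, size=grid.n_samples)


# ---------------------------------------------------------------------------
# full recordings


def _draw_events(
    design: BlockDesign,
    noise: NoiseModelParams,
    rng: np.random.Generator,
    n_events: int | None,
    dt: float,
) -> list[NoiseEvent]:
    max_events = min(noise.max_noise_events, design.n_trials)
    if n_events is None:
        n_events = int(rng.integers(0, max_events + 1))
    if n_events > max_events:
        raise ValueError(f"n_events={n_events} exceeds max {max_events}")
    trials = np.sort(rng.choice(design.n_trials, size=n_events, replace=False))
    onsets = design.sim_onsets()
    types = list(noise.event_types)
    w = np.array([_EVENT_WEIGHTS[t] for t in types])
    w = w / w.sum()
    events: list[NoiseEvent] = []
    for trial in trials:
        etype = types[int(rng.choice(len(types), p=w))]
        onset = onsets[trial]
        if etype == "baseline_shift":
            t0 = onset - design.pre_s  # ramp spans the full prestimulus
            slope = max(rng.normal(noise.shift_slope_mean, noise.shift_slope_sd), 1e-3)
            mag = slope * (1.0 if rng.random() < 0.5 else -1.0)
        else:
            win_lo = onset - design.pre_s + noise.event_margin_s
            win_hi = onset + design.stim_s + design.post_s - noise.event_margin_s
            t0 = rng.uniform(win_lo, win_hi)
            lo, hi = noise.spike_peak
            peak = rng.uniform(lo, hi)
            mag = peak * (1.0 if rng.random() < 0.5 else -1.0)
        events.append(NoiseEvent(trial=int(trial), type=etype, time_s=float(t0),
                                 magnitude=float(mag)))
    return events


def _render_events(
    events: Sequence[NoiseEvent],
    design: BlockDesign,
    noise: NoiseModelParams,
    hrf: HRFParams,
    grid: SamplingGrid,
) -> np.ndarray:
    dt = grid.dt
    out = np.zeros(grid.n_samples)
    onsets = design.sim_onsets()
    for ev in events:
        i0 = int(round(ev.time_s / dt))
        # the event perturbs its own trial's epoch: shifted levels persist to
        # the end of the epoch window and the next epoch starts re-settled
        win_end = min(
            int(round((onsets[ev.trial] + design.stim_s + design.post_s) / dt)),
            grid.n_samples,
        )
        if ev.type == "baseline_shift":
            # slope added in the baseline (prestimulus) interval only
            n_ramp = int(round(design.pre_s / dt))
            ramp = ev.magnitude * dt * np.arange(n_ramp)
            end = min(i0 + n_ramp, win_end)
            out[i0:end] += ramp[: end - i0]
        else:
            k = ev.magnitude * spike_kernel(
                dt, hrf, recovers=(ev.type == "spike"),
                rebound_width_s=noise.rebound_width_s,
            )
            end = min(i0 + k.size, win_end)
            out[i0:end] += k[: end - i0]
            if ev.type == "nonrecovery_spike" and end < win_end:
                out[end:win_end] += k[-1]  # hold the non-recovered offset
    return out


def generate_recording(
    design: BlockDesign = BlockDesign(),
    box: BoxcarParams = BoxcarParams(),
    hrf: HRFParams = HRFParams(),
    noise: NoiseModelParams = NoiseModelParams(),
    with_synthetic_noise: bool = False,
    seed: int | np.random.Generator | None = None,
    *,
    n_events: int | None = None,
    dt: float = 0.1,
    channel: str = "CH1",
    signal_type: str = "O2Hb",
) -> tuple[ContinuousRecording, GroundTruth]:
    """Generate one synthetic recording and its ground truth.

    The signal is ``f(t) = (h*b)(t) + p(t) + m(t)`` plus, when
    ``with_synthetic_noise`` is set, the rendered spike / baseline-shift
    events. ``n_events`` forces the event count (default: uniform draw over
    ``0..max_noise_events``, at most one event per trial).
    """
    rng = _rng(seed)
    grid = design.sim_grid(dt)
    task, amps = task_response(design, box, hrf, rng, dt=dt)
    p = physiological_noise(grid, noise.phys_sd, noise.phys_band, noise.phys_order, rng)
    ref_amp = box.mean_amp if box.mean_amp > 0 else noise.snr_reference_amp
    m = machine_noise(grid, noise.snr_db, ref_amp, rng)
    values = task + p + m

    events: list[NoiseEvent] = []
    if with_synthetic_noise:
        events = _draw_events(design, noise, rng, n_events, dt)
        values = values + _render_events(events, design, noise, hrf, grid)

    clean = np.ones(design.n_trials, dtype=bool)
    for ev in events:
        clean[ev.trial] = False
    recording = ContinuousRecording(
        grid=grid,
        channels=[channel],
        signal_type=signal_type,
        values=values[np.newaxis, :],
        trial_onsets=design.sim_onsets(),
    )
    truth = GroundTruth(events=events, clean=clean, amplitudes=amps, task_signal=task)
    return recording, truth
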