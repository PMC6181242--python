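import numpy as np
import pytest
from scipy import signal as sps

from nirsreject.design import BlockDesign, SamplingGrid
from nirsreject.preprocess import compute_snr, extract_epochs
from nirsreject.synth import (
    BoxcarParams,
    HRFParams,
    NoiseModelParams,
    first_derivative_nonrecovery,
    gamma_hrf,
    gamma_hrf_derivative,
    generate_recording,
    machine_noise,
    physiological_noise,
    spike_kernel,
    task_response,
)

DENSE = SamplingGrid(dt=0.01, n_samples=4001)  # 40 s at 100 Hz


class TestGammaHRF:
    def test_zero_at_origin(self):
        h = gamma_hrf(DENSE)
        assert h[0] == 0.0

    def test_peak_location_and_value(self):
        # analytic argmax tau*(n-1) = 2.16 s; value 2^2 e^-2 / (2 * 1.08)
        h = gamma_hrf(DENSE)
        t_peak = DENSE.times[np.argmax(h)]
        assert t_peak == pytest.approx(2.16, abs=DENSE.dt)
        expected = 4.0 * np.exp(-2.0) / (2.0 * 1.08)
        assert h[216] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.2506, abs=5e-5)

    def test_nonnegative_single_interior_max(self):
        h = gamma_hrf(DENSE)
        assert np.all(h >= 0)
        d = np.diff(h)
        # rises then falls: exactly one sign change of the derivative
        assert np.sum((d[:-1] > 0) & (d[1:] <= 0)) == 1

    def test_parameter_errors(self):
        with pytest.raises(ValueError):
            HRFParams(tau=0.0)
        with pytest.raises(ValueError):
            HRFParams(n=0)
        with pytest.raises(ValueError):
            gamma_hrf(SamplingGrid(0.1, 10))  # grid shorter than support


class TestNonrecoveryKernel:
    def test_unchanged_up_to_derivative_peak(self):
        d = gamma_hrf_derivative(DENSE)
        mod = first_derivative_nonrecovery(DENSE)
        i_max = int(np.argmax(d))
        assert np.array_equal(mod[: i_max + 1], d[: i_max + 1])
        # continuity at the splice point: 2*max - max = max
        assert mod[i_max] == d[i_max]

    def test_tail_settles_at_minus_peak(self):
        d = gamma_hrf_derivative(DENSE)
        mod = first_derivative_nonrecovery(DENSE)
        assert mod[-1] == pytest.approx(-np.max(d), rel=1e-6)

    def test_unmodified_derivative_integrates_to_zero(self):
        # h starts and ends at ~0, so its derivative integrates to ~0
        # (residual is the support-truncation error of the gamma tail)
        d = gamma_hrf_derivative(DENSE)
        assert np.trapezoid(d, DENSE.times) == pytest.approx(0.0, abs=1e-4)

    def test_spike_kernel_shapes(self):
        k_rec = spike_kernel(0.1, recovers=True)
        k_non = spike_kernel(0.1, recovers=False)
        assert np.max(np.abs(k_rec)) == pytest.approx(1.0)
        assert np.max(np.abs(k_non)) == pytest.approx(1.0)
        assert abs(k_rec[-1]) < 1e-4          # recovered: returns to ~zero
        assert k_non[-1] < -0.1               # non-recovered: lasting offset


class TestTaskResponse:
    def test_plateau_equals_drawn_amplitude(self):
        design = BlockDesign()
        sig, amps = task_response(design, BoxcarParams(mean_amp=0.2, sd_amp=0.0),
                                  seed=0)
        assert np.allclose(amps, 0.2)
        n = int(round(0.1 ** -1))
        for onset in design.sim_onsets():
            i0 = int(round(onset / 0.1))
            i1 = i0 + int(round(design.stim_s / 0.1))
            peak = sig[i0:i1].max()
            assert peak == pytest.approx(0.2, rel=0.02)

    def test_zero_mean_amp_gives_zero_signal(self):
        sig, _ = task_response(BlockDesign(), BoxcarParams(mean_amp=0.0, sd_amp=0.0),
                               seed=0)
        assert np.allclose(sig, 0.0)

    def test_shared_vs_per_trial_amplitudes(self):
        box_shared = BoxcarParams(mean_amp=0.2, ratio=2.0)
        _, amps = task_response(BlockDesign(), box_shared, seed=3)
        assert np.unique(amps).size == 1
        box_trial = BoxcarParams(mean_amp=0.2, ratio=2.0, per_trial=True)
        _, amps_t = task_response(BlockDesign(), box_trial, seed=3)
        assert np.unique(amps_t).size == 6

    def test_ratio_sets_sd(self):
        box = BoxcarParams(mean_amp=0.2, ratio=2.0)
        assert box.sd_amp == pytest.approx(0.1)


class TestPhysiologicalNoise:
    def test_band_limited_spectrum(self):
        grid = SamplingGrid(0.1, 200_000)
        p = physiological_noise(grid, seed=0)
        f, pxx = sps.welch(p, fs=10.0, nperseg=8192)
        in_band = pxx[np.argmin(np.abs(f - 0.115))]
        out_band = pxx[np.argmin(np.abs(f - 0.4))]
        assert out_band / in_band < 0.01

    def test_zero_mean(self):
        grid = SamplingGrid(0.1, 100_000)
        p = physiological_noise(grid, seed=1)
        assert abs(p.mean()) < 3 * p.std() / np.sqrt(p.size)

    def test_seeded_determinism(self):
        grid = SamplingGrid(0.1, 1000)
        a = physiological_noise(grid, seed=42)
        b = physiological_noise(grid, seed=42)
        assert np.array_equal(a, b)

    def test_invalid_band(self):
        with pytest.raises(ValueError):
            physiological_noise(SamplingGrid(0.1, 100), band=(0.2, 6.0), seed=0)


class TestMachineNoise:
    @pytest.mark.parametrize("snr_db,sigma", [(0.0, 0.2), (20.0, 0.02), (-40.0, 20.0)])
    def test_sd_inverts_snr_formula(self, snr_db, sigma):
        grid = SamplingGrid(0.1, 200_000)
        m = machine_noise(grid, snr_db, activation_mean=0.2, seed=0)
        assert m.std() == pytest.approx(sigma, rel=0.02)

    def test_rejects_bad_params(self):
        grid = SamplingGrid(0.1, 100)
        with pytest.raises(ValueError):
            machine_noise(grid, np.inf, 0.2)
        with pytest.raises(ValueError):
            machine_noise(grid, 0.0, 0.0)


class TestGenerateRecording:
    def test_no_noise_flag_gives_clean_ground_truth(self):
        _, truth = generate_recording(with_synthetic_noise=False, seed=0)
        assert truth.n_events == 0
        assert truth.clean.all()

    def test_forced_full_occupancy_marks_all_trials(self):
        _, truth = generate_recording(with_synthetic_noise=True, seed=1, n_events=6)
        assert truth.n_events == 6
        assert not truth.clean.any()

    def test_seeded_determinism_bit_identical(self):
        rec_a, _ = generate_recording(with_synthetic_noise=True, seed=9)
        rec_b, _ = generate_recording(with_synthetic_noise=True, seed=9)
        assert np.array_equal(rec_a.values, rec_b.values)

    def test_events_lie_in_their_trial_windows(self):
        design = BlockDesign()
        for seed in range(10):
            _, truth = generate_recording(design, with_synthetic_noise=True,
                                          seed=seed, n_events=6)
            onsets = design.sim_onsets()
            for ev in truth.events:
                lo = onsets[ev.trial] - design.pre_s
                hi = onsets[ev.trial] + design.stim_s + design.post_s
                assert lo - 1e-9 <= ev.time_s < hi + 1e-9

    def test_injected_baseline_shift_slope_recovers(self):
        """Least-squares fits on the raw prestimulus recover the 0.025 slope.

        Individual fits carry physiological/machine-noise error (~±0.01
        mM·mm/s at 3 SE over a 13-s window); the signed-magnitude-aligned
        mean over events must land within 20% of the injected slope.
        """
        design = BlockDesign()
        noise = NoiseModelParams(event_types=("baseline_shift",), shift_slope_sd=0.0)
        aligned = []
        for seed in range(8):
            rec, truth = generate_recording(
                design, BoxcarParams(mean_amp=0.22, ratio=2.0), noise=noise,
                with_synthetic_noise=True, seed=seed, n_events=6)
            t = rec.grid.times
            for ev in truth.events:
                onset = design.sim_onsets()[ev.trial]
                mask = (t >= onset - design.pre_s) & (t < onset)
                slope = np.polyfit(t[mask], rec.values[0, mask], 1)[0]
                assert abs(ev.magnitude) == pytest.approx(0.025, rel=1e-9)
                assert slope == pytest.approx(ev.magnitude, abs=0.012)
                aligned.append(slope * np.sign(ev.magnitude))
        assert len(aligned) == 48
        assert np.mean(aligned) == pytest.approx(0.025, rel=0.2)


class TestSNRRoundTrip:
    """Requested SNR matches the measured Eq.-style SNR on generated epochs.

    μ and σ are pooled over all epochs' activation/baseline samples of the
    raw (unpreprocessed) recording; at -20 dB a 600-trial record is used so
    the μ estimator error (~3%) stays well under the 1 dB check.
    """

    @staticmethod
    def _measure(design, snr_db):
        box = BoxcarParams(mean_amp=0.22, sd_amp=0.0)
        noise = NoiseModelParams(phys_sd=0.0, snr_db=snr_db)
        rec, _ = generate_recording(design, box, noise=noise, seed=5)
        es = extract_epochs(rec, design)["CH1"]
        t = es.times
        act = (t >= design.activation_onset_s) & (t < design.stim_s)
        base = (t >= -design.baseline_s) & (t < 0)
        mu = es.values[:, act].mean()
        sd = es.values[:, base].std(ddof=1)
        return 20.0 * np.log10(mu / sd)

    @pytest.mark.parametrize("snr_db", [0.0, 20.0])
    def test_six_trials(self, snr_db):
        assert self._measure(BlockDesign(), snr_db) == pytest.approx(snr_db, abs=1.0)

    def test_minus_twenty_long_record(self):
        design = BlockDesign(n_trials=600)
        assert self._measure(design, -20.0) == pytest.approx(-20.0, abs=1.0)


class TestSNRComputation:
    def test_on_generated_epoch_average(self):
        """compute_snr agrees with a direct evaluation on a clean average."""
        design = BlockDesign()
        box = BoxcarParams(mean_amp=0.22, sd_amp=0.0)
        noise = NoiseModelParams(phys_sd=0.0, snr_db=0.0)
        rec, _ = generate_recording(design, box, noise=noise, seed=2)
        es = extract_epochs(rec, design)["CH1"]
        avg = es.values.mean(axis=0)
        snr = compute_snr(avg, es.times, design)
        # averaging 6 epochs improves SNR by 10*log10(6) ~ 7.8 dB
        assert snr.value == pytest.approx(0.0 + 10 * np.log10(6), abs=1.5)
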