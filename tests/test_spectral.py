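"""DC correction, constrained time-domain fitting, series quantification and
summed-window ratios."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiodnp.acquisition import (
    AcquisitionParams,
    C1_SHIFTS_HZ,
    C2_SHIFTS_HZ,
    MetabolitePeakSpec,
    peaks_from_shifts,
)
from cardiodnp.errors import NoSignalError, ValidationError
from cardiodnp.fid import FidSeries
from cardiodnp.spectral import (
    PeakPrior,
    dc_offset_correct,
    fit_spectrum,
    priors_from_shifts,
    quantify_series,
    sum_window_ratios,
)
from cardiodnp.synthetic import (
    KineticGroundTruth,
    render_fids,
    simulate_kinetics,
)

SW = 13593.0


def damped_sinusoid(n, sw, amp, freq, lw, phase=0.0):
    t = np.arange(n) / sw
    return amp * np.exp(1j * phase) * np.exp((-math.pi * lw + 2j * math.pi * freq) * t)


class TestDcOffsetCorrect:
    def test_constant_fid_becomes_zero(self):
        fid = np.full(256, 3.0 + 4.0j)
        assert np.allclose(dc_offset_correct(fid), 0.0)

    def test_zero_tail_leaves_input_unchanged(self):
        fid = np.zeros(128, dtype=complex)
        fid[:32] = 1.0 + 2.0j
        np.testing.assert_array_equal(dc_offset_correct(fid), fid)

    def test_offset_recovered_from_decayed_tail(self):
        # fast-decaying signal plus offset: the tail mean is the offset and
        # the corrected tail mean is zero (direct-arithmetic oracle)
        n = 2048
        offset = 3.0 + 4.0j
        fid = damped_sinusoid(n, SW, amp=5.0, freq=0.0, lw=500.0) + offset
        tail_mean = fid[n - n // 2 :].mean()
        assert tail_mean == pytest.approx(offset, abs=1e-9)
        corrected = dc_offset_correct(fid)
        assert abs(corrected[n - n // 2 :].mean()) < 1e-12

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_idempotent_on_tail_centred_signals(self, seed):
        rng = np.random.default_rng(seed)
        fid = rng.standard_normal(64) + 1j * rng.standard_normal(64)
        once = dc_offset_correct(fid)
        twice = dc_offset_correct(once)
        np.testing.assert_allclose(twice, once, atol=1e-12)

    def test_empty_fid_rejected(self):
        with pytest.raises(ValidationError):
            dc_offset_correct(np.array([], dtype=complex))


class TestFitSpectrum:
    def test_two_peak_noiseless_recovery(self):
        truth = [(2.0, 1000.0, 25.0), (0.5, -1320.0, 18.0)]
        fid = sum(damped_sinusoid(2048, SW, a, f, w) for a, f, w in truth)
        priors = [
            PeakPrior("lactate", 1000.0),
            PeakPrior("bicarbonate", -1320.0),
        ]
        fit = fit_spectrum(fid, priors, SW)
        assert fit.converged
        for est, (a, f, w) in zip(fit.estimates, truth):
            assert est.amplitude == pytest.approx(a, rel=1e-6)
            assert est.frequency == pytest.approx(f, abs=1e-3)
            assert est.linewidth == pytest.approx(w, rel=1e-4)

    def test_zero_fid_gives_zero_amplitudes(self):
        priors = priors_from_shifts(C1_SHIFTS_HZ)
        fit = fit_spectrum(np.zeros(2048, dtype=complex), priors, SW)
        for est in fit.estimates:
            assert est.amplitude == pytest.approx(0.0, abs=1e-8)

    def test_amplitude_matches_fft_integral(self):
        # Parseval-style oracle: the mean of the discrete spectrum equals the
        # t=0 sample, which is the amplitude for a single phase-0 resonance
        amp = 3.7
        fid = damped_sinusoid(2048, SW, amp, freq=570.0, lw=22.0)
        prior = PeakPrior("alanine", 570.0, freq_tol_hz=0.0)
        fit = fit_spectrum(fid, [prior], SW)
        fft_integral = np.fft.fft(fid).sum().real / len(fid)
        assert fit.estimates[0].amplitude == pytest.approx(fft_integral, rel=1e-4)
        assert fft_integral == pytest.approx(amp, rel=1e-9)

    def test_global_phase_rotation_leaves_amplitudes_invariant(self):
        fid = damped_sinusoid(2048, SW, 1.5, 1000.0, 20.0) + damped_sinusoid(
            2048, SW, 0.8, -1320.0, 30.0
        )
        priors = [PeakPrior("lactate", 1000.0), PeakPrior("bicarbonate", -1320.0)]
        base = fit_spectrum(fid, priors, SW)
        rotated = fit_spectrum(fid * np.exp(1j * 0.9), priors, SW)
        for e0, e1 in zip(base.estimates, rotated.estimates):
            assert e1.amplitude == pytest.approx(e0.amplitude, rel=1e-6)

    def test_residual_norm_not_worse_than_zero_model(self):
        rng = np.random.default_rng(5)
        fid = damped_sinusoid(1024, SW, 1.0, 1000.0, 20.0) + 0.05 * (
            rng.standard_normal(1024) + 1j * rng.standard_normal(1024)
        )
        priors = [PeakPrior("lactate", 1000.0)]
        fit = fit_spectrum(fid, priors, SW)
        assert fit.rss <= np.sum(np.abs(fid) ** 2)

    def test_amplitude_uncertainty_scales_with_noise(self):
        rng = np.random.default_rng(7)
        clean = damped_sinusoid(1024, SW, 2.0, 1000.0, 20.0)
        priors = [PeakPrior("lactate", 1000.0)]
        ses = []
        for sd in (0.01, 0.1):
            noisy = clean + sd * (rng.standard_normal(1024) + 1j * rng.standard_normal(1024))
            fit = fit_spectrum(noisy, priors, SW)
            ses.append(fit.estimates[0].amplitude_stderr)
        assert ses[1] > 3 * ses[0]

    def test_duplicate_prior_frequencies_rejected(self):
        with pytest.raises(ValidationError):
            fit_spectrum(
                np.zeros(64, dtype=complex),
                [PeakPrior("a", 0.0), PeakPrior("b", 0.0)],
                SW,
            )


class TestQuantifySeries:
    def test_series_amplitudes_track_generator_truth(self, acq):
        truth = KineticGroundTruth()
        M, names = simulate_kinetics(truth, acq)
        peaks = peaks_from_shifts(C1_SHIFTS_HZ, names=names)
        priors = priors_from_shifts(C1_SHIFTS_HZ, names=names)
        from cardiodnp.synthetic import noise_sd_for_peak_snr

        sd = noise_sd_for_peak_snr(M, acq, snr=50.0)
        fids = render_fids(M, peaks, acq, noise_sd=sd, seed=123)
        series = quantify_series(fids, priors)
        sin_t = math.sin(acq.flip_angle_rad)
        for j, name in enumerate(names):
            if name == "co2":
                # the CO2 pool sits at the noise floor at this SNR (its flux
                # is a tenth of the bicarbonate share); no correlation claim
                continue
            est = series.amplitudes[name].to_numpy()
            ok = np.isfinite(est)
            r = np.corrcoef(est[ok], (M[ok, j] * sin_t))[0, 1]
            assert r >= 0.99, f"{name}: r={r:.4f}"

    def test_noiseless_series_reproduces_amplitudes_to_1e5(self, acq):
        truth = KineticGroundTruth()
        M, names = simulate_kinetics(truth, acq)
        peaks = peaks_from_shifts(C1_SHIFTS_HZ, names=names)
        priors = priors_from_shifts(C1_SHIFTS_HZ, names=names)
        fids = render_fids(M, peaks, acq, noise_sd=0.0)
        series = quantify_series(fids, priors)
        truth_amp = M * math.sin(acq.flip_angle_rad)
        est = series.amplitudes.to_numpy()
        mask = truth_amp > truth_amp.max() * 1e-4
        np.testing.assert_allclose(est[mask], truth_amp[mask], rtol=1e-5)

    def test_all_zero_series_gives_zero_amplitudes(self, acq_small):
        fids = FidSeries(
            data=np.zeros((acq_small.n_repetitions, acq_small.n_points), dtype=complex),
            acq=acq_small,
        )
        series = quantify_series(fids, priors_from_shifts(C1_SHIFTS_HZ))
        assert np.nanmax(np.abs(series.amplitudes.to_numpy())) < 1e-8

    def test_time_axis_spans_acquisition(self, acq):
        fids = FidSeries(
            data=np.zeros((acq.n_repetitions, acq.n_points), dtype=complex), acq=acq
        )
        series = quantify_series(fids, priors_from_shifts(C1_SHIFTS_HZ, names=["pyruvate"]))
        assert series.time[0] == 0.0
        assert series.time[-1] == pytest.approx(59.0)
        assert np.allclose(np.diff(series.time), acq.repetition_time)


class TestSumWindowRatios:
    @staticmethod
    def _c2_series(acq, pyr_curve, ratio, noise_sd=0.0, seed=None):
        names = list(C2_SHIFTS_HZ)
        M = np.zeros((acq.n_repetitions, len(names)))
        M[:, 0] = pyr_curve
        for j in range(1, len(names)):
            M[:, j] = ratio * pyr_curve
        peaks = peaks_from_shifts(C2_SHIFTS_HZ, names=names)
        return render_fids(M, peaks, acq, noise_sd=noise_sd, seed=seed)

    def test_fixed_ratio_preserved_under_summation(self, acq):
        pyr = np.zeros(acq.n_repetitions)
        pyr[3:] = np.exp(-np.arange(acq.n_repetitions - 3) / 25.0)
        fids = self._c2_series(acq, pyr, ratio=0.1)
        result = sum_window_ratios(fids, priors_from_shifts(C2_SHIFTS_HZ))
        for name, value in result.ratios.items():
            assert value == pytest.approx(0.1, abs=1e-6), name

    def test_zero_metabolite_signal_gives_zero_ratios(self, acq):
        pyr = np.zeros(acq.n_repetitions)
        pyr[2:] = 1.0
        fids = self._c2_series(acq, pyr, ratio=0.0)
        result = sum_window_ratios(fids, priors_from_shifts(C2_SHIFTS_HZ))
        for value in result.ratios.values():
            assert value == pytest.approx(0.0, abs=1e-6)

    def test_window_covers_30_repetitions_from_appearance(self, acq):
        pyr = np.zeros(acq.n_repetitions)
        pyr[5:] = 1.0
        fids = self._c2_series(acq, pyr, ratio=0.1)
        result = sum_window_ratios(fids, priors_from_shifts(C2_SHIFTS_HZ))
        assert result.appearance_index == 5
        assert result.window_repetitions == (5, 34)
        assert result.window_s == (5.0, 35.0)

    def test_no_signal_raises(self, acq_small):
        fids = FidSeries(
            data=np.zeros((acq_small.n_repetitions, acq_small.n_points), dtype=complex),
            acq=acq_small,
        )
        with pytest.raises(NoSignalError):
            sum_window_ratios(fids, priors_from_shifts(C2_SHIFTS_HZ))

    def test_missing_pyruvate_prior_rejected(self, acq_small):
        fids = FidSeries(
            data=np.zeros((acq_small.n_repetitions, acq_small.n_points), dtype=complex),
            acq=acq_small,
        )
        priors = priors_from_shifts(C2_SHIFTS_HZ, names=["citrate", "glutamate"])
        with pytest.raises(ValidationError):
            sum_window_ratios(fids, priors)
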