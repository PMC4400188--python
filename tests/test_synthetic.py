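"""Kinetic forward simulation, FID rendering, CINE and cohort generators."""

import math

import numpy as np
import pandas as pd
import pytest

from cardiodnp.acquisition import AcquisitionParams, MetabolitePeakSpec
from cardiodnp.errors import ValidationError
from cardiodnp.synthetic import (
    CineGeometry,
    CohortSpec,
    GammaVariateInput,
    KineticGroundTruth,
    TrapezoidInput,
    default_cohort_spec,
    noise_sd_for_peak_snr,
    render_fids,
    simulate_cine,
    simulate_cohort,
    simulate_kinetics,
)


class TestSimulateKinetics:
    def test_zero_flux_gives_zero_products(self, acq):
        truth = KineticGroundTruth(
            k_px={"lactate": 0.0, "bicarbonate": 0.0}, co2_bicarbonate_ratio=0.0
        )
        M, names = simulate_kinetics(truth, acq)
        assert names[0] == "pyruvate"
        assert np.all(M[:, 1:] == 0.0)
        assert M[:, 0].max() > 0  # injection still fills the pyruvate pool

    def test_label_conservation_closed_system(self):
        # input fully delivered before the first excitation, no decay, no flip:
        # total magnetization across pools is conserved over the train
        acq = AcquisitionParams(flip_angle_deg=0.0, n_repetitions=30)
        truth = KineticGroundTruth(
            k_px={"lactate": 0.05, "alanine": 0.02, "bicarbonate": 0.03},
            rho_x={"lactate": 0.0, "alanine": 0.0, "bicarbonate": 0.0, "co2": 0.0},
            rho_p=0.0,
            rho_default=0.0,
            input_fn=TrapezoidInput(start=-15.0, duration=10.0),
        )
        M, _ = simulate_kinetics(truth, acq)
        totals = M.sum(axis=1)
        assert totals[0] > 0
        assert np.allclose(totals, totals[0], rtol=1e-9)

    def test_constant_pyruvate_product_matches_analytic_solution(self):
        # steady pyruvate pool P0 (initial level + compensating inflow), one
        # product with rate k and decay rho: the hand-derived ODE solution is
        # x(t) = (k P0 / rho) (1 - exp(-rho t))
        P0, k, rho = 1.0, 0.02, 0.1
        acq = AcquisitionParams(flip_angle_deg=0.0, n_repetitions=40)
        truth = KineticGroundTruth(
            k_px={"lactate": k},
            rho_x={"lactate": rho},
            rho_p=0.0,
            input_fn=TrapezoidInput(start=0.0, duration=1e6, amplitude=k * P0, ramp=0.0),
            initial_pyruvate=P0,
            co2_bicarbonate_ratio=0.0,
        )
        M, names = simulate_kinetics(truth, acq)
        t = acq.repetition_times()
        expected = (k * P0 / rho) * (1.0 - np.exp(-rho * t))
        assert np.allclose(M[:, 0], P0, rtol=1e-9)  # pool held constant
        np.testing.assert_allclose(M[1:, 1], expected[1:], rtol=1e-6)

    @pytest.mark.parametrize("n_substeps", [10, 20, 50])
    def test_integrator_step_size_agreement_with_closed_form(self, n_substeps):
        P0, k, rho = 2.0, 0.03, 0.2
        acq = AcquisitionParams(flip_angle_deg=0.0, n_repetitions=20)
        truth = KineticGroundTruth(
            k_px={"lactate": k},
            rho_x={"lactate": rho},
            rho_p=0.0,
            input_fn=TrapezoidInput(start=0.0, duration=1e6, amplitude=k * P0, ramp=0.0),
            initial_pyruvate=P0,
            co2_bicarbonate_ratio=0.0,
        )
        M, _ = simulate_kinetics(truth, acq, n_substeps=n_substeps)
        t = acq.repetition_times()
        expected = (k * P0 / rho) * (1.0 - np.exp(-rho * t))
        np.testing.assert_allclose(M[1:, 1], expected[1:], rtol=1e-6)

    def test_monotone_depletion_with_flip_angle(self):
        finals = []
        for flip in [1.0, 5.0, 15.0, 45.0]:
            acq = AcquisitionParams(flip_angle_deg=flip)
            M, _ = simulate_kinetics(KineticGroundTruth(), acq)
            finals.append(M[-1].sum())
        assert all(a >= b for a, b in zip(finals, finals[1:]))

    def test_non_finite_rates_rejected(self):
        with pytest.raises(ValidationError):
            KineticGroundTruth(k_px={"lactate": float("nan")})
        with pytest.raises(ValidationError):
            KineticGroundTruth(k_px={"lactate": -0.1})

    def test_co2_split_preserves_total_pdh_flux(self, acq):
        truth = KineticGroundTruth(co2_bicarbonate_ratio=0.25)
        names, k, _ = truth.expanded_rates()
        assert "co2" in names
        k_map = dict(zip(names, k))
        assert k_map["bicarbonate"] + k_map["co2"] == pytest.approx(
            truth.k_px["bicarbonate"]
        )


class TestRenderFids:
    def test_zero_magnetization_zero_noise_gives_zero_fids(self, acq_small):
        peaks = [MetabolitePeakSpec("pyruvate", 0.0)]
        fids = render_fids(np.zeros((acq_small.n_repetitions, 1)), peaks, acq_small)
        assert np.all(fids.data == 0)

    def test_single_on_resonance_peak_is_real_decaying(self, acq_small):
        peaks = [MetabolitePeakSpec("pyruvate", 0.0, linewidth=30.0, phase=0.0)]
        M = np.ones((acq_small.n_repetitions, 1))
        fids = render_fids(M, peaks, acq_small)
        fid = fids.data[0]
        assert np.allclose(fid.imag, 0.0, atol=1e-12)
        assert np.all(fid.real > 0)
        assert np.all(np.diff(fid.real) < 0)

    def test_fft_shows_peaks_at_specified_offsets(self, acq):
        # FFT peak-picking oracle: two rendered resonances appear within one
        # spectral bin of their configured offsets
        offsets = (1000.0, -1320.0)
        peaks = [
            MetabolitePeakSpec("lactate", offsets[0], linewidth=15.0),
            MetabolitePeakSpec("bicarbonate", offsets[1], linewidth=15.0),
        ]
        M = np.full((acq.n_repetitions, 2), 1.0)
        fids = render_fids(M, peaks, acq)
        spectrum = np.abs(np.fft.fftshift(np.fft.fft(fids.data[0])))
        freqs = np.fft.fftshift(np.fft.fftfreq(acq.n_points, d=acq.dwell_time))
        bin_width = acq.sweep_width / acq.n_points
        # the two largest local maxima
        order = np.argsort(spectrum)[::-1]
        found = []
        for idx in order:
            f = freqs[idx]
            if all(abs(f - g) > 10 * bin_width for g in found):
                found.append(f)
            if len(found) == 2:
                break
        for offset in offsets:
            assert min(abs(f - offset) for f in found) <= bin_width

    def test_seeded_noise_is_reproducible(self, acq_small):
        peaks = [MetabolitePeakSpec("pyruvate", 0.0)]
        M = np.ones((acq_small.n_repetitions, 1))
        a = render_fids(M, peaks, acq_small, noise_sd=0.1, seed=42)
        b = render_fids(M, peaks, acq_small, noise_sd=0.1, seed=42)
        assert np.array_equal(a.data, b.data)

    def test_mismatched_peak_count_rejected(self, acq_small):
        peaks = [MetabolitePeakSpec("pyruvate", 0.0)]
        with pytest.raises(ValidationError):
            render_fids(np.zeros((acq_small.n_repetitions, 2)), peaks, acq_small)

    def test_noise_sd_for_peak_snr(self, acq):
        M = np.zeros((acq.n_repetitions, 1))
        M[5, 0] = 4.0
        sd = noise_sd_for_peak_snr(M, acq, snr=50.0)
        assert sd == pytest.approx(4.0 * math.sin(acq.flip_angle_rad) / 50.0)


class TestSimulateCine:
    def test_single_slice_truth_matches_analytic_areas(self):
        # one uniform slice: EDV = A * h at w=0 and ESV = A (1-c) h at w=1
        geom = CineGeometry(cavity_radius_mm=3.0, wall_thickness_mm=1.0, length_fraction=1e6)
        c, h = 0.4, 1.6
        table, truth = simulate_cine(
            geometry=geom, contraction_fraction=c, n_slices=1, n_frames=20,
            slice_thickness_mm=h,
        )
        area = math.pi * 3.0**2
        assert truth["edv_ul"] == pytest.approx(area * h, rel=1e-9)
        assert truth["esv_ul"] == pytest.approx(area * (1 - c) * h, rel=1e-9)
        assert truth["ef"] == pytest.approx(c, rel=1e-9)

    def test_zero_wall_thickness_gives_equal_areas(self):
        geom = CineGeometry(wall_thickness_mm=0.0)
        table, _ = simulate_cine(geometry=geom, n_slices=4, n_frames=10)
        np.testing.assert_allclose(
            table["epi_area_mm2"], table["endo_area_mm2"], rtol=1e-12
        )

    def test_epicardial_never_below_endocardial(self):
        table, _ = simulate_cine(noise_sd=2.0, seed=3)
        assert (table["epi_area_mm2"] >= table["endo_area_mm2"]).all()

    def test_same_seed_identical_tables(self):
        a, _ = simulate_cine(noise_sd=1.0, seed=11)
        b, _ = simulate_cine(noise_sd=1.0, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_contraction_rejected(self):
        with pytest.raises(ValidationError):
            simulate_cine(contraction_fraction=1.5)


class TestSimulateCohort:
    def test_zero_sd_reproduces_group_means(self):
        spec = CohortSpec(
            {("sham", "chow", 4, "m"): (10.0, 0.0, 5), ("aab", "wd", 4, "m"): (20.0, 0.0, 4)}
        )
        table = simulate_cohort(spec, seed=0)
        sham = table[table["surgery"] == "sham"]["value"]
        assert np.all(sham == 10.0)
        assert np.all(table[table["surgery"] == "aab"]["value"] == 20.0)

    def test_large_n_means_within_lln_bound(self):
        n = 10_000
        spec = CohortSpec({("sham", "chow", 4, "m"): (100.0, 5.0, n)})
        table = simulate_cohort(spec, seed=1)
        assert abs(table["value"].mean() - 100.0) <= 3 * 5.0 / math.sqrt(n)

    def test_default_spec_reproduces_published_group_sizes(self):
        table = simulate_cohort(default_cohort_spec(measures=["edv_ul"]), seed=0)
        wk4 = table[table["week"] == 4]
        ns = {
            (s, d): len(wk4[(wk4["surgery"] == s) & (wk4["diet"] == d)])
            for s in ("sham", "aab") for d in ("chow", "wd")
        }
        assert ns == {
            ("sham", "chow"): 11, ("sham", "wd"): 8, ("aab", "chow"): 10, ("aab", "wd"): 8,
        }

    def test_same_seed_identical_tables(self):
        spec = default_cohort_spec(measures=["esv_ul"])
        a = simulate_cohort(spec, seed=9)
        b = simulate_cohort(spec, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestInjectionInputs:
    def test_trapezoid_is_zero_outside_support(self):
        u = TrapezoidInput(start=2.0, duration=10.0, amplitude=3.0, ramp=2.0)
        t = np.array([1.9, 2.0, 4.0, 7.0, 12.0, 12.1])
        vals = u(t)
        assert vals[0] == 0 and vals[-1] == 0
        assert vals[2] == pytest.approx(3.0)  # plateau
        assert vals[3] == pytest.approx(3.0)

    def test_gamma_variate_peaks_at_time_to_peak(self):
        u = GammaVariateInput(start=0.0, amplitude=2.0, time_to_peak=4.0)
        t = np.linspace(0, 20, 2001)
        vals = u(t)
        assert t[np.argmax(vals)] == pytest.approx(4.0, abs=0.02)
        assert vals.max() == pytest.approx(2.0, rel=1e-6)
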