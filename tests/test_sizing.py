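import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from venosim.device import SalineMedium, default_layout, pairs
from venosim.forward import (LumenProfile, NoiseModel, simulate_voltages,
                             synthesize_carrier)
from venosim.mechanics import make_worked_example_vein
from venosim.sizing import (CalibrationResult, SizingError, SizingProfile,
                            calibrate_conductivity, csa_from_voltage,
                            demodulate, detect_minimal_lumen,
                            diameter_from_csa, read_profile,
                            reference_diameter, size_profile, write_profile)
from venosim.stats import regression_through_origin

SIGMA = 0.0016


class TestDemodulate:
    def test_clean_sine_identity(self):
        t = np.arange(200) / 200e3          # 10 cycles at 200 kHz
        w = 8.5e-3 * np.sin(2 * np.pi * 10e3 * t)
        assert demodulate(w, 10.0, 200.0) == pytest.approx(8.5e-3, rel=1e-12)

    def test_zero_waveform(self):
        assert demodulate(np.zeros(200), 10.0, 200.0) == 0.0

    def test_truncates_partial_cycle(self):
        t = np.arange(215) / 200e3          # 10.75 cycles
        w = 3e-3 * np.sin(2 * np.pi * 10e3 * t)
        assert demodulate(w, 10.0, 200.0) == pytest.approx(3e-3, rel=1e-12)

    def test_sub_cycle_rejected(self):
        with pytest.raises(SizingError):
            demodulate(np.zeros(10), 10.0, 200.0)

    def test_noise_rejection_scales_with_cycles(self):
        # Monte-Carlo oracle: lock-in error shrinks as 1/sqrt(cycles)
        rng = np.random.default_rng(11)
        amp, rel_sd, reps = 8.5e-3, 0.05, 200
        rms = {}
        for cycles in (10, 1000):
            n = cycles * 20
            t = np.arange(n) / 200e3
            clean = amp * np.sin(2 * np.pi * 10e3 * t)
            errs = []
            for _ in range(reps):
                w = clean + rng.normal(0, rel_sd * amp, n)
                errs.append(demodulate(w, 10.0, 200.0) - amp)
            rms[cycles] = np.sqrt(np.mean(np.square(errs))) / amp
        assert rms[10] < 0.01                       # within 1% at 10 cycles
        ratio = rms[10] / rms[1000]
        assert ratio == pytest.approx(np.sqrt(100), rel=0.35)


class TestCalibration:
    def test_closed_form(self, layout):
        rec = simulate_voltages(LumenProfile.uniform(50.0), layout,
                                SalineMedium(conductivity=SIGMA),
                                NoiseModel())
        cal = calibrate_conductivity(rec, layout, reference_csa=50.0,
                                     reference_pair=2)
        # sigma = I L / (dV A): 136e-6 * 5 / (8.5e-3 * 50)
        assert cal.sigma == pytest.approx(0.0016, rel=1e-12)

    @pytest.mark.parametrize("sigma_true", [0.0009, 0.0016, 0.0031])
    def test_round_trip_any_conductivity(self, layout, sigma_true):
        rec = simulate_voltages(LumenProfile.uniform(80.0), layout,
                                SalineMedium(conductivity=sigma_true),
                                NoiseModel())
        cal = calibrate_conductivity(rec, layout, reference_csa=80.0)
        assert cal.sigma == pytest.approx(sigma_true, rel=1e-12)

    def test_noisy_calibration_unbiased(self, layout, medium):
        # simulation oracle: mean over 100 seeds within 3 MC standard errors
        prof = LumenProfile.uniform(50.0)
        estimates = []
        for seed in range(100):
            rec = simulate_voltages(prof, layout, medium,
                                    NoiseModel(relative_sd=0.01, seed=seed))
            estimates.append(
                calibrate_conductivity(rec, layout, 50.0).sigma)
        estimates = np.array(estimates)
        se = estimates.std(ddof=1) / 10
        assert abs(estimates.mean() - SIGMA) < 3 * se + 1e-7 * SIGMA

    def test_single_pair_vs_average(self, layout, medium):
        rec = simulate_voltages(LumenProfile.uniform(50.0), layout, medium,
                                NoiseModel())
        avg = calibrate_conductivity(rec, layout, 50.0)
        single = calibrate_conductivity(rec, layout, 50.0, reference_pair=4)
        assert avg.sigma == pytest.approx(single.sigma, rel=1e-12)
        assert avg.pair_index is None and single.pair_index == 4

    def test_bad_inputs(self, layout, medium):
        rec = simulate_voltages(LumenProfile.uniform(50.0), layout, medium,
                                NoiseModel())
        with pytest.raises(SizingError):
            calibrate_conductivity(rec, layout, reference_csa=-1.0)
        with pytest.raises(SizingError):
            CalibrationResult(sigma=0.0)


class TestCsaFromVoltage:
    def test_closed_form_inversion(self):
        csa = csa_from_voltage(8.5e-3, 0.0016, 5.0, 136e-6)
        assert csa == pytest.approx(50.0, rel=1e-12)
        assert diameter_from_csa(csa) == pytest.approx(7.9788456, rel=1e-6)

    @pytest.mark.parametrize("diameter", range(2, 19))
    def test_noise_free_round_trip(self, layout, medium, diameter):
        csa_true = np.pi * (diameter / 2) ** 2
        rec = simulate_voltages(LumenProfile.uniform(csa_true), layout,
                                medium, NoiseModel())
        for dv, span in zip(rec.voltage, rec.span_mm):
            got = csa_from_voltage(dv, SIGMA, span, layout.current_a)
            assert got == pytest.approx(csa_true, rel=1e-12)

    def test_heterogeneous_pair_reports_harmonic_mean(self, layout, medium):
        z = np.arange(0.0, 60.001, 0.002)
        csa = 50.0 + 15.0 * np.sin(0.3 * z)
        prof = LumenProfile(z=z, csa=csa)
        rec = simulate_voltages(prof, layout, medium, NoiseModel())
        p = pairs(layout)[3]
        dv = rec.voltage[3]
        got = csa_from_voltage(dv, SIGMA, p.span_l, layout.current_a)
        # independent quadrature oracle for the span harmonic mean
        zz = np.linspace(p.proximal_position, p.distal_position, 100_000)
        harmonic = p.span_l / np.trapezoid(1.0 / (50.0 + 15.0 * np.sin(0.3 * zz)), zz)
        assert got == pytest.approx(harmonic, rel=1e-5)

    def test_domain_errors(self):
        with pytest.raises(SizingError):
            csa_from_voltage(0.0, SIGMA, 5.0, 136e-6)
        with pytest.raises(SizingError):
            csa_from_voltage(1e-3, SIGMA, -5.0, 136e-6)


class TestSizeProfile:
    def test_uniform_phantom(self, layout, medium):
        rec = simulate_voltages(LumenProfile.uniform(50.0), layout, medium,
                                NoiseModel())
        prof = size_profile(rec, layout, CalibrationResult(sigma=SIGMA))
        assert np.allclose(prof.csa, 50.0, rtol=1e-12)
        assert prof.n_pairs == 8

    def test_stenosis_minimum_at_center(self, layout, medium):
        z = np.arange(0.0, 60.5, 0.25)
        csa = 60.0 - 25.0 * np.exp(-((z - 30.0) / 5.0) ** 2)
        rec = simulate_voltages(LumenProfile(z=z, csa=csa), layout, medium,
                                NoiseModel())
        prof = size_profile(rec, layout, CalibrationResult(sigma=SIGMA))
        lesion, _ = detect_minimal_lumen(prof)
        assert lesion in (4, 5)

    def test_worked_example_end_pairs(self, layout, medium):
        vein = make_worked_example_vein()
        rec = simulate_voltages(vein.lumen_profile(0.0), layout, medium,
                                NoiseModel())
        prof = size_profile(rec, layout, CalibrationResult(sigma=SIGMA))
        assert prof.csa[0] == pytest.approx(60.0, rel=1e-9)
        assert prof.csa[-1] == pytest.approx(57.0, rel=1e-9)

    def test_pair_count_mismatch(self, layout, medium):
        rec = simulate_voltages(LumenProfile.uniform(50.0), layout, medium,
                                NoiseModel())
        small = default_layout()
        bad = small.__class__(detection_positions=(0.0, 5.0, 10.0),
                              excitation_positions=(0.0, 10.0))
        with pytest.raises(SizingError):
            size_profile(rec, bad, CalibrationResult(sigma=SIGMA))

    def test_full_chain_with_carrier_demodulation(self, layout, medium):
        """Carrier synthesis then lock-in detection recovers exact sizes."""
        rec = simulate_voltages(LumenProfile.uniform(120.0), layout, medium,
                                NoiseModel())
        wav = synthesize_carrier(rec, layout, 200.0, 2.0)
        amps = np.array([demodulate(wav.waveforms[i], 10.0, 200.0)
                         for i in range(wav.n_pairs)])
        csa = layout.current_a * rec.span_mm / (SIGMA * amps)
        assert np.allclose(csa, 120.0, rtol=1e-9)

    def test_profile_io_round_trip(self, tmp_path, layout, medium):
        rec = simulate_voltages(LumenProfile.uniform(75.0), layout, medium,
                                NoiseModel(), pressure_cmh2o=15.0)
        prof = size_profile(rec, layout, CalibrationResult(sigma=SIGMA))
        path = tmp_path / "profile.csv"
        write_profile(prof, path)
        back = read_profile(path)
        assert np.allclose(back.csa, prof.csa, rtol=1e-12)
        assert back.pressure_cmh2o == 15.0


class TestMinimalLumenAndReference:
    def _profile(self, csas):
        csas = np.asarray(csas, dtype=float)
        return SizingProfile(
            pair_index=np.arange(1, csas.size + 1),
            center_mm=np.linspace(10, 50, csas.size),
            csa=csas, diameter=diameter_from_csa(csas),
        )

    def test_published_pattern(self):
        prof = self._profile([60, 59, 58, 57, 58, 59, 60, 60])
        assert detect_minimal_lumen(prof) == (4, 57.0)

    def test_uniform_tie_break_proximal(self):
        prof = self._profile([50.0] * 8)
        assert detect_minimal_lumen(prof)[0] == 1

    def test_argmin_against_exhaustive_scan(self):
        from itertools import permutations
        rng = np.random.default_rng(0)
        values = list(rng.uniform(30, 90, 8))
        for perm in list(permutations(values))[:500]:
            prof = self._profile(list(perm))
            got, _ = detect_minimal_lumen(prof)
            best = min(range(8), key=lambda i: perm[i]) + 1
            assert got == best

    def test_reference_excludes_lesion_neighborhood(self):
        prof = self._profile([60, 59, 58, 40, 58, 59, 60, 60])
        ref = reference_diameter(prof, 4)
        keep = [0, 1, 5, 6, 7]
        assert ref == pytest.approx(np.mean(prof.diameter[keep]), rel=1e-12)

    def test_reference_on_uniform(self):
        prof = self._profile([50.0] * 8)
        ref = reference_diameter(prof, 1)
        assert ref == pytest.approx(diameter_from_csa(50.0), rel=1e-12)

    def test_all_excluded_error(self):
        prof = self._profile([50.0, 40.0])
        with pytest.raises(SizingError):
            reference_diameter(prof, 1)


class TestChainInvariants:
    def test_noise_free_identity_and_regression(self, layout, medium):
        true_d, meas_d = [], []
        for d in range(2, 19):
            csa = np.pi * (d / 2) ** 2
            rec = simulate_voltages(LumenProfile.uniform(csa), layout,
                                    medium, NoiseModel())
            prof = size_profile(rec, layout, CalibrationResult(sigma=SIGMA))
            true_d.extend([float(d)] * prof.n_pairs)
            meas_d.extend(prof.diameter)
        true_d, meas_d = np.array(true_d), np.array(meas_d)
        assert np.max(np.abs(meas_d - true_d)) < 1e-9
        slope, r2 = regression_through_origin(true_d, meas_d)
        assert slope == pytest.approx(1.0, abs=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_relative_error_scale_free(self, layout, medium):
        """Relative CSA error under multiplicative noise is independent
        of the true CSA."""
        rms = []
        for d in (3.0, 9.0, 17.0):
            csa_true = np.pi * (d / 2) ** 2
            errs = []
            for seed in range(200):
                rec = simulate_voltages(
                    LumenProfile.uniform(csa_true), layout, medium,
                    NoiseModel(relative_sd=0.01, seed=seed))
                prof = size_profile(rec, layout,
                                    CalibrationResult(sigma=SIGMA))
                errs.extend(prof.csa / csa_true - 1.0)
            rms.append(np.sqrt(np.mean(np.square(errs))))
        assert max(rms) / min(rms) < 1.15

    @given(sigma_guess=st.floats(min_value=1e-4, max_value=1e-2))
    @settings(max_examples=20, deadline=None)
    def test_calibration_ignores_prior_guess(self, sigma_guess):
        # the calibration depends only on the reference measurement
        layout = default_layout()
        medium = SalineMedium(conductivity=0.0021)
        rec = simulate_voltages(LumenProfile.uniform(60.0), layout, medium,
                                NoiseModel())
        cal = calibrate_conductivity(rec, layout, 60.0)
        assert cal.sigma == pytest.approx(0.0021, rel=1e-12)
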