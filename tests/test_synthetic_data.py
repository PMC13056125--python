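"""Generators: determinism, zero-noise exactness, statistical structure."""

import dataclasses

import numpy as np
import pytest

from spheromech import device as dev
from spheromech import fret
from spheromech import kinematics as kin
from spheromech import synthetic_data as synth
from spheromech.errors import CalibrationError, ValidationError


class TestDeterminism:
    def test_force_curve_bit_identical(self):
        spec = synth.CurveSpec(peak_amplitudes_sd_units=(2.0,), seed=7)
        a = synth.gen_force_curve(spec)
        b = synth.gen_force_curve(spec)
        assert np.array_equal(a.force, b.force)
        assert np.array_equal(a.displacement, b.displacement)

    def test_track_bit_identical(self):
        spec = synth.TrackSpec(noise_sd_pos=0.05, noise_sd_angle=2.0, seed=7)
        a = synth.gen_track(spec)
        b = synth.gen_track(spec)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.orientation,
                                                           b.orientation)

    def test_device_and_flim_bit_identical(self):
        spec = synth.DeviceSpec(noise_sd=1.0, seed=3)
        a = synth.gen_pressure_series(spec)
        b = synth.gen_pressure_series(spec)
        assert np.array_equal(a.pressure.pressure, b.pressure.pressure)
        mask = np.zeros((16, 16), bool)
        mask[:8] = True
        m1 = synth.gen_flim_map([(mask, 0.6), (~mask, 0.2)], 0.02, seed=5)
        m2 = synth.gen_flim_map([(mask, 0.6), (~mask, 0.2)], 0.02, seed=5)
        assert np.array_equal(m1, m2, equal_nan=True)

    def test_different_seeds_differ(self):
        spec = synth.CurveSpec()
        a = synth.gen_force_curve(spec, seed=1)
        b = synth.gen_force_curve(spec, seed=2)
        assert not np.array_equal(a.force, b.force)


class TestForceCurveGenerator:
    def test_zero_noise_minimum_is_exact_rupture(self, clean_curve_spec):
        curve = synth.gen_force_curve(clean_curve_spec, seed=0)
        assert curve.force.min() == pytest.approx(-40.0, abs=1e-12)
        # jump back to zero right after the ramp minimum
        i_min = int(np.argmin(curve.force))
        assert curve.force[i_min + 1] == pytest.approx(0.0, abs=1e-12)

    def test_rupture_sampling_matches_normal_oracle(self):
        # same rng stream as the generator: first draw is the rupture force
        spec = synth.CurveSpec(rupture_mean=39.9, rupture_sd=6.5, n_points=256)
        truths = []
        for s in range(40):
            curve = synth.gen_force_curve(spec, seed=s)
            oracle = 39.9 + 6.5 * np.random.default_rng(s).standard_normal()
            assert curve.metadata["true_rupture_pN"] == pytest.approx(oracle)
            truths.append(curve.metadata["true_rupture_pN"])
        assert abs(np.mean(truths) - 39.9) < 2 * 6.5 / np.sqrt(40)

    def test_injected_peak_count_recovered(self, noisy_peak_spec):
        from spheromech import force_spectroscopy as fs

        curve = synth.gen_force_curve(noisy_peak_spec, seed=42)
        result = fs.analyze_curve(curve)
        assert sum(p.significant for p in result["peaks"]) == 2

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValidationError):
            synth.CurveSpec(n_points=32)
        with pytest.raises(ValidationError):
            synth.CurveSpec(rupture_mean=-1.0)
        with pytest.raises(ValidationError):
            synth.CurveSpec(noise_sd=-0.1)


class TestSpectraGenerator:
    def test_donor_area_normalized(self, spectra_spec):
        donor, _ = synth.gen_spectra(spectra_spec)
        area = np.trapezoid(donor.value, donor.wavelength)
        assert area == pytest.approx(1.0, abs=1e-9)

    def test_acceptor_peak_equals_eps_max(self, spectra_spec):
        _, acceptor = synth.gen_spectra(spectra_spec)
        assert acceptor.value.max() == pytest.approx(spectra_spec.acceptor_eps_max)

    def test_grid_not_covering_band_rejected(self):
        with pytest.raises(ValidationError):
            synth.SpectraSpec(grid_start=500.0)  # cuts the donor band

    def test_calibration_round_trip(self, spectra_spec):
        cal = synth.calibrate_spectra_to_r0(spectra_spec, 5.25)
        donor, acceptor = synth.gen_spectra(cal)
        r0 = fret.forster_radius(fret.overlap_integral(donor, acceptor))
        assert r0 == pytest.approx(5.25, abs=1e-6)

    def test_calibration_fixed_point_and_sixth_power(self, spectra_spec):
        donor, acceptor = synth.gen_spectra(spectra_spec)
        current = fret.forster_radius(fret.overlap_integral(donor, acceptor))
        same = synth.calibrate_spectra_to_r0(spectra_spec, current)
        assert same.acceptor_eps_max == pytest.approx(
            spectra_spec.acceptor_eps_max, rel=1e-9)
        doubled = synth.calibrate_spectra_to_r0(spectra_spec, 2 * current)
        assert doubled.acceptor_eps_max == pytest.approx(
            64.0 * spectra_spec.acceptor_eps_max, rel=1e-9)

    def test_disjoint_bands_uncalibratable(self):
        spec = synth.SpectraSpec(donor_peak=430.0, donor_width=3.0,
                                 acceptor_peak=680.0, acceptor_width=3.0)
        with pytest.warns(UserWarning):
            with pytest.raises(CalibrationError):
                synth.calibrate_spectra_to_r0(spec, 5.25)


class TestTrackGenerator:
    def test_perfect_rolling_index_one(self):
        track = synth.gen_track(synth.TrackSpec(kind="rolling", slip=1.0), seed=0)
        assert kin.rolling_index(track) == pytest.approx(1.0, abs=1e-12)

    def test_pure_sliding_index_zero(self):
        track = synth.gen_track(synth.TrackSpec(kind="sliding"), seed=0)
        assert kin.rolling_index(track) == 0.0

    def test_partial_slip_scales_index(self):
        track = synth.gen_track(synth.TrackSpec(kind="rolling", slip=0.4), seed=0)
        assert kin.rolling_index(track) == pytest.approx(0.4, abs=1e-12)

    def test_decelerating_profile_recovered(self):
        spec = synth.TrackSpec(kind="sliding", speed_profile="decelerating",
                               noise_sd_pos=0.05)
        for s in range(20):
            track = synth.gen_track(spec, seed=s)
            assert kin.velocity_trend(track) == "decelerating"

    def test_cohort_extreme_probabilities(self):
        coh = synth.gen_cohort(1.0, 0.0, 20, synth.TrackSpec(), seed=0)
        a = kin.group_stats(coh["a"], "spherical")
        b = kin.group_stats(coh["b"], "discoid")
        assert a.rolling_fraction == 1.0 and b.rolling_fraction == 0.0

    def test_cohort_ratio_covers_construction(self):
        # binomial oracle: with the same seed the drawn kinds are binomial;
        # the classifier-recovered fold ratio must sit inside the Katz CI
        coh = synth.gen_cohort(0.7, 0.2, 500, synth.TrackSpec(), seed=11)
        a = kin.group_stats(coh["a"], "spherical")
        b = kin.group_stats(coh["b"], "discoid")
        res = kin.group_rolling_ratio(a, b)
        assert res.ci_low < 3.5 < res.ci_high

    def test_single_track_zero_denominator_flagged(self):
        coh = synth.gen_cohort(0.0, 0.0, 1, synth.TrackSpec(), seed=0)
        a = kin.group_stats(coh["a"], "spherical")
        b = kin.group_stats(coh["b"], "discoid")
        assert kin.group_rolling_ratio(a, b).undefined


class TestDeviceGenerator:
    def test_zero_growth_constant_baseline(self):
        run = synth.gen_pressure_series(synth.DeviceSpec(occlusion_growth=0.0))
        assert np.allclose(run.pressure.pressure, 50.0)

    def test_half_occlusion_doubles_pressure(self):
        spec = synth.DeviceSpec(occlusion_max=0.8, occlusion_growth=0.2,
                                duration=120.0, sample_interval=0.1)
        run = synth.gen_pressure_series(spec)
        i = int(np.argmin(np.abs(run.occlusion - 0.5)))
        assert run.occlusion[i] == pytest.approx(0.5, abs=0.01)
        assert run.pressure.pressure[i] == pytest.approx(
            50.0 / (1.0 - run.occlusion[i]), rel=1e-12)

    def test_constructed_crossing_gives_clot_time(self):
        spec = synth.DeviceSpec()
        g = synth.occlusion_growth_for_clot_time(spec, 25.0, 23.5)
        run = synth.gen_pressure_series(dataclasses.replace(
            spec, occlusion_growth=g))
        assert dev.clotting_time(run.pressure) == 24.0

    def test_act_series_decays_from_baseline(self):
        run = synth.gen_pressure_series(synth.DeviceSpec())
        assert run.act_s[0] == 140.0
        i15 = int(np.flatnonzero(run.act_t == 15.0)[0])
        assert run.act_s[i15] == pytest.approx(100.0)

    def test_full_occlusion_rejected(self):
        with pytest.raises(ValidationError):
            synth.DeviceSpec(occlusion_max=1.0)


class TestShapeKinetics:
    def test_zero_rate_constant_series(self):
        spec = synth.KineticsSpec(rate=0.0, recovery_rate=0.0,
                                  initial_discoid_fraction=0.9,
                                  recovery_plateau=0.9)
        df = synth.gen_shape_kinetics(spec)
        # decay is frozen; recovery relaxes from the switch value toward 0.9
        assert np.allclose(df["discoid_fraction"], 0.9)

    def test_treatment_and_recovery_endpoints(self):
        df = synth.gen_shape_kinetics(synth.KineticsSpec())
        at = lambda t: float(df.loc[df.t_min == t, "discoid_fraction"].iloc[0])
        assert at(0.0) == pytest.approx(0.90)
        assert at(30.0) <= 0.12
        assert at(120.0) == pytest.approx(0.65, abs=0.01)

    def test_instant_recovery_limit(self):
        spec = synth.KineticsSpec(recovery_rate=1e6)
        df = synth.gen_shape_kinetics(spec)
        post = df.loc[df.t_min > 60.0, "discoid_fraction"]
        assert np.allclose(post, 0.65, atol=1e-6)

    def test_unsorted_switch_times_rejected(self):
        with pytest.raises(ValidationError):
            synth.KineticsSpec(switch_times=(60.0, 30.0))


class TestFlimMapGenerator:
    def test_noiseless_single_region(self):
        mask = np.ones((10, 10), bool)
        m = synth.gen_flim_map([(mask, 0.6)], noise_sd=0.0)
        assert np.all(m == 0.6)

    def test_two_region_means_within_sampling_error(self):
        left = np.zeros((100, 200), bool)
        left[:, :100] = True
        m = synth.gen_flim_map([(left, 0.6), (~left, 0.2)], noise_sd=0.02, seed=1)
        se = 0.02 / np.sqrt(10_000)
        assert abs(np.mean(m[left]) - 0.6) < 3 * se
        assert abs(np.mean(m[~left]) - 0.2) < 3 * se

    def test_map_feeds_mixture_deconvolution(self):
        left = np.zeros((50, 100), bool)
        left[:, :50] = True
        m = synth.gen_flim_map([(left, 0.6), (~left, 0.2)], noise_sd=0.0)
        res = fret.map_activated_fraction(m, 0.6)
        assert np.mean(res.fraction_map[~left]) == pytest.approx(0.667, abs=0.001)

    def test_overlapping_masks_rejected(self):
        mask = np.ones((4, 4), bool)
        with pytest.raises(ValidationError):
            synth.gen_flim_map([(mask, 0.6), (mask, 0.2)])


class TestOutputsPassDownstreamValidation:
    """Every generator's output satisfies the consuming module's contracts."""

    def test_curve_track_device_spectra(self):
        from spheromech import force_spectroscopy as fs

        curve = synth.gen_force_curve(synth.CurveSpec(), seed=0)
        fs.estimate_noise(curve)  # would raise on contract violation
        track = synth.gen_track(synth.TrackSpec(noise_sd_pos=0.1,
                                                noise_sd_angle=2.0), seed=0)
        kin.summarize_track(track)
        run = synth.gen_pressure_series(synth.DeviceSpec(noise_sd=1.0), seed=0)
        dev.clotting_time(run.pressure)
        donor, acceptor = synth.gen_spectra(synth.SpectraSpec())
        fret.overlap_integral(donor, acceptor)
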