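"""Phasor transform, calibration, LLIF, density maps, lifetimes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import adipoflim as af
from adipoflim.exceptions import CalibrationError, ValidationError
from adipoflim.phantom import binned_periodic_decay
from adipoflim.phasor import angular_frequency, theoretical_phasor

from conftest import REF_LIFETIME, calibrated_field, make_uniform_stack

OMEGA = angular_frequency(12.5, 1)


class TestTheoreticalPhasor:
    def test_instantaneous_decay(self):
        assert theoretical_phasor(0.0, OMEGA) == (1.0, 0.0)

    def test_semicircle_apex(self):
        tau = 1.0 / OMEGA  # ωτ = 1
        g, s = theoretical_phasor(tau, OMEGA)
        assert g == pytest.approx(0.5)
        assert s == pytest.approx(0.5)

    def test_long_lifetimes_approach_origin_counterclockwise(self):
        taus = np.array([0.1, 0.5, 1.0, 3.0, 10.0, 100.0])
        g, s = theoretical_phasor(taus, OMEGA)
        # phase angle increases monotonically with lifetime along the arc
        phase = np.arctan2(s, g)
        assert np.all(np.diff(phase) > 0)
        assert g[-1] < 1e-3 and s[-1] < 0.05

    @settings(max_examples=50, deadline=None)
    @given(tau=st.floats(0.0, 50.0))
    def test_always_on_universal_semicircle(self, tau):
        g, s = theoretical_phasor(tau, OMEGA)
        assert abs((g - 0.5) ** 2 + s**2 - 0.25) < 1e-12


class TestLifetimeFromPhasor:
    def test_apex_inverts_to_inverse_omega(self):
        assert af.lifetime_from_phasor(0.5, 0.5, OMEGA) == pytest.approx(1 / OMEGA)

    def test_round_trip_through_theory(self):
        g, s = theoretical_phasor(6.5, OMEGA)
        assert af.lifetime_from_phasor(g, s, OMEGA) == pytest.approx(6.5)

    def test_zero_phase_is_zero_lifetime(self):
        assert af.lifetime_from_phasor(1.0, 0.0, OMEGA) == 0.0

    def test_nonpositive_g_signaled(self):
        with pytest.raises(ValidationError):
            af.lifetime_from_phasor(0.0, 0.5, OMEGA)


class TestPhasorTransform:
    def test_delta_decay_phasor(self):
        counts = np.zeros((8, 8, 64), dtype=np.uint32)
        counts[..., 0] = 1000
        stack = af.DecayStack(counts=counts, time_bin_width=12.5 / 64)
        field = af.phasor_transform(stack, bin_factor=1)
        t0 = stack.bin_centers[0]
        np.testing.assert_allclose(field.g, np.cos(OMEGA * t0), atol=1e-12)
        np.testing.assert_allclose(field.s, np.sin(OMEGA * t0), atol=1e-12)

    def test_uniform_image_gives_identical_phasors(self):
        stack, _, _ = make_uniform_stack(2.5)
        field = af.phasor_transform(stack)
        assert np.nanstd(field.g) < 1e-12
        assert np.nanstd(field.s) < 1e-12

    def test_monoexponential_matches_theory_within_quadrature(self):
        stack, _, spec = make_uniform_stack(6.5, irf_fwhm=0.0, irf_center=0.0)
        field = af.phasor_transform(stack)
        g_th, s_th = theoretical_phasor(6.5, field.omega)
        assert np.nanmean(field.g) == pytest.approx(g_th, abs=2e-3)
        assert np.nanmean(field.s) == pytest.approx(s_th, abs=2e-3)

    def test_empty_stack_all_invalid(self):
        stack = af.DecayStack(counts=np.zeros((8, 8, 16), dtype=np.uint32),
                              time_bin_width=12.5 / 16)
        field = af.phasor_transform(stack)
        assert not field.valid.any()

    def test_low_photon_bins_flagged_invalid(self):
        counts = np.zeros((11, 11, 16), dtype=np.uint32)
        counts[5, 5, 0] = 4  # 4 photons spread over every 5×5 window
        stack = af.DecayStack(counts=counts, time_bin_width=12.5 / 16)
        field = af.phasor_transform(stack, min_photons=10)
        assert not field.valid.any()

    def test_even_bin_factor_rejected(self):
        stack, _, _ = make_uniform_stack(2.0)
        with pytest.raises(ValidationError):
            af.phasor_transform(stack, bin_factor=4)


class TestCalibration:
    def test_perfect_instrument_is_identity(self):
        g, s = theoretical_phasor(REF_LIFETIME, OMEGA)
        ref = af.ReferenceCalibration(g_measured=g, s_measured=s,
                                      reference_lifetime=REF_LIFETIME, omega=OMEGA)
        assert ref.correction == pytest.approx(1.0 + 0.0j)

    def test_shared_irf_cancels(self):
        stack, ref, _ = make_uniform_stack(6.5, irf_fwhm=0.3)
        field = calibrated_field(stack, ref)
        g_th, s_th = theoretical_phasor(6.5, field.omega)
        assert np.nanmean(field.g) == pytest.approx(g_th, abs=2e-3)
        assert np.nanmean(field.s) == pytest.approx(s_th, abs=2e-3)

    def test_pure_delay_irf_is_phase_rotation(self):
        # an IRF that only delays the decay multiplies the phasor by a unit-
        # modulus factor, so the calibration correction is a pure rotation
        stack_delayed, _, _ = make_uniform_stack(REF_LIFETIME, irf_fwhm=0.0,
                                                 irf_center=2.0)
        stack_prompt, _, _ = make_uniform_stack(REF_LIFETIME, irf_fwhm=0.0,
                                                irf_center=0.0)
        cal_d = af.ReferenceCalibration.from_stack(stack_delayed, REF_LIFETIME)
        cal_p = af.ReferenceCalibration.from_stack(stack_prompt, REF_LIFETIME)
        rel = cal_d.correction / cal_p.correction
        # the delay contributes only a phase factor e^{-iωΔt}
        assert abs(rel) == pytest.approx(1.0, abs=1e-9)
        # delay recovered to within one TCSPC bin (the delta kernel snaps
        # to the bin lattice)
        assert -np.angle(rel) / OMEGA == pytest.approx(2.0, abs=12.5 / 256)

    def test_zero_modulus_reference_rejected(self):
        with pytest.raises(CalibrationError):
            af.ReferenceCalibration(g_measured=0.0, s_measured=0.0,
                                    reference_lifetime=5.0, omega=OMEGA)

    def test_mismatched_omega_rejected(self):
        stack, ref, _ = make_uniform_stack(2.0)
        field = af.phasor_transform(stack)
        cal = af.ReferenceCalibration(g_measured=0.5, s_measured=0.5,
                                      reference_lifetime=5.0, omega=2 * OMEGA)
        with pytest.raises(CalibrationError):
            af.calibrate(field, cal)

    def test_llif_invariant_to_irf_width(self):
        """Calibration removes the instrument response for any IRF width."""
        values = []
        for fwhm in (0.0, 0.2, 0.5):
            spec = af.TissuePhantomSpec(cyto_llif=0.4, droplet_count=0,
                                        nucleus_count=0, image_size=8,
                                        irf_fwhm=fwhm, seed=0)
            labels = np.ones((8, 8), dtype=np.uint8)
            stack, _, _ = af.render_decay_stack(labels, spec, noise=False)
            ref = af.generate_reference_measurement(REF_LIFETIME, spec)
            field = calibrated_field(stack, ref)
            lm = af.llif(field, 0.3, 6.5)
            values.append(np.nanmean(lm.values))
        np.testing.assert_allclose(values, values[0], atol=1e-3)


class TestLLIF:
    def _field_at(self, tau_or_point):
        if isinstance(tau_or_point, tuple):
            g, s = tau_or_point
        else:
            g, s = theoretical_phasor(tau_or_point, OMEGA)
        arr = np.full((3, 3), float(g)), np.full((3, 3), float(s))
        return af.PhasorField(g=arr[0], s=arr[1], weight=np.ones((3, 3)),
                              omega=OMEGA, calibrated=True)

    def test_pure_long_component_is_one(self):
        lm = af.llif(self._field_at(6.5), 0.3, 6.5)
        np.testing.assert_allclose(lm.values, 1.0, atol=1e-12)

    def test_pure_short_component_is_zero(self):
        lm = af.llif(self._field_at(0.3), 0.3, 6.5)
        np.testing.assert_allclose(lm.values, 0.0, atol=1e-12)

    def test_rendered_mixture_recovers_true_fraction(self):
        spec = af.TissuePhantomSpec(cyto_llif=0.4, droplet_count=0,
                                    nucleus_count=0, image_size=8, seed=0)
        labels = np.ones((8, 8), dtype=np.uint8)
        stack, _, _ = af.render_decay_stack(labels, spec, noise=False)
        ref = af.generate_reference_measurement(REF_LIFETIME, spec)
        lm = af.llif(calibrated_field(stack, ref), 0.3, 6.5)
        assert np.nanmean(lm.values) == pytest.approx(0.40, abs=0.004)

    def test_monotone_in_true_fraction(self):
        estimates = []
        for frac in (0.1, 0.3, 0.5, 0.7, 0.9):
            p0 = np.array(theoretical_phasor(0.3, OMEGA))
            p1 = np.array(theoretical_phasor(6.5, OMEGA))
            p = p0 + frac * (p1 - p0)
            lm = af.llif(self._field_at((p[0], p[1])), 0.3, 6.5)
            estimates.append(lm.values[0, 0])
        assert np.all(np.diff(estimates) > 0)
        np.testing.assert_allclose(estimates, (0.1, 0.3, 0.5, 0.7, 0.9),
                                   atol=1e-12)

    def test_degenerate_endpoints_rejected(self):
        with pytest.raises(ValidationError):
            af.llif(self._field_at(2.0), 6.5, 6.5)

    def test_values_clamped_to_unit_interval(self):
        lm = af.llif(self._field_at(12.0), 0.3, 6.5)  # beyond the long end
        assert np.all((lm.values >= 0) & (lm.values <= 1))


class TestDensityMapAndCentroid:
    def test_single_lifetime_occupies_one_cell(self):
        stack, _, _ = make_uniform_stack(3.0)
        field = af.phasor_transform(stack)
        dm = af.density_map(field, bins=64)
        assert (dm.hist > 0).sum() == 1
        assert dm.hist.max() == 1.0

    def test_additivity_before_normalization(self):
        s1, r1, _ = make_uniform_stack(2.0)
        s2, r2, _ = make_uniform_stack(5.0)
        f1, f2 = calibrated_field(s1, r1), calibrated_field(s2, r2)
        joint = af.density_map([f1, f2], bins=64)
        assert (joint.hist > 0).sum() == 2

    def test_empty_input_rejected(self):
        stack = af.DecayStack(counts=np.zeros((8, 8, 16), dtype=np.uint32),
                              time_bin_width=12.5 / 16)
        field = af.phasor_transform(stack)
        with pytest.raises(ValidationError):
            af.density_map(field)

    def test_centroid_of_constant_field(self):
        stack, _, _ = make_uniform_stack(2.0)
        field = af.phasor_transform(stack)
        g, s = af.centroid(field)
        assert g == pytest.approx(field.g[3, 3])
        assert s == pytest.approx(field.s[3, 3])

    def test_centroid_of_symmetric_two_point_distribution(self):
        g = np.array([[0.2, 0.8]] * 2)
        s = np.array([[0.1, 0.3]] * 2)
        field = af.PhasorField(g=g, s=s, weight=np.ones((2, 2)), omega=OMEGA)
        gc, sc = af.centroid(field)
        assert (gc, sc) == (pytest.approx(0.5), pytest.approx(0.2))

    def test_map_centroid_close_to_field_centroid(self):
        stack, _, _ = make_uniform_stack(3.0)
        field = af.phasor_transform(stack)
        dm = af.density_map(field, bins=256)
        g_f, s_f = af.centroid(field)
        g_m, s_m = af.centroid(dm)
        assert g_m == pytest.approx(g_f, abs=1.0 / 256)
        assert s_m == pytest.approx(s_f, abs=0.6 / 256)


class TestPhasorLinearity:
    @settings(max_examples=20, deadline=None)
    @given(frac=st.floats(0.0, 1.0), tau_a=st.floats(0.2, 8.0),
           tau_b=st.floats(0.2, 8.0))
    def test_mixture_phasor_is_convex_combination(self, frac, tau_a, tau_b):
        n, T = 128, 12.5
        omega = angular_frequency(T)
        t = (np.arange(n) + 0.5) * (T / n)
        da = binned_periodic_decay(tau_a, n, T)
        db = binned_periodic_decay(tau_b, n, T)
        mix = frac * da + (1 - frac) * db

        def phasor(d):
            return (d * np.exp(1j * omega * t)).sum() / d.sum()

        expected = frac * phasor(da) + (1 - frac) * phasor(db)
        assert abs(phasor(mix) - expected) < 1e-10

    def test_semicircle_containment_after_calibration(self, bat_phantom):
        field = bat_phantom["field"]
        g, s = field.g[field.valid], field.s[field.valid]
        # physical decays lie inside/on the universal semicircle, with a
        # small tolerance for photon noise at the low-count bins
        assert np.all(g**2 + s**2 <= g + 0.05)
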