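import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chirpendor import (
    ChirpSpec,
    RectSpec,
    Spectrum,
    convolve_sf_spectrum,
    excitation_profile,
    fwhm,
    normalize_spectrum,
    resample_to_grid,
    simulate_spectrum,
)
from chirpendor.profiles import ExcitationProfile


def make_profile(offsets, eff):
    return ExcitationProfile(np.asarray(offsets, float), np.asarray(eff, float))


class TestResample:
    def test_identity_on_matching_grid(self):
        sp = Spectrum(np.arange(0, 1.01, 0.1), np.random.default_rng(0).random(11))
        out = resample_to_grid(sp, 0.1)
        assert np.array_equal(out.intensities, sp.intensities)

    def test_linear_data_resampled_exactly(self):
        f = np.array([0.0, 0.3, 1.0])
        sp = Spectrum(f, 2.0 * f + 1.0)
        out = resample_to_grid(sp, 0.25)
        np.testing.assert_allclose(out.intensities, 2.0 * out.frequencies + 1.0,
                                   atol=1e-12)

    def test_two_point_midpoint(self):
        out = resample_to_grid(Spectrum([0.0, 1.0], [0.0, 1.0]), 0.5)
        np.testing.assert_allclose(out.frequencies, [0.0, 0.5, 1.0])
        assert out.intensities[1] == pytest.approx(0.5)

    def test_non_monotonic_grid_rejected(self):
        with pytest.raises(ValueError):
            Spectrum([0.0, 0.2, 0.1], [1, 2, 3])


class TestConvolution:
    def test_identity_kernel_returns_input(self):
        rng = np.random.default_rng(1)
        sp = Spectrum(np.arange(0, 5.001, 0.1), rng.random(51))
        prof = make_profile([-0.1, 0.0, 0.1], [0.0, 1.0, 0.0])
        out = convolve_sf_spectrum(sp, prof)
        np.testing.assert_allclose(out.intensities, sp.intensities, atol=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        vals=st.lists(st.floats(0, 10, allow_nan=False), min_size=5, max_size=40),
        kern=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=9),
    )
    def test_sum_rule_under_zero_padding(self, vals, kern):
        m = len(kern) // 2
        if len(kern) % 2 == 0:
            kern = kern + [0.0]
            m = len(kern) // 2
        # zero margins wide enough that no convolved mass leaves the grid
        vals = [0.0] * m + vals + [0.0] * m
        step = 0.1
        sp = Spectrum(step * np.arange(len(vals)), vals)
        prof = make_profile(step * (np.arange(len(kern)) - m), kern)
        out = convolve_sf_spectrum(sp, prof, window=step * m + step)
        assert np.sum(out.intensities) == pytest.approx(
            np.sum(vals) * np.sum(kern), rel=1e-9, abs=1e-9
        )

    def test_gaussian_kernel_widths_add_in_quadrature(self):
        step = 0.1
        f = np.arange(0, 40.0001, step)
        w1, w2 = 1.5, 2.0
        line = np.exp(-4 * np.log(2) * (f - 20.0) ** 2 / w1**2)
        offs = np.arange(-5.0, 5.0001, step)
        kern = np.exp(-4 * np.log(2) * offs**2 / w2**2)
        out = convolve_sf_spectrum(Spectrum(f, line), make_profile(offs, kern))
        expected = np.hypot(w1, w2)
        assert fwhm(out.frequencies, out.intensities) == pytest.approx(
            expected, rel=0.02
        )

    def test_convolution_never_narrows(self):
        step = 0.1
        f = np.arange(0, 30.0001, step)
        line = np.exp(-4 * np.log(2) * (f - 15.0) ** 2 / 1.2**2)
        offs = np.arange(-3.0, 3.0001, step)
        for kern_w in (0.3, 1.0, 2.5):
            kern = np.exp(-4 * np.log(2) * offs**2 / kern_w**2)
            out = convolve_sf_spectrum(Spectrum(f, line), make_profile(offs, kern),
                                       window=3.0)
            assert fwhm(out.frequencies, out.intensities) >= 1.2 - 1e-9

    def test_mismatched_steps_rejected(self):
        sp = Spectrum(np.arange(0, 1.01, 0.1), np.ones(11))
        prof = make_profile(np.arange(-0.5, 0.501, 0.05), np.ones(21) * 0.5)
        with pytest.raises(ValueError, match="same frequency step"):
            convolve_sf_spectrum(sp, prof)

    def test_wide_profile_window_warns(self):
        sp = Spectrum(np.arange(0, 1.01, 0.1), np.ones(11))
        prof = make_profile(np.arange(-2.0, 2.001, 0.1), np.full(41, 0.1))
        with pytest.warns(UserWarning, match="window exceeds"):
            convolve_sf_spectrum(sp, prof, window=2.0)


class TestNormalize:
    def test_constant_becomes_ones_and_idempotent(self):
        sp = Spectrum(np.arange(3.0), np.full(3, 4.2))
        out = normalize_spectrum(sp)
        np.testing.assert_allclose(out.intensities, 1.0)
        again = normalize_spectrum(out)
        np.testing.assert_allclose(again.intensities, out.intensities)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        vals = rng.random(20) + 0.1
        a = normalize_spectrum(Spectrum(np.arange(20.0), vals))
        b = normalize_spectrum(Spectrum(np.arange(20.0), 7.3 * vals))
        np.testing.assert_allclose(a.intensities, b.intensities, atol=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_spectrum(Spectrum(np.arange(3.0), np.zeros(3)))


class TestConsistencyWithSpinDynamics:
    def test_convolved_sf_spectrum_matches_direct_chirp_simulation(
        self, system, dist41
    ):
        """Convolving the single-frequency simulated spectrum with the chirp
        inversion profile reproduces the directly simulated chirp spectrum
        (normalized) to <=10% RMS of peak for bandwidths <= 2 MHz."""
        step = 0.1
        scan = np.arange(9.0, 19.2001, step)
        sf = simulate_spectrum(dist41, system, RectSpec(14.1, 10.0, 0.1), scan)
        sf_spec = Spectrum(scan, sf.effect)
        offs = np.arange(-5.0, 5.0001, step)
        for bw in (1.0, 2.0):
            pulse = ChirpSpec(14.1, bw, 40.0, edge_time=0.2, peak_amplitude=0.1)
            sim = simulate_spectrum(dist41, system, pulse, scan)
            prof = excitation_profile(pulse, offs)
            conv = convolve_sf_spectrum(sf_spec, prof, normalize=True)
            simn = sim.effect / sim.effect.max()
            rms = np.sqrt(np.mean((conv.intensities - simn) ** 2))
            assert rms <= 0.10
            # peak positions agree within one grid step on the upper side
            upper = scan > 14.1
            p_sim = scan[upper][np.argmax(simn[upper])]
            p_conv = scan[upper][np.argmax(conv.intensities[upper])]
            assert abs(p_sim - p_conv) <= step + 1e-9
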