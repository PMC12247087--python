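import numpy as np
import pytest

from chirpendor import (
    ChirpSpec,
    RectSpec,
    TwoSpinSystem,
    build_hamiltonian,
    endor_signal,
    gaussian_weights,
    initial_state,
    manifold_propagate,
    propagate,
    sample_chirp,
    sample_rect,
)
from chirpendor.spin import I_Z_S_Z, S_Z
from chirpendor import HyperfineDistribution


class TestGaussianWeights:
    def test_mode_density_value(self):
        # continuous density at the mean: 1/sqrt(2 pi sigma^2) for sigma = 0.5
        dist = HyperfineDistribution(mean=4.0, sigma=0.5)
        assert dist.density(4.0) == pytest.approx(0.7979, abs=1e-4)

    def test_weights_symmetric_and_normalized(self):
        grid, w = gaussian_weights(4.0, 0.5, n_points=81, truncation=4.0)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(w, w[::-1], atol=1e-15)
        np.testing.assert_allclose(grid[0], 2.0)
        np.testing.assert_allclose(grid[-1], 6.0)

    @pytest.mark.parametrize(
        "sigma,n_points", [(0.5, 80), (0.5, 2), (0.0, 81), (-1.0, 81)]
    )
    def test_invalid_parameters_rejected(self, sigma, n_points):
        with pytest.raises(ValueError):
            gaussian_weights(4.0, sigma, n_points)


class TestInitialStateAndSignal:
    def test_two_spin_order_is_traceless_unit_signal(self):
        rho = initial_state()
        assert abs(np.trace(rho)) <= 1e-15
        assert endor_signal(rho) == pytest.approx(1.0)
        # normalized inner product <2IzSz | 2IzSz> = Tr(rho 2IzSz)/Tr((2IzSz)^2)
        two_izsz = 2 * I_Z_S_Z
        num = np.trace(rho @ two_izsz).real
        den = np.trace(two_izsz @ two_izsz).real
        assert num / den == pytest.approx(1.0)

    def test_signal_sign_flip(self):
        assert endor_signal(-initial_state()) == pytest.approx(-1.0)

    def test_ideal_pi_on_beta_manifold_gives_zero(self):
        # swapping the |ba> and |bb> populations of 2IzSz nulls the echo
        rho = np.diag([0.5, -0.5, 0.5, -0.5]).astype(complex)
        assert endor_signal(rho) == pytest.approx(0.0)


class TestHamiltonian:
    def test_diagonal_at_zero_drive_with_first_order_splittings(self, system):
        h = build_hamiltonian(system, 0.0)
        assert np.max(np.abs(h - np.diag(np.diag(h)))) == 0.0
        # nuclear transition frequencies within each electron manifold
        d = np.diag(h).real
        assert abs(d[0] - d[1]) == pytest.approx(16.1)
        assert abs(d[2] - d[3]) == pytest.approx(12.1)

    def test_commutes_with_electron_z(self, system):
        h = build_hamiltonian(system, 0.37)
        assert np.max(np.abs(h @ S_Z - S_Z @ h)) <= 1e-14

    def test_drive_enters_as_nuclear_x_matrix_elements(self, system):
        h = build_hamiltonian(system, 0.1)
        assert h[0, 1] == pytest.approx(0.05)
        assert h[2, 3] == pytest.approx(0.05)
        assert h[0, 2] == 0 and h[1, 3] == 0  # no electron flips


class TestPropagation:
    def test_zero_drive_leaves_populations_unchanged(self, system):
        wf = sample_rect(RectSpec(14.1, 1.0, peak_amplitude=0.0))
        rho = propagate(initial_state(), system, wf)
        np.testing.assert_allclose(np.diag(rho), np.diag(initial_state()), atol=1e-12)

    def test_resonant_pi_pulse_nulls_the_signal(self, system):
        # 10 us rect at nu_H + A/2 with nu2max = 0.1 MHz: effective nutation
        # 50 kHz, a pi pulse on the electron-alpha nuclear transition
        wf = sample_rect(RectSpec(16.1, 10.0, peak_amplitude=0.1))
        sig = endor_signal(manifold_propagate(initial_state(), system, wf))
        assert abs(sig) <= 0.02

    def test_unitarity_preserves_trace_and_spectrum(self, system):
        wf = sample_chirp(ChirpSpec(15.5, 1.0, 2.0, peak_amplitude=0.3,
                                    sample_period=0.002))
        rho0 = initial_state()
        rho = propagate(rho0, system, wf)
        assert abs(np.trace(rho)) <= 1e-12
        assert np.max(np.abs(rho - rho.conj().T)) <= 1e-12
        ev0 = np.sort(np.linalg.eigvalsh(rho0))
        ev1 = np.sort(np.linalg.eigvalsh(rho))
        assert np.max(np.abs(ev0 - ev1)) <= 1e-10

    def test_full_and_manifold_block_paths_agree(self, system):
        wf = sample_chirp(ChirpSpec(15.8, 0.5, 2.0, peak_amplitude=0.3,
                                    sample_period=0.002))
        rho0 = initial_state()
        full = propagate(rho0, system, wf)
        blocks = manifold_propagate(rho0, system, wf)
        assert np.max(np.abs(full - blocks)) <= 1e-10
        assert endor_signal(full) == pytest.approx(endor_signal(blocks), abs=1e-10)

    def test_rwa_nutation_envelope(self, system):
        # on-resonance rect drive: the driven manifold's population difference
        # nutates as cos(2 pi (nu2max/2) t_p); counter-rotating error ~0.004
        for tp in (2.5, 5.0, 7.5, 10.0):
            wf = sample_rect(RectSpec(16.1, tp, peak_amplitude=0.1))
            rho = manifold_propagate(initial_state(), system, wf)
            pop_diff = (rho[0, 0] - rho[1, 1]).real
            assert pop_diff == pytest.approx(np.cos(2 * np.pi * 0.05 * tp), abs=0.02)

    def test_non_hermitian_input_rejected(self, system):
        wf = sample_rect(RectSpec(14.1, 0.1, peak_amplitude=0.1))
        bad = initial_state()
        bad[0, 1] = 1.0
        with pytest.raises(ValueError, match="Hermitian"):
            propagate(bad, system, wf)

    def test_coarse_carrier_sampling_rejected(self, system):
        from chirpendor.pulses import Waveform

        wf = Waveform(0.05, np.zeros(10), np.zeros(10), np.full(10, 14.1))
        with pytest.raises(ValueError, match="coarse"):
            propagate(initial_state(), system, wf)
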