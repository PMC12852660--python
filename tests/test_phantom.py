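"""Phantom generator: protocol table, field statistics, FODs, noise model."""

import numpy as np
import pytest

import sminr
from sminr import sh
from sminr.phantom import NoiseSpec, add_noise, generate_phantom, simulate_signals


class TestOptimizedProtocol:
    def test_shell_table(self, protocol):
        assert protocol.n_measurements == 154
        assert np.all(protocol.b_delta >= 0)  # analytic path valid
        dw = protocol.b > 0
        norms = np.linalg.norm(protocol.u[dw], axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)

    def test_deterministic(self):
        p1 = sminr.optimized_protocol(seed=3)
        p2 = sminr.optimized_protocol(seed=3)
        np.testing.assert_array_equal(p1.u, p2.u)


class TestGeneratePhantom:
    def test_bounds_and_de_ordering(self, small_phantom):
        k = small_phantom.kernel
        m = small_phantom.mask
        assert np.all((k.f_i[m] >= 0.3) & (k.f_i[m] <= 0.8))
        assert np.all((k.D_i[m] >= 1.5) & (k.D_i[m] <= 3.0))
        assert np.all((k.De_par[m] >= 1.0) & (k.De_par[m] <= 2.5))
        assert np.all(k.De_perp[m] <= 1.5)
        assert np.all(k.De_par[m] > k.De_perp[m])

    def test_spatial_autocorrelation(self):
        ph = generate_phantom((16, 16, 16), lmax=2, seed=1, smoothness_vox=3.0,
                              mask_type="full")
        f = ph.kernel.f_i
        a = f[:-1].ravel() - f[:-1].mean()
        b = f[1:].ravel() - f[1:].mean()
        rho = (a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum())
        assert rho > 0.9

    def test_fod_nonnegative_and_unit_integral(self):
        for config in ("single", "crossing", "fanning"):
            ph = generate_phantom((6, 6, 6), lmax=8, seed=2,
                                  fiber_config=config, mask_type="full")
            np.testing.assert_allclose(
                ph.fod.coeffs[..., 0], 1 / np.sqrt(4 * np.pi), atol=1e-12
            )
            dirs = sh.hemisphere_directions(300, seed=4)
            amp = sminr.fod_amplitude(ph.fod, dirs)
            assert amp.min() > -1e-9

    def test_crossing_peak_separation(self):
        ph = generate_phantom((6, 6, 6), lmax=8, seed=3, fiber_config="crossing",
                              crossing_angle_deg=60.0, kappa=25.0,
                              mask_type="full")
        center = tuple(s // 2 for s in (6, 6, 6))
        fod = sh.FODCoefficients(lmax=8, coeffs=ph.fod.coeffs[center])
        grid = sh.sphere_quadrature(65, 128)
        amp = sminr.fod_amplitude(fod, grid)
        # two strongest well-separated local maxima
        order = np.argsort(amp)[::-1]
        d1 = grid.dirs[order[0]]
        sep = np.abs(grid.dirs[order] @ d1)
        second = order[np.argmax(sep < np.cos(np.deg2rad(25.0)))]
        d2 = grid.dirs[second]
        angle = np.degrees(np.arccos(np.clip(abs(d1 @ d2), 0, 1)))
        assert abs(angle - 60.0) < 5.0

    def test_determinism_and_validation(self):
        a = generate_phantom((5, 5, 5), seed=7)
        b = generate_phantom((5, 5, 5), seed=7)
        np.testing.assert_array_equal(a.fod.coeffs, b.fod.coeffs)
        with pytest.raises(ValueError):
            generate_phantom((3, 3, 3))
        with pytest.raises(ValueError):
            generate_phantom((6, 6, 6), fiber_config="spiral")


class TestSimulateSignals:
    def test_b0_equals_s0_and_monotone_shells(self, small_phantom,
                                              noiseless_signals, protocol):
        m = small_phantom.mask
        b0 = noiseless_signals.data[..., protocol.b == 0]
        np.testing.assert_allclose(b0[m], 1.0, atol=1e-12)
        # LTE shell-mean signal decreases with b
        lte = np.abs(protocol.b_delta - 1.0) < 1e-9
        means = []
        for b in sorted(set(protocol.b[lte])):
            sel = lte & (protocol.b == b)
            means.append(noiseless_signals.data[m][:, sel].mean())
        assert np.all(np.diff(means) < 0)

    def test_outside_mask_is_zero(self, protocol):
        ph = generate_phantom((8, 8, 8), seed=1, mask_type="ellipsoid")
        sig = simulate_signals(ph, protocol)
        assert np.all(sig.data[~ph.mask] == 0)


class TestAddNoise:
    def test_none_is_identity(self, noiseless_signals, protocol):
        noisy, sigma = add_noise(noiseless_signals, protocol,
                                 NoiseSpec(kind="none", snr=20))
        np.testing.assert_array_equal(noisy.data, noiseless_signals.data)
        assert np.all(sigma.data == 0)

    def test_sigma_rule(self, small_phantom, noiseless_signals, protocol):
        # S0 = 1, SNR = 20 -> sigma = 0.05 in every masked voxel
        _, sigma = add_noise(noiseless_signals, protocol,
                             NoiseSpec(kind="gaussian", snr=20, seed=1))
        np.testing.assert_allclose(sigma.data[small_phantom.mask], 0.05,
                                   atol=1e-12)

    def test_rician_positive_and_rayleigh_mean(self, rng):
        # zero signal + Rician noise has mean sigma * sqrt(pi / 2)
        sigma = 0.3
        n = 10**5
        draws = np.sqrt(
            (sigma * rng.standard_normal(n)) ** 2
            + (sigma * rng.standard_normal(n)) ** 2
        )
        expected = sigma * np.sqrt(np.pi / 2)
        se = sigma * np.sqrt((4 - np.pi) / 2) / np.sqrt(n)
        assert abs(draws.mean() - expected) < 4 * se

    def test_rician_volume_positive_and_deterministic(
        self, noiseless_signals, protocol
    ):
        spec = NoiseSpec(kind="rician", snr=20, seed=9)
        n1, _ = add_noise(noiseless_signals, protocol, spec)
        n2, _ = add_noise(noiseless_signals, protocol, spec)
        np.testing.assert_array_equal(n1.data, n2.data)
        assert np.all(n1.data >= 0)

    def test_empirical_snr_recovered(self, small_phantom, noiseless_signals,
                                     protocol):
        noisy, _ = add_noise(noiseless_signals, protocol,
                             NoiseSpec(kind="gaussian", snr=20, seed=4))
        b0 = noisy.data[small_phantom.mask][:, protocol.b == 0]
        # pooled sigma estimate from b0 repeats across voxels
        sigma_hat = np.sqrt(
            np.mean((b0 - b0.mean(axis=1, keepdims=True)) ** 2)
            * b0.shape[1] / (b0.shape[1] - 1)
        )
        snr_hat = b0.mean() / sigma_hat
        assert abs(snr_hat - 20) / 20 < 0.1

    def test_invalid_snr(self):
        with pytest.raises(ValueError):
            NoiseSpec(kind="gaussian", snr=0)


class TestHarmonicMode:
    def test_continuous_truth_matches_grid(self):
        ph = generate_phantom((8, 8, 8), seed=6, field_mode="harmonic",
                              mask_type="full")
        vox = np.argwhere(ph.mask).astype(float)
        truth = ph.kernel_truth_at(vox)
        for name in ("f_i", "D_i", "De_par", "De_perp"):
            np.testing.assert_allclose(
                truth[name], getattr(ph.kernel, name)[ph.mask], atol=1e-12
            )

    def test_grid_mode_has_no_continuous_truth(self, small_phantom):
        with pytest.raises(ValueError, match="harmonic"):
            small_phantom.kernel_truth_at(np.zeros((1, 3)))
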