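"""Losses, the FOD non-negativity penalty, and the self-supervised trainer."""

import numpy as np
import pytest

import sminr
from sminr.fitting import (
    FitConfig,
    fit_inr,
    fod_nonneg_penalty,
    mse_loss,
    rician_nll_loss,
    upsample,
)
from sminr.forward import AnalyticForward, KernelParams
from sminr.sh import FODCoefficients, hemisphere_directions
from tests.conftest import mask_grid


class TestMSELoss:
    def test_examples(self):
        assert mse_loss([1.0, 1.0], [1.0, 1.0]) == 0.0
        assert mse_loss([1.0, 1.0], [0.0, 2.0]) == 1.0
        # pairing matters: no hidden sorting
        assert mse_loss([1.0, 2.0], [2.0, 1.0]) != mse_loss([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            mse_loss([1.0], [1.0, 2.0])


class TestRicianLoss:
    def test_estimator_consistency_monte_carlo(self, rng):
        # Rician draws with true amplitude 1, sigma 0.25: the Rician-NLL
        # minimizer recovers the amplitude; the MSE minimizer recovers the
        # (biased) Rician mean > 1
        n = 10**5
        sigma = 0.25
        draws = np.sqrt(
            (1.0 + sigma * rng.standard_normal(n)) ** 2
            + (sigma * rng.standard_normal(n)) ** 2
        )
        nus = np.linspace(0.7, 1.4, 281)
        ric = [rician_nll_loss(draws, np.full(n, v), np.full(n, sigma)) for v in nus]
        mse = [mse_loss(draws, np.full(n, v)) for v in nus]
        nu_ric = nus[int(np.argmin(ric))]
        nu_mse = nus[int(np.argmin(mse))]
        assert abs(nu_ric - 1.0) < 0.01
        assert nu_mse > 1.01  # overshoots toward the Rician mean

    def test_small_sigma_limit_peaks_at_observation(self):
        s_meas = 0.8
        nus = np.linspace(0.5, 1.1, 601)
        losses = [
            rician_nll_loss([s_meas], [v], [0.005]) for v in nus
        ]
        assert abs(nus[int(np.argmin(losses))] - s_meas) < 0.005

    def test_log_i0_overflow_guard(self):
        # S * nu / sigma^2 = 1e6 must stay finite
        val = rician_nll_loss([1000.0], [1000.0], [1.0])
        assert np.isfinite(val)

    def test_sigma_validation(self):
        with pytest.raises(ValueError):
            rician_nll_loss([1.0], [1.0], [0.0])


@pytest.fixture(scope="module")
def cdirs():
    return hemisphere_directions(300, seed=0)


class TestNonnegPenalty:
    def test_isotropic_positive_fod_is_free(self, cdirs):
        assert fod_nonneg_penalty(FODCoefficients.isotropic(2), cdirs) == 0.0

    def test_constant_negative_amplitude(self, cdirs):
        c = np.zeros(6)
        c[0] = -1.0
        pen = fod_nonneg_penalty(FODCoefficients(lmax=2, coeffs=c), cdirs)
        assert abs(pen - 1.0 / np.sqrt(4 * np.pi)) < 1e-12

    def test_positive_homogeneity(self, cdirs, rng):
        c = rng.normal(0, 0.3, 15)
        p1 = fod_nonneg_penalty(FODCoefficients(lmax=4, coeffs=c), cdirs)
        p3 = fod_nonneg_penalty(FODCoefficients(lmax=4, coeffs=3 * c), cdirs)
        assert abs(p3 - 3 * p1) < 1e-12


@pytest.fixture(scope="module")
def noiseless_fit(small_phantom, noiseless_signals, protocol):
    # batch 128 on the 512-voxel fixture gives 8 optimizer steps per epoch,
    # enough for the 150-epoch budget to converge into the sub-percent regime
    cfg = FitConfig(
        loss="mse", epochs=150, batch_size=128, lmax=2, n_p=256, n_h=256,
        sigma2=1.0, seed=0, learning_rate=3e-4,
    )
    model, trace = fit_inr(
        noiseless_signals, protocol, mask_grid(small_phantom), cfg
    )
    return model, trace


class TestFitInr:
    def test_noiseless_signal_rmse_below_one_percent(
        self, noiseless_fit, small_phantom, noiseless_signals, protocol
    ):
        model, _ = noiseless_fit
        mask = small_phantom.mask
        vox = np.argwhere(mask).astype(float)
        params, fod = sminr.predict(model, vox)
        fwd = AnalyticForward(protocol, 2)
        S_pred = fwd.signal(
            params.f_i, params.D_i, params.De_par, params.De_perp, params.S0,
            fod.coeffs,
        )
        S_true = noiseless_signals.data[mask]
        rmse = np.sqrt(np.mean((S_pred - S_true) ** 2))
        b0_mean = S_true[:, protocol.b == 0].mean()
        assert rmse < 0.01 * b0_mean

    def test_loss_decreases(self, noiseless_fit):
        _, trace = noiseless_fit
        assert trace[-1] < trace[0]

    def test_constant_phantom_low_spatial_variation(self, protocol):
        # uniform ground truth: predicted maps should be near-constant
        shape = (6, 6, 6)
        mask = np.ones(shape, dtype=bool)
        kernel = KernelParams(
            f_i=np.full(shape, 0.55), D_i=np.full(shape, 2.3),
            De_par=np.full(shape, 1.9), De_perp=np.full(shape, 0.7),
            S0=np.ones(shape),
        )
        c = np.zeros(shape + (6,))
        c[..., 0] = 1 / np.sqrt(4 * np.pi)
        c[..., 3] = 0.15
        ph = sminr.Phantom(
            grid=sminr.VolumeGrid(data=np.zeros(shape)),
            kernel=kernel, fod=FODCoefficients(lmax=2, coeffs=c),
            mask=mask,
        )
        sig = sminr.simulate_signals(ph, protocol)
        cfg = FitConfig(epochs=150, lmax=2, n_p=128, n_h=64, sigma2=3.5,
                        seed=1, learning_rate=3e-4)
        model, _ = fit_inr(sig, protocol, mask_grid(ph), cfg)
        params, _ = sminr.predict(model, np.argwhere(mask).astype(float))
        for name in ("f_i", "D_i", "De_par", "De_perp"):
            vals = getattr(params, name)
            assert vals.std() / vals.mean() < 0.02

    def test_rician_requires_sigma_map(
        self, small_phantom, noiseless_signals, protocol
    ):
        cfg = FitConfig(loss="rician", epochs=1, lmax=2, n_p=8, n_h=8)
        with pytest.raises(ValueError, match="sigma"):
            fit_inr(noiseless_signals, protocol, mask_grid(small_phantom), cfg)

    def test_measurement_count_mismatch(self, small_phantom, protocol):
        bad = sminr.VolumeGrid(data=np.zeros(small_phantom.mask.shape + (3,)))
        cfg = FitConfig(epochs=1, lmax=2, n_p=8, n_h=8)
        with pytest.raises(ValueError, match="4th dimension"):
            fit_inr(bad, protocol, mask_grid(small_phantom), cfg)

    def test_numeric_path_selected_for_planar_encoding(self, rng):
        # a protocol with negative b_delta must train through the quadrature
        # path; the loss still decreases
        n_m = 12
        u = rng.standard_normal((n_m, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        b = np.r_[0.0, np.full(n_m - 1, 2.0)]
        bdelta = np.r_[1.0, np.full(5, -0.5), np.full(6, 1.0)]
        prot = sminr.AcquisitionProtocol(b=b, b_delta=bdelta, u=u)
        shape = (4, 4, 4)
        kernel = KernelParams(
            f_i=np.full(shape, 0.5), D_i=np.full(shape, 2.2),
            De_par=np.full(shape, 1.8), De_perp=np.full(shape, 0.6),
            S0=np.ones(shape),
        )
        c = np.zeros(shape + (6,))
        c[..., 0] = 1 / np.sqrt(4 * np.pi)
        ph = sminr.Phantom(
            grid=sminr.VolumeGrid(data=np.zeros(shape)), kernel=kernel,
            fod=FODCoefficients(lmax=2, coeffs=c),
            mask=np.ones(shape, dtype=bool),
        )
        fwd = sminr.sm_signal_numeric(kernel, ph.fod, prot)
        dwi = sminr.VolumeGrid(data=fwd)
        cfg = FitConfig(epochs=8, lmax=2, n_p=16, n_h=16, seed=0,
                        integration="analytic", learning_rate=1e-3)
        model, trace = fit_inr(dwi, prot, mask_grid(ph), cfg)
        assert trace[-1] < trace[0]

    def test_identity_gradient_tensor_bit_identical(
        self, small_phantom, noiseless_signals, protocol
    ):
        cfg = FitConfig(epochs=5, lmax=2, n_p=32, n_h=16, seed=2)
        shape = small_phantom.mask.shape
        ident = sminr.GradientTensorField(
            L=np.tile(np.eye(3), shape + (1, 1))
        )
        m1, t1 = fit_inr(noiseless_signals, protocol,
                         mask_grid(small_phantom), cfg)
        m2, t2 = fit_inr(noiseless_signals, protocol,
                         mask_grid(small_phantom), cfg, grad_tensor=ident)
        assert t1 == t2
        for k in m1.weights:
            np.testing.assert_array_equal(m1.weights[k], m2.weights[k])


class TestUpsample:
    def test_factor_one_reproduces_grid_predictions(self, noiseless_fit,
                                                    small_phantom):
        model, _ = noiseless_fit
        grid = small_phantom.grid
        maps = upsample(model, grid, factor=1)
        vox = np.argwhere(np.ones(grid.shape, dtype=bool)).astype(float)
        direct = model.forward(model.scale(vox)).reshape(maps.data.shape)
        np.testing.assert_array_equal(maps.data, direct)

    def test_factor_eight_finite_maps(self, noiseless_fit, small_phantom):
        model, _ = noiseless_fit
        maps = upsample(model, small_phantom.grid, factor=8)
        assert maps.data.shape == (64, 64, 64, model.n_outputs)
        assert np.all(np.isfinite(maps.data))
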