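"""Standard Model forward operator: kernels, both signal paths, effective protocols."""

import numpy as np
import pytest
from scipy.special import erf

import sminr
from sminr import sh
from sminr.forward import (
    KernelParams,
    effective_protocol,
    sm_signal_analytic,
    sm_signal_numeric,
    zeppelin_kernel,
)


def random_case(rng, lmax):
    params = KernelParams(
        f_i=rng.uniform(0.2, 0.9),
        D_i=rng.uniform(1.0, 3.5),
        De_par=rng.uniform(1.0, 3.0),
        De_perp=rng.uniform(0.1, 0.9),
        S0=rng.uniform(0.5, 2.0),
    )
    c = np.r_[1 / np.sqrt(4 * np.pi), rng.normal(0, 0.06, sh.n_coeffs(lmax) - 1)]
    return params, sh.FODCoefficients(lmax=lmax, coeffs=c)


class TestZeppelinKernel:
    def test_b_zero_is_one(self):
        assert zeppelin_kernel(0.0, 1.0, 0.3, 2.0, 0.5) == 1.0

    def test_isotropic_collapses_to_md_decay(self):
        # equal diffusivities: exp(-b D), independent of shape and angle
        for bd, t in [(1.0, 0.2), (0.0, 0.9), (-0.5, 0.5)]:
            v = zeppelin_kernel(2.0, bd, t, 1.7, 1.7)
            assert abs(v - np.exp(-2.0 * 1.7)) < 1e-12

    def test_linear_encoding_axial_decay(self):
        v = zeppelin_kernel(3.0, 1.0, 1.0, 2.2, 0.0)
        assert abs(v - np.exp(-3.0 * 2.2)) < 1e-12


class TestAnalyticSignal:
    def test_b0_identity(self, protocol, rng):
        params, fod = random_case(rng, 4)
        S = sm_signal_analytic(params, fod, protocol)
        expected = float(params.S0) * np.sqrt(4 * np.pi) * fod.coeffs[0]
        np.testing.assert_allclose(S[protocol.b == 0], expected, rtol=1e-12)

    def test_isotropic_stick_orientation_average(self):
        # f_i = 1, isotropic unit FOD, b D_i = 3: closed-form erf average
        prot = sminr.AcquisitionProtocol(
            b=np.array([1.0]), b_delta=np.array([1.0]), u=np.array([[0, 0, 1.0]])
        )
        params = KernelParams(f_i=1.0, D_i=3.0, De_par=2.0, De_perp=0.5, S0=1.0)
        S = sm_signal_analytic(params, sh.FODCoefficients.isotropic(2), prot)
        expected = np.sqrt(np.pi / 12.0) * erf(np.sqrt(3.0))
        assert abs(S[0] - expected) < 1e-6

    def test_spherical_encoding_biexponential(self, rng):
        # bD = 0 kills all angular structure: orientation-independent decay
        params, fod = random_case(rng, 4)
        b = 2.0
        us = rng.standard_normal((5, 3))
        us /= np.linalg.norm(us, axis=1, keepdims=True)
        prot = sminr.AcquisitionProtocol(
            b=np.full(5, b), b_delta=np.zeros(5), u=us
        )
        S = sm_signal_analytic(params, fod, prot)
        f, Di = float(params.f_i), float(params.D_i)
        Dp, Dv = float(params.De_par), float(params.De_perp)
        expected = (
            float(params.S0) * np.sqrt(4 * np.pi) * fod.coeffs[0]
            * (f * np.exp(-b * Di / 3) + (1 - f) * np.exp(-b * (Dp + 2 * Dv) / 3))
        )
        np.testing.assert_allclose(S, expected, rtol=1e-10)
        # higher-order coefficients must not matter
        c2 = fod.coeffs.copy()
        c2[1:] = rng.normal(0, 0.2, c2.size - 1)
        S2 = sm_signal_analytic(
            params, sh.FODCoefficients(lmax=4, coeffs=c2), prot
        )
        np.testing.assert_allclose(S2, expected, rtol=1e-10)

    def test_validity_contract(self, protocol):
        params = KernelParams(f_i=0.5, D_i=2.0, De_par=1.0, De_perp=1.2, S0=1.0)
        with pytest.raises(ValueError, match="numeric"):
            sm_signal_analytic(params, sh.FODCoefficients.isotropic(2), protocol)
        prot_neg = sminr.AcquisitionProtocol(
            b=np.array([1.0]), b_delta=np.array([-0.5]), u=np.array([[0, 0, 1.0]])
        )
        good = KernelParams(f_i=0.5, D_i=2.0, De_par=2.0, De_perp=0.5, S0=1.0)
        with pytest.raises(ValueError, match="numeric"):
            sm_signal_analytic(good, sh.FODCoefficients.isotropic(2), prot_neg)

    def test_monotone_decay_with_b(self, rng):
        params, fod = random_case(rng, 2)
        b = np.linspace(0, 8, 9)
        prot = sminr.AcquisitionProtocol(
            b=b, b_delta=np.ones(9), u=np.tile([0, 0, 1.0], (9, 1))
        )
        S = sm_signal_analytic(params, fod, prot)
        assert np.all(np.diff(S) < 0)


class TestCrossPath:
    @pytest.mark.parametrize("lmax", [2, 4, 6, 8])
    def test_analytic_numeric_agreement(self, lmax, protocol, rng):
        for _ in range(8):
            params, fod = random_case(rng, lmax)
            Sa = sm_signal_analytic(params, fod, protocol)
            Sn = sm_signal_numeric(params, fod, protocol)
            assert np.abs((Sa - Sn) / np.abs(Sa)).max() < 1e-3

    def test_numeric_negative_bdelta_monte_carlo(self, rng):
        # planar encoding, extra-axonal only: quadrature vs dense Monte Carlo
        params = KernelParams(f_i=0.0, D_i=2.0, De_par=2.0, De_perp=0.5, S0=1.0)
        prot = sminr.AcquisitionProtocol(
            b=np.array([2.0]), b_delta=np.array([-0.5]), u=np.array([[0, 0, 1.0]])
        )
        S = sm_signal_numeric(params, sh.FODCoefficients.isotropic(2), prot)
        n = 10**6
        v = rng.standard_normal((n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        t2 = v[:, 2] ** 2
        g = 2.0 * (-0.5)
        delta = 2.0 - 0.5
        samples = np.exp(-g * delta * t2)
        pref = np.exp((g * delta - 2.0 * (2.0 + 2 * 0.5)) / 3.0)
        mc = pref * samples.mean()
        se = pref * samples.std() / np.sqrt(n)
        assert abs(S[0] - mc) < 3 * se

    def test_quadrature_self_convergence(self, protocol, rng):
        params, fod = random_case(rng, 8)
        S1 = sm_signal_numeric(params, fod, protocol,
                               quadrature=sh.sphere_quadrature(33, 64))
        S2 = sm_signal_numeric(params, fod, protocol,
                               quadrature=sh.sphere_quadrature(65, 128))
        assert np.abs(S1 - S2).max() < 1e-6

    def test_coarse_grid_rejected(self, protocol):
        with pytest.raises(ValueError, match="coarse"):
            sminr.forward.NumericForward(
                protocol, 8, quadrature=sh.sphere_quadrature(5, 8)
            )


class TestRotationalEquivariance:
    def test_joint_rotation_leaves_signal_unchanged(self, protocol, rng):
        from scipy.spatial.transform import Rotation

        quad_grid = sh.sphere_quadrature()
        B = sh.real_sh_basis(4, quad_grid)
        for k in range(5):
            params, fod = random_case(rng, 4)
            R = Rotation.random(random_state=k).as_matrix()
            # rotated FOD: FOD'(n) = FOD(R^T n), i.e. resample at dirs @ R
            amp_rot = sh.fod_amplitude(fod, quad_grid.dirs @ R)
            coeffs_rot = B.T @ (quad_grid.weights * amp_rot)
            fod_rot = sh.FODCoefficients(lmax=4, coeffs=coeffs_rot)
            prot_rot = sminr.AcquisitionProtocol(
                b=protocol.b, b_delta=protocol.b_delta,
                u=protocol.u @ R.T, b0_replaced=protocol.b0_replaced,
            )
            S1 = sm_signal_analytic(params, fod, protocol)
            S2 = sm_signal_analytic(params, fod_rot, prot_rot)
            assert np.abs(S1 - S2).max() < 1e-5


class TestEffectiveProtocol:
    def test_identity_tensor_is_noop(self, protocol):
        pe = effective_protocol(protocol, np.eye(3))
        np.testing.assert_allclose(pe.b, protocol.b, atol=1e-12)
        np.testing.assert_allclose(pe.b_delta, protocol.b_delta, atol=1e-10)
        dw = protocol.b > 0
        axis_dot = np.abs((pe.u[dw] * protocol.u[dw]).sum(axis=1))
        np.testing.assert_allclose(axis_dot, 1.0, atol=1e-9)

    def test_uniform_scaling(self, protocol):
        c = 1.07
        pe = effective_protocol(protocol, c * np.eye(3))
        np.testing.assert_allclose(pe.b, c * c * protocol.b, rtol=1e-12)
        np.testing.assert_allclose(pe.b_delta, protocol.b_delta, atol=1e-10)

    def test_spherical_shell_eigen_oracle(self, protocol, rng):
        L = np.eye(3) + 0.2 * rng.standard_normal((3, 3))
        pe = effective_protocol(protocol, L)
        i = int(np.argmax((protocol.b_delta == 0) & (protocol.b > 0)))
        b = protocol.b[i]
        lam = np.linalg.eigvalsh((b / 3) * L @ L.T)
        b_eff = lam.sum()
        d = 1.5 * lam - 0.5 * b_eff
        k = np.argmax(np.abs(d))
        assert abs(pe.b[i] - b_eff) < 1e-12
        assert abs(pe.b_delta[i] - d[k] / b_eff) < 1e-12

    def test_degenerate_tensor_rejected(self, protocol):
        with pytest.raises(ValueError, match="degenerate"):
            effective_protocol(protocol, np.zeros((3, 3)))
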