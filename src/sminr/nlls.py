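"""Voxel-wise nonlinear least-squares fitting of the Standard Model.

The classic comparator: each voxel is fit independently by minimizing the
sum of squared signal residuals over the joint parameter vector
[f_i, D_i, De_par, De_perp, S0, p_l^m...] using the analytic forward path.
Physiological bounds are enforced by a smooth reparameterization (sigmoids
for the bounded kernel parameters, De_perp expressed as a fraction of
De_par so the analytic path's ordering is respected, log-scale S0), so the
optimizer itself runs unconstrained trust-region least squares with the
exact analytic Jacobian.  Two initializations are fitted per voxel — one
data-driven, one random within bounds — and the solution with the smallest
residual norm is kept.  No FOD non-negativity constraint is applied here.

The FOD is kept at unit integral by pinning p_0^0 = 1/sqrt(4 pi): S0 and
the FOD scale enter the forward model only through their product, so fitting
both would leave the joint scale unidentifiable; the pin resolves the
degeneracy with the conventional normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .forward import AnalyticForward, effective_protocol_field
from .io import AcquisitionProtocol, GradientTensorField, VolumeGrid
from .sh import n_coeffs

logger = logging.getLogger(__name__)

__all__ = ["NLLSResult", "nlls_fit_voxel", "nlls_fit_volume"]

_SIG_CLIP = 12.0  # logit clip keeping initial guesses away from saturation


@dataclass
class NLLSResult:
    """Best-of-initializations voxel fit (arrays in the volume version)."""

    f_i: np.ndarray
    D_i: np.ndarray
    De_par: np.ndarray
    De_perp: np.ndarray
    S0: np.ndarray
    coeffs: np.ndarray
    residual_norm: np.ndarray
    converged: np.ndarray
    init_index: np.ndarray
    identifiable: np.ndarray


def _sigmoid(v):
    from scipy.special import expit

    return expit(v)


def _logit(p):
    p = np.clip(p, _sigmoid(-_SIG_CLIP), _sigmoid(_SIG_CLIP))
    return np.log(p / (1.0 - p))


_P00 = 1.0 / np.sqrt(4.0 * np.pi)  # pinned unit-integral FOD mean


def _unpack(v, s0_ref, C):
    f = _sigmoid(v[0])
    D_i = 4.0 * _sigmoid(v[1])
    De_par = 4.0 * _sigmoid(v[2])
    frac = _sigmoid(v[3])
    De_perp = frac * De_par
    S0 = s0_ref * np.exp(v[4])
    p = np.concatenate([[_P00], v[5 : 4 + C]])
    return f, D_i, De_par, De_perp, S0, p, frac


def _pack(f, D_i, De_par, frac, S0, p_rest, s0_ref):
    return np.concatenate(
        [
            [_logit(f), _logit(D_i / 4.0), _logit(De_par / 4.0), _logit(frac),
             np.log(max(S0, 1e-9) / s0_ref)],
            p_rest,
        ]
    )


def _residual_and_jac(v, fwd, signal, s0_ref, C, want_jac):
    f, D_i, De_par, De_perp, S0, p, frac = _unpack(v, s0_ref, C)
    S, g = fwd.signal_and_gradients(
        np.array([f]), np.array([D_i]), np.array([De_par]),
        np.array([De_perp]), np.array([S0]), p[None],
    )
    res = S[0] - signal
    if not want_jac:
        return res
    M = signal.shape[0]
    J = np.zeros((M, 4 + C))
    # chain rule through the smooth reparameterization
    J[:, 0] = g["f_i"][0] * f * (1.0 - f)
    J[:, 1] = g["D_i"][0] * D_i * (1.0 - D_i / 4.0)
    dDe_par_dv = De_par * (1.0 - De_par / 4.0)
    J[:, 2] = (g["De_par"][0] + g["De_perp"][0] * frac) * dDe_par_dv
    J[:, 3] = g["De_perp"][0] * De_par * frac * (1.0 - frac)
    J[:, 4] = g["S0"][0] * S0
    J[:, 5:] = fwd.p_jacobian(g)[0][:, 1:]  # p00 pinned
    return res, J


def _data_driven_init(signal, protocol, C, s0_ref):
    """Powder-average log-linear heuristics for the diffusivity starting point."""
    b0 = protocol.b == 0
    lte = (protocol.b > 0) & (np.abs(protocol.b_delta - 1.0) < 1e-9)
    s0 = max(float(signal[b0].mean()) if b0.any() else float(signal.max()), 1e-9)
    D_md = 1.0
    if lte.any():
        b_low = np.min(protocol.b[lte])
        sel = lte & (protocol.b == b_low)
        powder = max(float(signal[sel].mean()), 1e-9)
        D_md = float(np.clip(-np.log(powder / s0) / b_low, 0.1, 3.0))
    return _pack(
        f=0.5, D_i=np.clip(2.5 * D_md, 0.5, 3.8), De_par=np.clip(2.0 * D_md, 0.5, 3.8),
        frac=0.3, S0=s0, p_rest=np.zeros(C - 1), s0_ref=s0_ref,
    )


def _random_init(rng, C, s0_ref, s0_guess):
    return _pack(
        f=rng.uniform(0.2, 0.8),
        D_i=rng.uniform(1.0, 3.5),
        De_par=rng.uniform(0.8, 3.0),
        frac=rng.uniform(0.15, 0.7),
        S0=s0_guess * rng.uniform(0.8, 1.25),
        p_rest=rng.normal(0.0, 0.05, C - 1),
        s0_ref=s0_ref,
    )


def nlls_fit_voxel(
    signal: np.ndarray,
    protocol: AcquisitionProtocol,
    lmax: int = 2,
    n_init: int = 2,
    max_iter: int = 1000,
    seed: int = 0,
    fwd: AnalyticForward | None = None,
) -> NLLSResult:
    """Multi-start NLLS fit of one voxel's signal vector.

    Deterministic given the seed.  If every measurement is b = 0 the
    diffusivities are unidentifiable: S0 is set to the b = 0 mean and the
    result is flagged.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.shape != (protocol.n_measurements,):
        raise ValueError("signal length must match the protocol")
    C = n_coeffs(lmax)
    if not np.any(protocol.b > 0):
        p = np.zeros(C)
        p[0] = 1.0 / np.sqrt(4.0 * np.pi)
        # S = S0 * sqrt(4 pi) * p00 = S0 for the unit-integral isotropic FOD
        return NLLSResult(
            f_i=np.float64(0.5), D_i=np.float64(np.nan),
            De_par=np.float64(np.nan), De_perp=np.float64(np.nan),
            S0=np.float64(signal.mean()), coeffs=p,
            residual_norm=np.float64(np.linalg.norm(signal - signal.mean())),
            converged=np.True_, init_index=np.int64(-1), identifiable=np.False_,
        )
    if fwd is None:
        fwd = AnalyticForward(protocol, lmax)
    rng = np.random.default_rng(seed)
    s0_ref = max(float(signal[protocol.b == 0].mean())
                 if np.any(protocol.b == 0) else float(signal.max()), 1e-9)

    inits = [_data_driven_init(signal, protocol, C, s0_ref)]
    for _ in range(max(n_init - 1, 0)):
        inits.append(_random_init(rng, C, s0_ref, s0_ref))

    best = None
    for k, x0 in enumerate(inits):
        try:
            sol = least_squares(
                lambda v: _residual_and_jac(v, fwd, signal, s0_ref, C, False),
                x0,
                jac=lambda v: _residual_and_jac(v, fwd, signal, s0_ref, C, True)[1],
                method="trf",
                max_nfev=max_iter,
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:  # noqa: BLE001 - a failed start is not fatal
            continue
        if best is None or sol.cost < best[0].cost:
            best = (sol, k)
    if best is None:
        nanv = np.float64(np.nan)
        return NLLSResult(
            f_i=nanv, D_i=nanv, De_par=nanv, De_perp=nanv, S0=nanv,
            coeffs=np.full(C, np.nan), residual_norm=np.float64(np.inf),
            converged=np.False_, init_index=np.int64(-1), identifiable=np.True_,
        )
    sol, k = best
    f, D_i, De_par, De_perp, S0, p, _ = _unpack(sol.x, s0_ref, C)
    return NLLSResult(
        f_i=np.float64(f), D_i=np.float64(D_i), De_par=np.float64(De_par),
        De_perp=np.float64(De_perp), S0=np.float64(S0), coeffs=np.asarray(p),
        residual_norm=np.float64(np.sqrt(2.0 * sol.cost)),
        converged=np.bool_(sol.status > 0), init_index=np.int64(k),
        identifiable=np.True_,
    )


def nlls_fit_volume(
    dwi: VolumeGrid,
    protocol: AcquisitionProtocol,
    mask: VolumeGrid,
    lmax: int = 2,
    grad_tensor: GradientTensorField | None = None,
    n_init: int = 2,
    max_iter: int = 1000,
    seed: int = 0,
) -> NLLSResult:
    """Independent per-voxel NLLS fits over a masked volume.

    With a gradient-coil tensor field, every voxel is fit under its own
    effective protocol (identity fields are recognized as a no-op).  Returns
    parameter maps as full-volume arrays (NaN outside the mask).
    """
    mask_arr = np.asarray(mask.data, dtype=bool)
    if not mask_arr.any():
        raise ValueError("empty mask")
    if dwi.data.shape[:3] != mask_arr.shape or dwi.data.ndim != 4:
        raise ValueError("dwi must be 4-D on the mask grid")
    vox = np.argwhere(mask_arr)
    V = vox.shape[0]
    C = n_coeffs(lmax)
    shape = mask_arr.shape

    per_voxel = None
    if grad_tensor is not None and not grad_tensor.is_identity():
        L_vox = grad_tensor.L[mask_arr]
        per_voxel = effective_protocol_field(protocol, L_vox)

    shared_fwd = AnalyticForward(protocol, lmax)

    out = {
        name: np.full(shape, np.nan)
        for name in ("f_i", "D_i", "De_par", "De_perp", "S0", "residual_norm")
    }
    coeffs = np.full(shape + (C,), np.nan)
    conv = np.zeros(shape, dtype=bool)
    init_idx = np.full(shape, -1, dtype=np.int64)
    ident = np.zeros(shape, dtype=bool)

    signals = dwi.data[mask_arr]
    ss = np.random.SeedSequence([seed, 0x51A])
    voxel_seeds = ss.generate_state(V)
    for j in range(V):
        if per_voxel is not None:
            b_eff, bd_eff, u_eff = per_voxel
            if np.any(bd_eff[j] < 0):
                raise ValueError(
                    "effective b_delta < 0 under this coil tensor; the NLLS "
                    "baseline uses the analytic path only"
                )
            fwd = AnalyticForward((b_eff[j][None], bd_eff[j][None]), lmax,
                                  u=u_eff[j][None])
            prot_j = AcquisitionProtocol(
                b=b_eff[j], b_delta=np.clip(bd_eff[j], -0.5, 1.0), u=u_eff[j],
                b0_replaced=protocol.b0_replaced,
            )
        else:
            fwd, prot_j = shared_fwd, protocol
        res = nlls_fit_voxel(
            signals[j].astype(float), prot_j, lmax=lmax, n_init=n_init,
            max_iter=max_iter, seed=int(voxel_seeds[j] % (2**31 - 1)), fwd=fwd,
        )
        i, jj, kk = vox[j]
        for name in ("f_i", "D_i", "De_par", "De_perp", "S0", "residual_norm"):
            out[name][i, jj, kk] = getattr(res, name)
        coeffs[i, jj, kk] = res.coeffs
        conv[i, jj, kk] = bool(res.converged)
        init_idx[i, jj, kk] = int(res.init_index)
        ident[i, jj, kk] = bool(res.identifiable)
        if (j + 1) % 500 == 0:
            logger.info("NLLS: %d / %d voxels fit", j + 1, V)
    return NLLSResult(
        f_i=out["f_i"], D_i=out["D_i"], De_par=out["De_par"],
        De_perp=out["De_perp"], S0=out["S0"], coeffs=coeffs,
        residual_norm=out["residual_norm"], converged=conv,
        init_index=init_idx, identifiable=ident,
    )
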