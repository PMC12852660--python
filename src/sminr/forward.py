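"""Standard Model forward signal: stick + zeppelin kernel convolved with a FOD.

The measured signal is modeled as the spherical convolution of an axially
symmetric two-compartment kernel with the fiber orientation distribution

    S(b, b_delta, u) = S0 * int_{S^2} K(b, b_delta, n.u) P(n) dn,

with an intra-axonal stick (axial diffusivity D_i, zero perpendicular) of
signal fraction f_i and an extra-axonal zeppelin (De_par, De_perp) of
fraction 1 - f_i.  Two evaluation paths are provided:

* the *analytic* path applies the Funk-Hecke theorem: the convolution scales
  each SH degree l of the FOD by the Legendre projection r_l(a) of the
  Gaussian kernel factor (valid for b_delta >= 0 and De_par > De_perp);
* the *numeric* path evaluates the spherical integrals by product-grid
  quadrature and places no restriction on b_delta's sign.

Both paths are smooth in all kernel parameters and FOD coefficients; this
module also provides the exact parameter gradients used by the INR trainer
and the NLLS baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import AcquisitionProtocol
from .sh import (
    FODCoefficients,
    SphereDirections,
    legendre_projection_table,
    n_coeffs,
    real_sh_basis,
    sh_degrees,
    sphere_quadrature,
)

__all__ = [
    "KernelParams",
    "zeppelin_kernel",
    "sm_signal_analytic",
    "sm_signal_numeric",
    "effective_protocol",
    "effective_protocol_field",
    "AnalyticForward",
    "NumericForward",
    "KERNEL_BOUNDS",
]

# physiological parameter bounds: rows (lo, hi) for f_i, D_i, De_par, De_perp
# (diffusivities in um^2/ms); S0 is only bounded below by 0.
KERNEL_BOUNDS = np.array(
    [
        [0.0, 1.0],  # f_i
        [0.0, 4.0],  # D_i
        [0.0, 4.0],  # De_par
        [0.0, 1.5],  # De_perp
    ]
)


@dataclass
class KernelParams:
    """SM kernel parameters; each field may be scalar or a broadcastable array."""

    f_i: np.ndarray
    D_i: np.ndarray
    De_par: np.ndarray
    De_perp: np.ndarray
    S0: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.S0 is None:
            self.S0 = np.asarray(1.0)
        for name in ("f_i", "D_i", "De_par", "De_perp", "S0"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        checks = [
            ("f_i", self.f_i, 0.0, 1.0),
            ("D_i", self.D_i, 0.0, 4.0),
            ("De_par", self.De_par, 0.0, 4.0),
            ("De_perp", self.De_perp, 0.0, 1.5),
        ]
        for name, arr, lo, hi in checks:
            if np.any(arr < lo - 1e-12) or np.any(arr > hi + 1e-12):
                raise ValueError(f"{name} out of physiological bounds [{lo}, {hi}]")
        if np.any(self.S0 < 0):
            raise ValueError("S0 must be non-negative")


def zeppelin_kernel(b, b_delta, t, D_par, D_perp):
    """Axially symmetric tensor response for one measurement.

    ``t = n . u`` is the cosine between the fiber and encoding axes.  The
    exponent is
    ``(1/3) b b_delta (D_par - D_perp) - (1/3) b (D_par + 2 D_perp)
    - b b_delta t^2 (D_par - D_perp)``; at b = 0 the kernel is 1.
    """
    b = np.asarray(b, dtype=float)
    delta = np.asarray(D_par, dtype=float) - np.asarray(D_perp, dtype=float)
    expo = (
        b * b_delta * delta / 3.0
        - b * (np.asarray(D_par) + 2.0 * np.asarray(D_perp)) / 3.0
        - b * b_delta * np.asarray(t) ** 2 * delta
    )
    return np.exp(expo)


def _as_batch(x) -> np.ndarray:
    return np.atleast_1d(np.asarray(x, dtype=float))


class AnalyticForward:
    """Funk-Hecke evaluation of the SM signal for a fixed protocol.

    Precomputes the SH basis at the encoding directions and, when the
    protocol is shared across voxels, factorizes measurements into unique
    (b*b_delta, b) shells so the per-degree projections are evaluated once
    per shell instead of once per measurement.

    ``g = b * b_delta`` and ``beta = b`` may be 1-D (shared protocol, length
    M) or 2-D (per-voxel effective protocol, shape (V, M)); in the latter
    case ``u`` must be (V, M, 3).
    """

    def __init__(
        self,
        protocol_or_arrays,
        lmax: int,
        u: np.ndarray | None = None,
        Y: np.ndarray | None = None,
    ):
        if isinstance(protocol_or_arrays, AcquisitionProtocol):
            p = protocol_or_arrays
            b, b_delta, u = p.b, p.b_delta, p.u
        else:
            b, b_delta = protocol_or_arrays
            if u is None and Y is None:
                raise ValueError("u or Y required when passing raw arrays")
        self.lmax = int(lmax)
        self.n_coeffs = n_coeffs(self.lmax)
        self.ldeg_half = (sh_degrees(self.lmax) // 2).astype(int)
        b = np.asarray(b, dtype=float)
        b_delta = np.asarray(b_delta, dtype=float)
        self.g = b * b_delta
        self.beta = b
        self.per_voxel = b.ndim == 2
        if self.per_voxel:
            # (V, M, C) basis, computed here unless supplied precomputed
            if Y is not None:
                self.Y = np.asarray(Y, dtype=float)
            else:
                u = np.asarray(u, dtype=float)
                self.Y = real_sh_basis(self.lmax, u.reshape(-1, 3)).reshape(
                    u.shape[:2] + (self.n_coeffs,)
                )
            self._shell_of = None
        else:
            self.Y = (
                np.asarray(Y, dtype=float)
                if Y is not None
                else real_sh_basis(self.lmax, np.asarray(u, dtype=float))
            )
            pairs = np.stack([self.g, self.beta], axis=1)
            uniq, inv = np.unique(pairs, axis=0, return_inverse=True)
            self.g_s = uniq[:, 0]
            self.beta_s = uniq[:, 1]
            self._shell_of = inv

    # -- internals ---------------------------------------------------------

    def _compartments(self, D_i, De_par, De_perp, with_grads: bool):
        """Per-(voxel, shell-or-measurement, degree) compartment responses."""
        if self._shell_of is not None:
            g, beta = self.g_s, self.beta_s  # (S,)
        else:
            g, beta = self.g, self.beta  # (V, M)
        g = g[None] if g.ndim == 1 else g
        beta = beta[None] if beta.ndim == 1 else beta
        out = {}
        a_int = g * D_i[:, None]
        a_ext = g * (De_par - De_perp)[:, None]
        pref_int = np.exp((g - beta) * D_i[:, None] / 3.0)
        pref_ext = np.exp(
            (g * (De_par - De_perp)[:, None] - beta * (De_par + 2.0 * De_perp)[:, None])
            / 3.0
        )
        if with_grads:
            r_i, dr_i = legendre_projection_table(self.lmax, a_int, True)
            r_e, dr_e = legendre_projection_table(self.lmax, a_ext, True)
        else:
            r_i = legendre_projection_table(self.lmax, a_int)
            r_e = legendre_projection_table(self.lmax, a_ext)
            dr_i = dr_e = None
        out["R_int"] = pref_int[..., None] * r_i
        out["R_ext"] = pref_ext[..., None] * r_e
        if with_grads:
            gb = ((g - beta) / 3.0)[..., None]
            out["dR_int_dDi"] = pref_int[..., None] * (gb * r_i + g[..., None] * dr_i)
            out["dR_ext_dDepar"] = pref_ext[..., None] * (
                gb * r_e + g[..., None] * dr_e
            )
            out["dR_ext_dDeperp"] = pref_ext[..., None] * (
                ((-g - 2.0 * beta) / 3.0)[..., None] * r_e - g[..., None] * dr_e
            )
        return out

    def _gather(self, X: np.ndarray) -> np.ndarray:
        """(V, S, L) per-shell -> (V, M, C) per-measurement-per-coefficient."""
        if self._shell_of is not None:
            X = X[:, self._shell_of, :]  # (V, M, L)
        return X[..., self.ldeg_half]  # (V, M, C)

    def _contract(self, Xc: np.ndarray, p: np.ndarray) -> np.ndarray:
        """sum_c p[v,c] Y[(v),m,c] Xc[v,m,c] -> (V, M)."""
        if self.per_voxel:
            return np.einsum("vc,vmc,vmc->vm", p, self.Y, Xc, optimize=True)
        return np.einsum("vc,mc,vmc->vm", p, self.Y, Xc, optimize=True)

    # -- public ------------------------------------------------------------

    def signal(self, f_i, D_i, De_par, De_perp, S0, p) -> np.ndarray:
        """Predicted signals, shape (V, M)."""
        f_i, D_i = _as_batch(f_i), _as_batch(D_i)
        De_par, De_perp, S0 = _as_batch(De_par), _as_batch(De_perp), _as_batch(S0)
        p = np.atleast_2d(np.asarray(p, dtype=float))
        comp = self._compartments(D_i, De_par, De_perp, with_grads=False)
        K = (
            f_i[:, None, None] * comp["R_int"]
            + (1.0 - f_i)[:, None, None] * comp["R_ext"]
        )
        return S0[:, None] * self._contract(self._gather(K), p)

    def signal_and_gradients(self, f_i, D_i, De_par, De_perp, S0, p):
        """Signals plus exact partials w.r.t. every kernel parameter.

        Returns ``(S, grads)`` where ``grads`` holds (V, M) arrays for
        ``f_i, D_i, De_par, De_perp, S0`` and a cache for the FOD-coefficient
        gradient (see :meth:`p_gradient` / :meth:`vjp`).
        """
        f_i, D_i = _as_batch(f_i), _as_batch(D_i)
        De_par, De_perp, S0 = _as_batch(De_par), _as_batch(De_perp), _as_batch(S0)
        p = np.atleast_2d(np.asarray(p, dtype=float))
        comp = self._compartments(D_i, De_par, De_perp, with_grads=True)
        K = (
            f_i[:, None, None] * comp["R_int"]
            + (1.0 - f_i)[:, None, None] * comp["R_ext"]
        )
        Kc = self._gather(K)
        F = self._contract(Kc, p)
        S = S0[:, None] * F
        grads = {
            "S0": F,
            "f_i": S0[:, None]
            * self._contract(self._gather(comp["R_int"] - comp["R_ext"]), p),
            "D_i": S0[:, None]
            * f_i[:, None]
            * self._contract(self._gather(comp["dR_int_dDi"]), p),
            "De_par": S0[:, None]
            * (1.0 - f_i)[:, None]
            * self._contract(self._gather(comp["dR_ext_dDepar"]), p),
            "De_perp": S0[:, None]
            * (1.0 - f_i)[:, None]
            * self._contract(self._gather(comp["dR_ext_dDeperp"]), p),
            "_Kc": Kc,
            "_S0": S0,
        }
        return S, grads

    def p_jacobian(self, grads) -> np.ndarray:
        """dS/dp, shape (V, M, C) (used by the voxel-wise NLLS jacobian)."""
        Kc, S0 = grads["_Kc"], grads["_S0"]
        if self.per_voxel:
            return S0[:, None, None] * self.Y * Kc
        return S0[:, None, None] * self.Y[None] * Kc

    def vjp_p(self, G: np.ndarray, grads) -> np.ndarray:
        """Accumulate upstream dL/dS (V, M) into dL/dp (V, C)."""
        Kc, S0 = grads["_Kc"], grads["_S0"]
        W = G * S0[:, None]
        if self.per_voxel:
            return np.einsum("vm,vmc,vmc->vc", W, self.Y, Kc, optimize=True)
        return np.einsum("vm,mc,vmc->vc", W, self.Y, Kc, optimize=True)


def sm_signal_analytic(
    params: KernelParams, fod: FODCoefficients, protocol: AcquisitionProtocol
) -> np.ndarray:
    """SM signal via the Funk-Hecke analytic path.

    Valid only for ``b_delta >= 0`` and ``De_par > De_perp``; other inputs
    raise with a pointer to :func:`sm_signal_numeric`.  Returns shape
    ``batch + (N_m,)`` (a bare ``(N_m,)`` vector for scalar parameters).
    """
    if np.any(protocol.b_delta < 0):
        raise ValueError(
            "analytic path requires b_delta >= 0; use sm_signal_numeric"
        )
    if np.any(params.De_par <= params.De_perp):
        raise ValueError(
            "analytic path requires De_par > De_perp; use sm_signal_numeric"
        )
    batch_shape = np.broadcast_shapes(
        params.f_i.shape, params.D_i.shape, params.De_par.shape,
        params.De_perp.shape, params.S0.shape, fod.coeffs.shape[:-1],
    )
    fwd = AnalyticForward(protocol, fod.lmax)
    C = fod.coeffs.shape[-1]
    S = fwd.signal(
        np.broadcast_to(params.f_i, batch_shape).ravel(),
        np.broadcast_to(params.D_i, batch_shape).ravel(),
        np.broadcast_to(params.De_par, batch_shape).ravel(),
        np.broadcast_to(params.De_perp, batch_shape).ravel(),
        np.broadcast_to(params.S0, batch_shape).ravel(),
        np.broadcast_to(fod.coeffs, batch_shape + (C,)).reshape(-1, C),
    )
    return S.reshape(batch_shape + (protocol.n_measurements,)) if batch_shape else S[0]


class NumericForward:
    """Quadrature evaluation of the SM spherical integrals.

    Uses a product grid in (theta, phi) (Gauss-Legendre in cos(theta) x
    uniform phi, default 33 x 64 nodes, exact to rounding for band-limited
    FODs at lmax = 8).  Supports negative ``b_delta`` and arbitrary
    diffusivity ordering.
    """

    def __init__(
        self,
        protocol_or_arrays,
        lmax: int,
        u: np.ndarray | None = None,
        quadrature: SphereDirections | None = None,
        chunk: int = 8,
    ):
        if isinstance(protocol_or_arrays, AcquisitionProtocol):
            p = protocol_or_arrays
            b, b_delta, u = p.b, p.b_delta, p.u
        else:
            b, b_delta = protocol_or_arrays
        self.lmax = int(lmax)
        if quadrature is None:
            quadrature = sphere_quadrature()
        if quadrature.weights is None:
            raise ValueError("numeric path needs quadrature weights")
        min_nodes = 2 * (self.lmax + 1) ** 2
        if quadrature.n < min_nodes:
            raise ValueError(
                f"quadrature grid too coarse for lmax={self.lmax}: "
                f"{quadrature.n} < {min_nodes} nodes"
            )
        self.quad = quadrature
        self.Yq = real_sh_basis(self.lmax, quadrature)  # (Q, C)
        self.g = np.asarray(b, dtype=float) * np.asarray(b_delta, dtype=float)
        self.beta = np.asarray(b, dtype=float)
        self.per_voxel = self.beta.ndim == 2
        self.u = np.asarray(u, dtype=float)
        self.chunk = int(chunk)

    def _t2(self, m_slice) -> np.ndarray:
        """(n.u)^2 on the quadrature grid: ((V,)m, Q)."""
        if self.per_voxel:
            return np.einsum("vmi,qi->vmq", self.u[:, m_slice], self.quad.dirs) ** 2
        return (self.u[m_slice] @ self.quad.dirs.T) ** 2

    def signal(self, f_i, D_i, De_par, De_perp, S0, p, with_grads: bool = False):
        f_i, D_i = _as_batch(f_i), _as_batch(D_i)
        De_par, De_perp, S0 = _as_batch(De_par), _as_batch(De_perp), _as_batch(S0)
        p = np.atleast_2d(np.asarray(p, dtype=float))
        V = f_i.shape[0]
        M = self.beta.shape[-1]
        wP = self.quad.weights  # (Q,)
        amp = p @ self.Yq.T  # (V, Q) FOD amplitude on the grid
        delta_e = De_par - De_perp
        S = np.zeros((V, M))
        grads = {
            k: np.zeros((V, M))
            for k in ("f_i", "D_i", "De_par", "De_perp", "S0")
        }
        self._last_dSdp_chunks = [] if with_grads else None
        for m0 in range(0, M, self.chunk):
            sl = slice(m0, min(m0 + self.chunk, M))
            t2 = self._t2(sl)  # (m, Q) shared or (V, m, Q) per-voxel
            g = self.g[..., sl]
            beta = self.beta[..., sl]
            if self.per_voxel:
                gt2 = g[..., None] * t2  # (V, m, Q)
            else:
                gt2 = (g[:, None] * t2)[None]  # (1, m, Q)
            # intra: exp(-g D t^2) with prefactor exp((g - beta) D / 3)
            E_i = np.exp(-D_i[:, None, None] * gt2)
            E_e = np.exp(-delta_e[:, None, None] * gt2)
            I_i = np.einsum("vmq,q,vq->vm", E_i, wP, amp, optimize=True)
            I_e = np.einsum("vmq,q,vq->vm", E_e, wP, amp, optimize=True)
            c_i = np.exp((g - beta) * D_i[:, None] / 3.0)
            c_e = np.exp(
                (g * delta_e[:, None] - beta * (De_par + 2 * De_perp)[:, None]) / 3.0
            )
            S[:, sl] = S0[:, None] * (
                f_i[:, None] * c_i * I_i + (1 - f_i)[:, None] * c_e * I_e
            )
            if with_grads:
                t2b = t2[None] if not self.per_voxel else t2
                dI_i = -np.einsum(
                    "vmq,q,vq->vm",
                    E_i * t2b, wP, amp, optimize=True,
                )
                dI_e = -np.einsum(
                    "vmq,q,vq->vm", E_e * t2b, wP, amp, optimize=True
                )
                grads["S0"][:, sl] = (
                    f_i[:, None] * c_i * I_i + (1 - f_i)[:, None] * c_e * I_e
                )
                grads["f_i"][:, sl] = S0[:, None] * (c_i * I_i - c_e * I_e)
                grads["D_i"][:, sl] = (
                    S0[:, None]
                    * f_i[:, None]
                    * c_i
                    * ((g - beta) / 3.0 * I_i + g * dI_i)
                )
                grads["De_par"][:, sl] = (
                    S0[:, None]
                    * (1 - f_i)[:, None]
                    * c_e
                    * ((g - beta) / 3.0 * I_e + g * dI_e)
                )
                grads["De_perp"][:, sl] = (
                    S0[:, None]
                    * (1 - f_i)[:, None]
                    * c_e
                    * ((-g - 2 * beta) / 3.0 * I_e - g * dI_e)
                )
                # dS/damp contribution folded into dS/dp via the basis
                W_i = f_i[:, None] * c_i * S0[:, None]
                W_e = (1 - f_i)[:, None] * c_e * S0[:, None]
                dSdp = np.einsum(
                    "vm,vmq,q,qc->vmc", W_i, E_i, wP, self.Yq, optimize=True
                ) + np.einsum(
                    "vm,vmq,q,qc->vmc", W_e, E_e, wP, self.Yq, optimize=True
                )
                self._last_dSdp_chunks.append((sl, dSdp))
        if with_grads:
            return S, grads
        return S

    def vjp_p(self, G: np.ndarray) -> np.ndarray:
        """dL/dp from upstream dL/dS, using the chunks cached by signal()."""
        if self._last_dSdp_chunks is None:
            raise RuntimeError("call signal(..., with_grads=True) first")
        out = None
        for sl, dSdp in self._last_dSdp_chunks:
            c = np.einsum("vm,vmc->vc", G[:, sl], dSdp, optimize=True)
            out = c if out is None else out + c
        return out

    def p_jacobian(self) -> np.ndarray:
        """dS/dp, (V, M, C), assembled from the cached chunks."""
        if self._last_dSdp_chunks is None:
            raise RuntimeError("call signal(..., with_grads=True) first")
        V = self._last_dSdp_chunks[0][1].shape[0]
        M = self.beta.shape[-1]
        C = self.Yq.shape[1]
        J = np.zeros((V, M, C))
        for sl, dSdp in self._last_dSdp_chunks:
            J[:, sl, :] = dSdp
        return J


def sm_signal_numeric(
    params: KernelParams,
    fod: FODCoefficients,
    protocol: AcquisitionProtocol,
    quadrature: SphereDirections | None = None,
) -> np.ndarray:
    """SM signal via spherical quadrature (no restriction on b_delta's sign)."""
    batch_shape = np.broadcast_shapes(
        params.f_i.shape, params.D_i.shape, params.De_par.shape,
        params.De_perp.shape, params.S0.shape, fod.coeffs.shape[:-1],
    )
    fwd = NumericForward(protocol, fod.lmax, quadrature=quadrature)
    C = fod.coeffs.shape[-1]
    S = fwd.signal(
        np.broadcast_to(params.f_i, batch_shape).ravel(),
        np.broadcast_to(params.D_i, batch_shape).ravel(),
        np.broadcast_to(params.De_par, batch_shape).ravel(),
        np.broadcast_to(params.De_perp, batch_shape).ravel(),
        np.broadcast_to(params.S0, batch_shape).ravel(),
        np.broadcast_to(fod.coeffs, batch_shape + (C,)).reshape(-1, C),
    )
    return S.reshape(batch_shape + (protocol.n_measurements,)) if batch_shape else S[0]


# --- gradient non-uniformity -----------------------------------------------


def _nominal_btensor(b: np.ndarray, b_delta: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Axially symmetric B-tensor with trace b: (b/3) [(1-bD) I + 3 bD u u^T]."""
    eye = np.eye(3)
    uuT = u[..., :, None] * u[..., None, :]
    return (b[..., None, None] / 3.0) * (
        (1.0 - b_delta)[..., None, None] * eye + 3.0 * b_delta[..., None, None] * uuT
    )


def _effective_arrays(b, b_delta, u, L):
    """Vectorized effective (b, b_delta, u) under B_eff = L B L^T.

    ``L`` has shape (..., 3, 3) broadcasting against the measurement axis of
    b/b_delta/u.  The closest axially symmetric description is returned: the
    symmetry axis is the eigenvalue most distinct from the mean of the other
    two, and b_delta_eff = (lam_axis - mean(others)) / b_eff.
    """
    B = _nominal_btensor(b, b_delta, u)  # (M, 3, 3)
    Beff = np.einsum("...ij,mjk,...lk->...mil", L, B, L, optimize=True)
    b_eff = np.trace(Beff, axis1=-2, axis2=-1)
    dw = b > 0
    if np.any(b_eff[..., dw] <= 0):
        raise ValueError("degenerate gradient tensor: effective b <= 0")
    w, v = np.linalg.eigh(Beff)  # ascending eigenvalues, (..., M, 3), (..., M, 3, 3)
    # distinctness of each eigenvalue from the mean of the other two
    d = 1.5 * w - 0.5 * b_eff[..., None]
    sel = np.argmax(np.abs(d), axis=-1)
    d_sel = np.take_along_axis(d, sel[..., None], axis=-1)[..., 0]
    u_eff = np.take_along_axis(v, sel[..., None, None], axis=-1)[..., 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        bd_eff = np.where(b_eff > 0, d_sel / np.where(b_eff > 0, b_eff, 1.0), 0.0)
    # fix eigenvector sign: first component of largest magnitude non-negative
    lead = np.argmax(np.abs(u_eff), axis=-1)
    signs = np.sign(np.take_along_axis(u_eff, lead[..., None], axis=-1)[..., 0])
    signs = np.where(signs == 0, 1.0, signs)
    u_eff = u_eff * signs[..., None]
    # isotropic effective tensors have no preferred axis: keep the nominal u
    iso = np.abs(bd_eff) < 1e-10
    u_eff = np.where(iso[..., None], np.broadcast_to(u, u_eff.shape), u_eff)
    # b = 0 rows carry no encoding: keep nominal values
    b_eff = np.where(dw, b_eff, b)
    bd_eff = np.where(dw, bd_eff, b_delta)
    u_eff = np.where(dw[..., None], u_eff, u)
    return b_eff, bd_eff, u_eff


def effective_protocol(
    protocol: AcquisitionProtocol, L: np.ndarray
) -> AcquisitionProtocol:
    """Effective acquisition protocol at a voxel with coil tensor ``L``.

    Builds the nominal axially symmetric B-tensor for every measurement,
    transforms it as ``B_eff = L B L^T``, and re-expresses the result in the
    closest axially symmetric parameterization (b from the trace, u from the
    symmetry-axis eigenvector, b_delta from the eigenvalue anisotropy).
    """
    L = np.asarray(L, dtype=float)
    if L.shape != (3, 3) or not np.all(np.isfinite(L)):
        raise ValueError("L must be a finite 3x3 matrix")
    b_eff, bd_eff, u_eff = _effective_arrays(
        protocol.b, protocol.b_delta, protocol.u, L
    )
    return AcquisitionProtocol(
        b=b_eff, b_delta=np.clip(bd_eff, -0.5, 1.0), u=u_eff,
        b0_replaced=protocol.b0_replaced,
    )


def effective_protocol_field(protocol: AcquisitionProtocol, L_field: np.ndarray):
    """Per-voxel effective (b, b_delta, u) arrays for a stack of coil tensors.

    ``L_field`` is (V, 3, 3); returns arrays of shape (V, M), (V, M), (V, M, 3).
    """
    L_field = np.asarray(L_field, dtype=float)
    b_eff, bd_eff, u_eff = _effective_arrays(
        protocol.b, protocol.b_delta, protocol.u, L_field
    )
    return b_eff, np.clip(bd_eff, -0.5, 1.0), u_eff
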