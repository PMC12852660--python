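"""Real spherical harmonics, Legendre projections and spherical point sets.

This module is the numeric substrate shared by the forward signal model, the
FOD non-negativity constraint and the phantom generator.  Conventions:

* Only even degrees ``l`` are used (fiber orientation distributions are
  antipodally symmetric).
* The real, orthonormal basis follows the Descoteaux-style convention:
  ``m < 0`` maps to ``sqrt(2) * Im(Y_l^{|m|})``, ``m = 0`` to ``Y_l^0`` and
  ``m > 0`` to ``sqrt(2) * Re(Y_l^m)``.  Coefficients are ordered
  lexicographically in ``(l, m)`` with ``m`` running from ``-l`` to ``l``.
* ``legendre_projection`` computes the Funk-Hecke factor
  ``r_l(a) = 2*pi * int_{-1}^{1} P_l(t) * exp(-a t^2) dt``
  by a fixed 64-node Gauss-Legendre rule, which is smooth and differentiable
  in ``a`` and accurate to ~1e-12 over the physiological range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import eval_legendre, sph_harm_y

__all__ = [
    "FODCoefficients",
    "SphereDirections",
    "n_coeffs",
    "sh_degrees",
    "sh_index_list",
    "real_sh_basis",
    "fod_amplitude",
    "legendre_projection",
    "legendre_projection_table",
    "p2_invariant",
    "hemisphere_directions",
    "sphere_quadrature",
]

_N_GL = 64
# Gauss-Legendre nodes/weights mapped to [0, 1]; the integrand is even in t so
# the projection integral over [-1, 1] is twice the one over [0, 1].
_gl_x, _gl_w = np.polynomial.legendre.leggauss(_N_GL)
GL_NODES = 0.5 * (_gl_x + 1.0)
GL_WEIGHTS = 0.5 * _gl_w
GL_NODES_SQ = GL_NODES**2


def n_coeffs(lmax: int) -> int:
    """Number of even-degree real SH coefficients up to ``lmax``."""
    if lmax < 0 or lmax % 2 != 0:
        raise ValueError(f"lmax must be a non-negative even integer, got {lmax}")
    return (lmax + 1) * (lmax + 2) // 2


def sh_degrees(lmax: int) -> np.ndarray:
    """Degree ``l`` of each coefficient in the canonical ordering."""
    return np.concatenate([np.full(2 * l + 1, l) for l in range(0, lmax + 1, 2)])


def sh_index_list(lmax: int) -> list[tuple[int, int]]:
    """Canonical ``(l, m)`` ordering: l ascending (even), m from -l to l."""
    return [(l, m) for l in range(0, lmax + 1, 2) for m in range(-l, l + 1)]


@dataclass
class SphereDirections:
    """A set of unit vectors on S^2, optionally with quadrature weights."""

    dirs: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dirs = np.atleast_2d(np.asarray(self.dirs, dtype=float))
        if self.dirs.ndim != 2 or self.dirs.shape[1] != 3 or self.dirs.shape[0] == 0:
            raise ValueError("dirs must be a non-empty (n, 3) array")
        norms = np.linalg.norm(self.dirs, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("directions must be unit norm (tol 1e-9)")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (self.dirs.shape[0],):
                raise ValueError("weights must match the number of directions")
            if np.any(self.weights <= 0):
                raise ValueError("quadrature weights must be positive")

    @property
    def n(self) -> int:
        return self.dirs.shape[0]


@dataclass
class FODCoefficients:
    """Real even-order SH coefficients of a fiber orientation distribution.

    ``coeffs`` may carry leading batch axes; the last axis indexes the
    ``(l, m)`` pairs in canonical order.
    """

    lmax: int
    coeffs: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.lmax not in (0, 2, 4, 6, 8):
            raise ValueError(f"lmax must be an even integer in 0..8, got {self.lmax}")
        if self.coeffs is None:
            self.coeffs = np.zeros(n_coeffs(self.lmax))
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape[-1] != n_coeffs(self.lmax):
            raise ValueError(
                f"expected {n_coeffs(self.lmax)} coefficients for lmax={self.lmax}, "
                f"got {self.coeffs.shape[-1]}"
            )
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("FOD coefficients must be finite")

    @classmethod
    def isotropic(cls, lmax: int) -> "FODCoefficients":
        """Unit-integral isotropic FOD: p00 = 1/sqrt(4 pi), rest zero."""
        c = np.zeros(n_coeffs(lmax))
        c[0] = 1.0 / np.sqrt(4.0 * np.pi)
        return cls(lmax=lmax, coeffs=c)


def _dirs_array(directions: SphereDirections | np.ndarray) -> np.ndarray:
    if isinstance(directions, SphereDirections):
        return directions.dirs
    return np.atleast_2d(np.asarray(directions, dtype=float))


def real_sh_basis(lmax: int, directions: SphereDirections | np.ndarray) -> np.ndarray:
    """Evaluate the real even-order SH basis at unit directions.

    Returns an ``(n_dirs, n_coeffs)`` matrix ``B`` with
    ``B[j, c] = Y_{l_c}^{m_c}(n_j)``.  The basis is orthonormal:
    ``B.T @ diag(w) @ B = I`` for a dense quadrature grid with weights ``w``.
    """
    if lmax % 2 != 0:
        raise ValueError("lmax must be even")
    dirs = _dirs_array(directions)
    if dirs.shape[0] == 0:
        raise ValueError("empty direction set")
    x, y, z = dirs[:, 0], dirs[:, 1], dirs[:, 2]
    theta = np.arccos(np.clip(z, -1.0, 1.0))
    phi = np.arctan2(y, x)
    cols = []
    for l in range(0, lmax + 1, 2):
        # complex Y_l^m for m = 0..l in one call each
        ylm = {m: sph_harm_y(l, m, theta, phi) for m in range(0, l + 1)}
        for m in range(-l, l + 1):
            if m < 0:
                cols.append(np.sqrt(2.0) * ylm[-m].imag)
            elif m == 0:
                cols.append(ylm[0].real)
            else:
                cols.append(np.sqrt(2.0) * ylm[m].real)
    return np.stack(cols, axis=1)


def fod_amplitude(
    coeffs: FODCoefficients, directions: SphereDirections | np.ndarray
) -> np.ndarray:
    """FOD amplitude ``sum_lm p_l^m Y_l^m(n)`` at each direction.

    Linear in the coefficients; supports batched coefficient arrays with the
    batch axes leading, returning ``(..., n_dirs)``.
    """
    basis = real_sh_basis(coeffs.lmax, directions)
    return coeffs.coeffs @ basis.T


def legendre_projection_table(
    lmax: int, a: np.ndarray, with_derivative: bool = False
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Funk-Hecke factors ``r_l(a)`` for all even ``l <= lmax`` at once.

    ``a`` may have any shape; the result has shape ``a.shape + (lmax//2 + 1,)``
    with the last axis running over ``l = 0, 2, ..., lmax``.  When
    ``with_derivative`` is true, ``dr_l/da`` is returned as well (same shape),
    computed with the identical quadrature rule so that gradients are exact
    for the implemented forward model.
    """
    a = np.asarray(a, dtype=float)
    ls = np.arange(0, lmax + 1, 2)
    # P_l(t_k) for each even degree at the fixed nodes: (n_l, 64)
    pl = eval_legendre(ls[:, None], GL_NODES[None, :])
    expo = np.exp(-a[..., None] * GL_NODES_SQ)  # (..., 64)
    r = 4.0 * np.pi * np.einsum("...k,lk,k->...l", expo, pl, GL_WEIGHTS)
    if not with_derivative:
        return r
    dr = -4.0 * np.pi * np.einsum(
        "...k,lk,k->...l", expo * GL_NODES_SQ, pl, GL_WEIGHTS
    )
    return r, dr


def legendre_projection(l: int, a: float | np.ndarray) -> float | np.ndarray:
    """``r_l(a) = 2*pi * int_{-1}^{1} P_l(t) exp(-a t^2) dt`` for even ``l``.

    This is the analytic path's per-degree kernel factor; it requires
    ``a >= 0`` (the domain on which the convolution theorem is applied with a
    decaying Gaussian kernel).  For negative ``a`` use the numeric-integration
    signal path (``sm_signal_numeric``), which places no sign restriction.
    """
    if l % 2 != 0:
        raise ValueError("l must be even")
    a_arr = np.asarray(a, dtype=float)
    if np.any(a_arr < 0):
        raise ValueError(
            "legendre_projection requires a >= 0 on the analytic path; "
            "use the numeric integration path for negative B-tensor shapes"
        )
    r = legendre_projection_table(l, a_arr)[..., l // 2]
    return float(r) if np.isscalar(a) or a_arr.ndim == 0 else r


def p2_invariant(coeffs: FODCoefficients) -> float | np.ndarray:
    """Degree-2 rotational invariant ``p2 = sqrt(4 pi / 5) * ||p_{2m}||``.

    A scalar measure of FOD anisotropy that does not depend on the FOD's
    orientation (the degree-2 subspace transforms unitarily under rotation).
    """
    if coeffs.lmax < 2:
        raise ValueError("p2 requires lmax >= 2")
    p2m = coeffs.coeffs[..., 1:6]
    out = np.sqrt(4.0 * np.pi / 5.0) * np.sqrt(np.sum(p2m**2, axis=-1))
    return float(out) if out.ndim == 0 else out


def hemisphere_directions(n: int, seed: int = 0, n_iter: int = 1000) -> SphereDirections:
    """Well-separated directions by electrostatic repulsion with antipodal charges.

    Starts from seeded random points on the upper hemisphere and runs
    projected gradient descent on the Coulomb energy
    ``sum_{i<j} 1/|x_i - x_j| + 1/|x_i + x_j|`` (each point interacts with the
    others and their antipodes, the appropriate criterion for diffusion
    gradient schemes where ``u`` and ``-u`` are equivalent).  Deterministic
    for a fixed seed.
    """
    if n < 1:
        raise ValueError("need at least one direction")
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n, 3))
    v[:, 2] = np.abs(v[:, 2]) + 1e-3
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    if n == 1:
        return SphereDirections(dirs=v)

    step = 0.05
    eye = np.eye(n, dtype=bool)
    for it in range(n_iter):
        diff = v[:, None, :] - v[None, :, :]      # x_i - x_j
        dsum = v[:, None, :] + v[None, :, :]      # x_i + x_j (antipodal charge)
        r1 = np.linalg.norm(diff, axis=-1)
        r2 = np.linalg.norm(dsum, axis=-1)
        np.fill_diagonal(r1, np.inf)
        np.fill_diagonal(r2, np.inf)
        # force = -grad energy; 1/r potential gives r_hat / r^2
        f = (diff / r1[..., None] ** 3).sum(axis=1) + (
            dsum / r2[..., None] ** 3
        ).sum(axis=1)
        # tangential component only, normalized per point for stable steps
        f -= (f * v).sum(axis=1, keepdims=True) * v
        fn = np.linalg.norm(f, axis=1, keepdims=True)
        fn[fn == 0] = 1.0
        v = v + step * (1.0 - it / n_iter) * f / fn
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        _ = eye
    return SphereDirections(dirs=v)


def sphere_quadrature(n_theta: int = 33, n_phi: int = 64) -> SphereDirections:
    """Product quadrature grid on S^2, exact for band-limited integrands.

    Gauss-Legendre nodes in ``t = cos(theta)`` combined with a uniform
    (periodic trapezoid) rule in ``phi``: exact for spherical polynomials up
    to degree ``min(2 n_theta - 1, n_phi - 1)`` and spectrally convergent
    for smooth kernels, so the default 33 x 64 grid resolves lmax = 8
    integrands to rounding.  Total weight is exactly 4*pi.
    """
    if n_theta < 4 or n_phi < 4:
        raise ValueError("n_theta and n_phi must be >= 4")
    t, w_t = np.polynomial.legendre.leggauss(n_theta)
    phi = 2.0 * np.pi * np.arange(n_phi) / n_phi
    st = np.sqrt(np.clip(1.0 - t**2, 0.0, None))
    tt_s, pp = np.meshgrid(st, phi, indexing="ij")
    tt_c = np.meshgrid(t, phi, indexing="ij")[0]
    dirs = np.stack(
        [tt_s * np.cos(pp), tt_s * np.sin(pp), tt_c], axis=-1
    ).reshape(-1, 3)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    w = (w_t[:, None] * np.full(n_phi, 2.0 * np.pi / n_phi)[None, :]).reshape(-1)
    return SphereDirections(dirs=dirs, weights=w)
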