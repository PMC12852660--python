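"""Synthetic phantoms: smooth SM parameter fields, Watson-mixture FODs,
the optimized multi-shell B-tensor protocol, and Gaussian/Rician noise.

The generator emulates the statistical structure of simulation studies in
this domain: spatially smooth kernel-parameter maps inside physiological
bounds, antipodally symmetric FOD fields with smoothly varying orientations,
and noise whose standard deviation is set per voxel by the mean b = 0 signal
and a target SNR.  Everything is deterministic given a seed and requires no
external data.

Two field modes are available:

* ``smooth_noise`` (default): Gaussian-smoothed white noise affinely mapped
  into parameter sub-ranges — cheap and statistically rich;
* ``harmonic``: band-limited random trigonometric fields, which are exactly
  evaluable at *any* continuous coordinate (``Phantom.kernel_truth_at``),
  the property needed to score continuous upsampling off the voxel grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import eval_legendre

from .forward import AnalyticForward, KernelParams
from .io import AcquisitionProtocol, VolumeGrid
from .sh import (
    FODCoefficients,
    hemisphere_directions,
    legendre_projection_table,
    n_coeffs,
    real_sh_basis,
    sh_degrees,
)

__all__ = [
    "NoiseSpec",
    "Phantom",
    "optimized_protocol",
    "generate_phantom",
    "simulate_signals",
    "add_noise",
]

# the published optimized multi-shell B-tensor protocol:
# shell b-values in s/mm^2, direction counts, B-tensor shapes
PROTOCOL_SHELLS_B = (0, 1000, 2000, 8000, 5000, 2000)
PROTOCOL_SHELLS_NDIR = (4, 20, 40, 40, 35, 15)
PROTOCOL_SHELLS_BDELTA = (1.0, 1.0, 1.0, 1.0, 0.8, 0.0)


@dataclass
class NoiseSpec:
    """Noise model: kind in {none, gaussian, rician}, SNR on the b=0 signal."""

    kind: str = "gaussian"
    snr: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "gaussian", "rician"):
            raise ValueError("kind must be 'none', 'gaussian' or 'rician'")
        if not self.snr > 0:
            raise ValueError("snr must be positive")


@dataclass
class Phantom:
    """Gridded ground truth: kernel fields, FOD field, mask and geometry."""

    grid: VolumeGrid
    kernel: KernelParams  # fields of shape grid.shape
    fod: FODCoefficients  # coeffs of shape grid.shape + (C,)
    mask: np.ndarray
    meta: dict = field(default_factory=dict)
    _truth_fns: dict = field(default_factory=dict, repr=False)

    @property
    def lmax(self) -> int:
        return self.fod.lmax

    def kernel_truth_at(self, coords_vox: np.ndarray) -> dict[str, np.ndarray]:
        """Evaluate the kernel parameter fields at continuous voxel coordinates.

        Only available in ``harmonic`` field mode, where the fields are
        closed-form functions of position.
        """
        if not self._truth_fns:
            raise ValueError(
                "continuous ground truth requires field_mode='harmonic'"
            )
        coords = np.asarray(coords_vox, dtype=float)
        return {k: fn(coords) for k, fn in self._truth_fns.items()}


def optimized_protocol(seed: int = 0) -> AcquisitionProtocol:
    """The published optimized acquisition protocol (154 measurements).

    Shells: b = [0, 1000, 2000, 8000, 5000, 2000] s/mm^2 with
    [4, 20, 40, 40, 35, 15] directions and B-tensor shapes
    [1, 1, 1, 1, 0.8, 0].  Directions per shell are generated by
    electrostatic repulsion on the hemisphere, after which every second
    direction is flipped to cover the full sphere.
    """
    b_list, bd_list, u_list, rep_list = [], [], [], []
    for i, (b_si, n_dir, bd) in enumerate(
        zip(PROTOCOL_SHELLS_B, PROTOCOL_SHELLS_NDIR, PROTOCOL_SHELLS_BDELTA)
    ):
        if b_si == 0:
            dirs = np.tile([1.0, 0.0, 0.0], (n_dir, 1))
            rep = np.ones(n_dir, dtype=bool)
        else:
            dirs = hemisphere_directions(n_dir, seed=seed * 101 + i).dirs.copy()
            dirs[1::2] *= -1.0  # flip half to the lower hemisphere
            rep = np.zeros(n_dir, dtype=bool)
        b_list.append(np.full(n_dir, b_si / 1000.0))
        bd_list.append(np.full(n_dir, bd))
        u_list.append(dirs)
        rep_list.append(rep)
    return AcquisitionProtocol(
        b=np.concatenate(b_list),
        b_delta=np.concatenate(bd_list),
        u=np.concatenate(u_list),
        b0_replaced=np.concatenate(rep_list),
    )


# --- smooth random fields --------------------------------------------------


def _smooth_field(rng, shape, smooth_vox: float) -> np.ndarray:
    """Gaussian-smoothed white noise, globally rescaled to [0, 1]."""
    f = gaussian_filter(rng.standard_normal(shape), smooth_vox, mode="nearest")
    lo, hi = f.min(), f.max()
    return (f - lo) / max(hi - lo, 1e-12)


class _HarmonicField:
    """Band-limited random field u(x) in [0, 1], closed-form at any coordinate."""

    def __init__(self, rng, shape, n_modes: int = 4, max_cycles: float = 1.25):
        self.shape = np.asarray(shape, dtype=float)
        self.freq = rng.uniform(-max_cycles, max_cycles, size=(n_modes, 3))
        self.phase = rng.uniform(0.0, 2.0 * np.pi, size=n_modes)
        self.amp = rng.uniform(0.5, 1.0, size=n_modes)

    def __call__(self, coords_vox: np.ndarray) -> np.ndarray:
        x = np.asarray(coords_vox, dtype=float) / self.shape
        arg = 2.0 * np.pi * (x @ self.freq.T) + self.phase
        s = (np.cos(arg) * self.amp).sum(axis=-1)
        return 0.5 + s / (2.0 * np.sum(self.amp))


def _affine_map(u, lo, hi):
    return lo + (hi - lo) * u


# --- Watson-mixture FODs ---------------------------------------------------


def _watson_degree_ratios(lmax: int, kappa: np.ndarray) -> np.ndarray:
    """Per-degree SH ratios c_l / c_0 of a Watson density exp(kappa (n.mu)^2).

    By the convolution theorem an axially symmetric density has coefficients
    c_l * Y_l^m(mu); normalizing the spherical integral to one divides by
    c_0.  Computed by the same Gauss-Legendre rule as the kernel projections
    (negative 'a' is fine for the quadrature).
    """
    c = legendre_projection_table(lmax, -np.asarray(kappa, dtype=float))
    return c / c[..., :1]


def _nonneg_shrink(ratios: np.ndarray, lmax: int, n_t: int = 4097) -> np.ndarray:
    """Shrink l >= 2 degree ratios so the truncated profile is non-negative.

    The truncated axially symmetric amplitude is
    ``A(t) = sum_l (c_l/c_0) (2l+1)/(4 pi) P_l(t)``; SH truncation can ring
    below zero near the equator.  The minimal uniform shrink of the l >= 2
    terms that restores ``min_t A(t) >= 0`` is applied per voxel, keeping
    the unit integral (the l = 0 term) intact.
    """
    ls = np.arange(0, lmax + 1, 2)
    t = np.linspace(-1.0, 1.0, n_t)
    P = eval_legendre(ls[:, None], t[None, :])  # (L, T)
    w = (2 * ls + 1) / (4.0 * np.pi)
    prof = np.einsum("...l,l,lt->...t", ratios, w, P)
    aniso = prof - ratios[..., :1] * w[0]  # subtract isotropic part (= 1/(4pi))
    iso = ratios[..., 0] * w[0]
    m = (iso[..., None] + aniso).min(axis=-1)
    neg = m < 0
    s = np.ones_like(m)
    if np.any(neg):
        # keep a small positive floor (1e-3 of the isotropic level) so that
        # the continuous minimum between profile nodes cannot dip below zero
        worst = (aniso.min(axis=-1))[neg]
        s[neg] = (1.0 - 1e-3) * iso[neg] / (-worst)
    out = ratios.copy()
    out[..., 1:] *= s[..., None]
    return out


def _watson_coeffs(mu: np.ndarray, ratios: np.ndarray, lmax: int) -> np.ndarray:
    """Unit-integral SH coefficients of a (shrunk) Watson density around mu."""
    C = n_coeffs(lmax)
    Y_mu = real_sh_basis(lmax, mu.reshape(-1, 3)).reshape(mu.shape[:-1] + (C,))
    ldeg_half = (sh_degrees(lmax) // 2).astype(int)
    full = ratios[..., ldeg_half] * Y_mu  # c_l/c_0 * Y_lm(mu)
    # normalize so the spherical integral is 1: p00 = 1/sqrt(4 pi)
    return full / (full[..., :1] * np.sqrt(4.0 * np.pi))


def _orientation_field(u1: np.ndarray, u2: np.ndarray) -> np.ndarray:
    """Smoothly varying unit vectors from two scalar fields (angles)."""
    theta = _affine_map(u1, 0.25 * np.pi, 0.75 * np.pi)
    phi = _affine_map(u2, 0.0, np.pi)
    return np.stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)],
        axis=-1,
    )


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of unit vectors v about unit axes by a fixed angle."""
    c, s = np.cos(angle), np.sin(angle)
    cross = np.cross(axis, v)
    dot = np.sum(axis * v, axis=-1, keepdims=True)
    return v * c + cross * s + axis * dot * (1.0 - c)


def generate_phantom(
    shape,
    lmax: int = 2,
    seed: int = 0,
    smoothness_vox: float = 3.0,
    fiber_config: str = "single",
    field_mode: str = "smooth_noise",
    kappa: float = 9.0,
    crossing_angle_deg: float = 60.0,
    s0: float = 1.0,
    mask_type: str = "ellipsoid",
    detail_cycles: float | None = None,
) -> Phantom:
    """Generate a spatially smooth ground-truth phantom.

    Kernel fields are mapped into conservative physiological sub-ranges
    (f_i in [0.3, 0.8], D_i in [1.5, 3.0], De_par in [1.0, 2.5],
    De_perp = De_par * r with smooth r in [0.2, 0.6], which guarantees
    De_par > De_perp everywhere).  FODs are unit-integral mixtures of one or
    two Watson densities with smoothly varying orientations; fiber_config is
    'single', 'crossing' (two populations at ``crossing_angle_deg``) or
    'fanning' (orientation dispersion, i.e. kappa, varies across space).
    """
    shape = tuple(int(s) for s in shape)
    if min(shape) < 4:
        raise ValueError("phantom shape must be at least 4 voxels per axis")
    if lmax not in (2, 4, 6, 8):
        raise ValueError(f"lmax must be one of 2, 4, 6, 8, got {lmax}")
    if fiber_config not in ("single", "crossing", "fanning"):
        raise ValueError(f"unknown fiber_config '{fiber_config}'")
    if field_mode not in ("smooth_noise", "harmonic"):
        raise ValueError(f"unknown field_mode '{field_mode}'")
    rng = np.random.default_rng(seed)

    # harmonic-field bandwidth: default features span ~2 correlation lengths
    # of the smooth-noise mode (wavelength 2 * smoothness in voxels)
    if detail_cycles is None:
        detail_cycles = max(min(shape) / (2.0 * smoothness_vox), 1.0)

    truth_fns: dict = {}
    if field_mode == "smooth_noise":
        fields = [_smooth_field(rng, shape, smoothness_vox) for _ in range(6)]
    else:
        hf = [_HarmonicField(rng, shape, max_cycles=detail_cycles)
              for _ in range(6)]
        coords = np.stack(
            np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1
        ).astype(float)
        fields = [f(coords) for f in hf]
        ranges = {
            "f_i": (0.3, 0.8), "D_i": (1.5, 3.0), "De_par": (1.0, 2.5),
        }
        truth_fns = {
            name: (lambda c, f=hf[i], lo=lo, hi=hi: _affine_map(f(c), lo, hi))
            for i, (name, (lo, hi)) in enumerate(ranges.items())
        }
        truth_fns["De_perp"] = lambda c, f2=hf[2], f3=hf[3]: _affine_map(
            f2(c), 1.0, 2.5
        ) * _affine_map(f3(c), 0.2, 0.6)

    f_i = _affine_map(fields[0], 0.3, 0.8)
    D_i = _affine_map(fields[1], 1.5, 3.0)
    De_par = _affine_map(fields[2], 1.0, 2.5)
    r = _affine_map(fields[3], 0.2, 0.6)
    De_perp = De_par * r

    mu = _orientation_field(fields[4], fields[5])

    if fiber_config == "fanning":
        kap = _affine_map(fields[0], 4.0, 3.0 * kappa)
    else:
        kap = np.full(shape, float(kappa))
    ratios = _nonneg_shrink(_watson_degree_ratios(lmax, kap), lmax)

    if fiber_config == "crossing":
        # rotate mu about a smoothly varying perpendicular axis
        helper = np.stack(
            [np.cos(fields[1] * np.pi), np.sin(fields[1] * np.pi),
             np.zeros(shape)], axis=-1,
        )
        axis = np.cross(mu, helper)
        axis /= np.maximum(np.linalg.norm(axis, axis=-1, keepdims=True), 1e-12)
        ang = np.deg2rad(crossing_angle_deg)
        mu2 = _rotate_about(mu, axis, ang)
        coeffs = 0.5 * (
            _watson_coeffs(mu, ratios, lmax) + _watson_coeffs(mu2, ratios, lmax)
        )
    else:
        coeffs = _watson_coeffs(mu, ratios, lmax)

    if mask_type == "ellipsoid":
        idx = np.stack(
            np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1
        ).astype(float)
        c = (np.asarray(shape, dtype=float) - 1.0) / 2.0
        rad = np.maximum(np.asarray(shape, dtype=float) / 2.0, 1.0)
        mask = (((idx - c) / rad) ** 2).sum(axis=-1) <= 1.0
    elif mask_type == "full":
        mask = np.ones(shape, dtype=bool)
    else:
        raise ValueError(f"unknown mask_type '{mask_type}'")

    S0 = np.where(mask, float(s0), 0.0)
    kernel = KernelParams(f_i=f_i, D_i=D_i, De_par=De_par, De_perp=De_perp, S0=S0)
    fod = FODCoefficients(lmax=lmax, coeffs=coeffs)
    grid = VolumeGrid(data=np.zeros(shape), affine=np.diag([2.0, 2.0, 2.0, 1.0]))
    meta = {
        "seed": seed, "smoothness_vox": smoothness_vox,
        "fiber_config": fiber_config, "field_mode": field_mode,
        "kappa": kappa, "crossing_angle_deg": crossing_angle_deg,
    }
    return Phantom(grid=grid, kernel=kernel, fod=fod, mask=mask, meta=meta,
                   _truth_fns=truth_fns)


def simulate_signals(
    phantom: Phantom, protocol: AcquisitionProtocol
) -> VolumeGrid:
    """Noiseless SM signals on the phantom grid (analytic path).

    Voxels outside the mask carry zero signal.
    """
    if np.any(protocol.b_delta < 0):
        raise ValueError("the analytic simulation path requires b_delta >= 0")
    mask = phantom.mask
    k = phantom.kernel
    fwd = AnalyticForward(protocol, phantom.lmax)
    S = fwd.signal(
        k.f_i[mask], k.D_i[mask], k.De_par[mask], k.De_perp[mask], k.S0[mask],
        phantom.fod.coeffs[mask],
    )
    out = np.zeros(mask.shape + (protocol.n_measurements,))
    out[mask] = S
    return VolumeGrid(data=out, affine=phantom.grid.affine)


def add_noise(
    signals: VolumeGrid, protocol: AcquisitionProtocol, noise: NoiseSpec
) -> tuple[VolumeGrid, VolumeGrid]:
    """Add noise with spatially varying sigma set by the b = 0 signal and SNR.

    Per voxel ``sigma(x) = mean_{b=0 volumes} signal(x) / SNR``.  Gaussian:
    ``S + eps``; Rician: ``sqrt((S + eps1)^2 + eps2^2)`` with independent
    ``eps ~ N(0, sigma^2)`` (the magnitude of a complex signal with noisy
    real and imaginary channels).  Returns the noisy volume and the sigma map.
    """
    data = np.asarray(signals.data, dtype=float)
    b0_vols = protocol.b == 0
    if not np.any(b0_vols):
        raise ValueError("protocol has no b = 0 volumes to set the noise scale")
    sigma = data[..., b0_vols].mean(axis=-1) / noise.snr
    sigma_grid = VolumeGrid(data=sigma, affine=signals.affine)
    if noise.kind == "none":
        return VolumeGrid(data=data.copy(), affine=signals.affine), VolumeGrid(
            data=np.zeros_like(sigma), affine=signals.affine
        )
    rng = np.random.default_rng(noise.seed)
    s = sigma[..., None]
    if noise.kind == "gaussian":
        noisy = data + rng.standard_normal(data.shape) * s
    else:
        e1 = rng.standard_normal(data.shape) * s
        e2 = rng.standard_normal(data.shape) * s
        noisy = np.sqrt((data + e1) ** 2 + e2**2)
    return VolumeGrid(data=noisy, affine=signals.affine), sigma_grid
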