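"""The coordinate network: Fourier-feature encoding, MLP and output heads.

An implicit neural representation maps a 3-D position to the Standard Model
kernel parameters and the FOD SH coefficients at that position.  The network
is the composition

    x -> gamma(x) = [cos(2 pi A x), sin(2 pi A x)]       (fixed random A)
      -> 4 fully connected layers of width n_h, ReLU     (latent z >= 0)
      -> per-parameter heads: scaled sigmoid for f_i, D_i, De_par, De_perp
         (physiological bounds), softplus for S0, identity for each p_l^m.

The encoding matrix A (n_p x 3, entries ~ N(0, sigma^2)) is drawn once at
initialization and never trained; sigma^2 controls how fine the spatial
detail the network can represent is, i.e. the strength of the implicit
spatial regularization.

Everything here is plain NumPy; the trainer in :mod:`sminr.fitting` supplies
hand-derived gradients, which is exact because the architecture is a fixed
composition of smooth (or piecewise-linear) primitives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .forward import KERNEL_BOUNDS
from .io import VolumeGrid
from .sh import FODCoefficients, n_coeffs

__all__ = [
    "FourierEncoding",
    "INRModel",
    "init_model",
    "scale_coordinates",
    "grid_scaler",
    "encode",
    "predict",
    "voxel_center_coordinates",
]

N_KERNEL_HEADS = 4  # f_i, D_i, De_par, De_perp
KERNEL_HEAD_NAMES = ("f_i", "D_i", "De_par", "De_perp")


@dataclass
class FourierEncoding:
    """Fixed random frequency matrix for the sinusoidal coordinate encoding."""

    A: np.ndarray
    sigma2: float
    seed: int = 0

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2 or self.A.shape[1] != 3:
            raise ValueError("A must be (n_p, 3)")

    @property
    def n_p(self) -> int:
        return self.A.shape[0]

    @classmethod
    def create(cls, n_p: int, sigma2: float, seed: int) -> "FourierEncoding":
        rng = np.random.default_rng(seed)
        A = rng.normal(0.0, np.sqrt(sigma2), size=(n_p, 3))
        return cls(A=A, sigma2=float(sigma2), seed=int(seed))


def encode(x_scaled: np.ndarray, encoding: FourierEncoding) -> np.ndarray:
    """gamma(x) = [cos(2 pi A x), sin(2 pi A x)], cos block first.

    ``x_scaled`` is (..., 3) in [-1, 1]^3; output is (..., 2 n_p) with all
    entries in [-1, 1].
    """
    ax = 2.0 * np.pi * (np.asarray(x_scaled, dtype=float) @ encoding.A.T)
    return np.concatenate([np.cos(ax), np.sin(ax)], axis=-1)


def grid_scaler(grid: VolumeGrid) -> tuple[np.ndarray, float]:
    """Center (in mm, voxel units * voxel_size) and scale factor for a grid.

    The longest physical axis (voxel-center to voxel-center) maps onto
    [-1, 1]; the other axes are scaled by the same factor so the aspect
    ratio is preserved.
    """
    shape = np.asarray(grid.shape, dtype=float)
    extent = (shape - 1.0) * grid.voxel_size
    if np.max(extent) <= 0:
        raise ValueError("degenerate grid: zero physical extent")
    center = (shape - 1.0) / 2.0 * grid.voxel_size
    factor = 2.0 / np.max(extent)
    return center, float(factor)


def scale_coordinates(
    coords: np.ndarray, grid: VolumeGrid, voxel_units: bool = True
) -> np.ndarray:
    """Map coordinates into the aspect-ratio-preserving [-1, 1]^3 input cube.

    ``coords`` are voxel-index coordinates (possibly fractional) when
    ``voxel_units`` is true, otherwise physical mm offsets on the grid axes.
    """
    center, factor = grid_scaler(grid)
    coords = np.asarray(coords, dtype=float)
    phys = coords * grid.voxel_size if voxel_units else coords
    return (phys - center) * factor


def voxel_center_coordinates(shape) -> np.ndarray:
    """All voxel-center index coordinates of a grid, shape (nx*ny*nz, 3)."""
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=-1).astype(float)


class INRModel:
    """Fourier encoding + 4-layer ReLU MLP + per-parameter output heads.

    ``weights`` maps layer names to arrays: ``W1..W4``/``b1..b4`` for the
    MLP, ``Wh``/``bh`` for the (stacked) heads.  Head columns are ordered
    [f_i, D_i, De_par, De_perp, S0, p_0^0, ..., p_lmax^lmax]; the first four
    use a sigmoid scaled to the physiological bounds, S0 uses
    softplus * s0_scale (``s0_scale`` is set from the mean b = 0 signal when
    fitting, so the initial S0 sits at a data-driven scale), and the SH
    coefficients are linear.
    """

    def __init__(
        self,
        encoding: FourierEncoding,
        n_h: int,
        lmax: int,
        weights: dict[str, np.ndarray],
        seed: int,
        s0_scale: float = 1.0,
        bounds: np.ndarray | None = None,
        scaler_center: np.ndarray | None = None,
        scaler_factor: float = 1.0,
        protocol_fingerprint: str | None = None,
        pin_p00: bool = False,
    ):
        if lmax not in (2, 4, 6, 8):
            raise ValueError(f"lmax must be one of 2, 4, 6, 8, got {lmax}")
        self.encoding = encoding
        self.n_h = int(n_h)
        self.lmax = int(lmax)
        self.weights = weights
        self.seed = int(seed)
        self.s0_scale = float(s0_scale)
        self.bounds = KERNEL_BOUNDS.copy() if bounds is None else np.asarray(bounds)
        self.scaler_center = (
            np.zeros(3) if scaler_center is None else np.asarray(scaler_center, float)
        )
        self.scaler_factor = float(scaler_factor)
        self.protocol_fingerprint = protocol_fingerprint
        # optionally fix the FOD mean at the unit-integral value, removing
        # the S0 x FOD scale degeneracy (S0 then carries the signal scale)
        self.pin_p00 = bool(pin_p00)
        self.voxel_size = np.ones(3)

    # -- geometry ----------------------------------------------------------

    def attach_grid(self, grid: VolumeGrid) -> None:
        """Bind the coordinate scaler to a volume's geometry (done at fit time)."""
        center, factor = grid_scaler(grid)
        self.scaler_center = center
        self.scaler_factor = factor
        self.voxel_size = np.asarray(grid.voxel_size, dtype=float)

    def scale(self, coords_vox: np.ndarray) -> np.ndarray:
        phys = np.asarray(coords_vox, dtype=float) * self.voxel_size
        return (phys - self.scaler_center) * self.scaler_factor

    # -- dimensions --------------------------------------------------------

    @property
    def n_coeffs(self) -> int:
        return n_coeffs(self.lmax)

    @property
    def n_outputs(self) -> int:
        return N_KERNEL_HEADS + 1 + self.n_coeffs

    # -- forward -----------------------------------------------------------

    def forward(self, x_scaled: np.ndarray, cache: bool = False):
        """Raw network pass: scaled coords -> head outputs (..., n_outputs).

        With ``cache=True`` also returns the intermediates needed by the
        trainer's backward pass.
        """
        w = self.weights
        gamma = encode(x_scaled, self.encoding)
        h, caches = gamma, [gamma]
        for i in range(1, 5):
            pre = h @ w[f"W{i}"] + w[f"b{i}"]
            h = np.maximum(pre, 0.0)
            if cache:
                caches.append(pre)
        pre_heads = h @ w["Wh"] + w["bh"]
        out = self._activate(pre_heads)
        if cache:
            return out, {"acts": caches, "z": h, "pre_heads": pre_heads}
        return out

    def _activate(self, pre: np.ndarray) -> np.ndarray:
        from scipy.special import expit

        out = np.empty_like(pre)
        lo, hi = self.bounds[:, 0], self.bounds[:, 1]
        sig = expit(pre[..., :N_KERNEL_HEADS])
        out[..., :N_KERNEL_HEADS] = lo + (hi - lo) * sig
        out[..., N_KERNEL_HEADS] = (
            np.logaddexp(0.0, pre[..., N_KERNEL_HEADS]) * self.s0_scale
        )
        out[..., N_KERNEL_HEADS + 1 :] = pre[..., N_KERNEL_HEADS + 1 :]
        if self.pin_p00:
            out[..., N_KERNEL_HEADS + 1] = 1.0 / np.sqrt(4.0 * np.pi)
        return out

    def predict_scaled(self, x_scaled: np.ndarray) -> np.ndarray:
        return self.forward(x_scaled)

    # -- serialization helper ---------------------------------------------

    def copy(self) -> "INRModel":
        m = INRModel(
            encoding=FourierEncoding(
                A=self.encoding.A.copy(), sigma2=self.encoding.sigma2,
                seed=self.encoding.seed,
            ),
            n_h=self.n_h, lmax=self.lmax,
            weights={k: v.copy() for k, v in self.weights.items()},
            seed=self.seed, s0_scale=self.s0_scale, bounds=self.bounds.copy(),
            scaler_center=self.scaler_center.copy(),
            scaler_factor=self.scaler_factor,
            protocol_fingerprint=self.protocol_fingerprint,
        )
        m.voxel_size = self.voxel_size.copy()
        return m


def init_model(
    n_p: int = 5000,
    n_h: int = 2048,
    sigma2: float = 3.5,
    lmax: int = 2,
    seed: int = 0,
) -> INRModel:
    """Deterministic model initialization.

    MLP layers use He-normal weights (appropriate for ReLU); the stacked
    head layer starts at zero weights and zero biases so that the kernel
    parameters begin mid-range (sigmoid(0) = 0.5), S0 at
    softplus(0) * s0_scale, and the FOD at zero — a physiologic,
    non-saturated starting point.
    """
    if n_p < 1 or n_h < 1:
        raise ValueError("n_p and n_h must be positive")
    if lmax not in (2, 4, 6, 8):
        raise ValueError(f"lmax must be one of 2, 4, 6, 8, got {lmax}")
    rng = np.random.default_rng(seed)
    enc = FourierEncoding.create(n_p, sigma2, seed=int(rng.integers(2**31 - 1)))
    dims = [2 * n_p, n_h, n_h, n_h, n_h]
    weights: dict[str, np.ndarray] = {}
    for i in range(1, 5):
        fan_in = dims[i - 1]
        weights[f"W{i}"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, dims[i]))
        weights[f"b{i}"] = np.zeros(dims[i])
    n_out = N_KERNEL_HEADS + 1 + n_coeffs(lmax)
    weights["Wh"] = np.zeros((n_h, n_out))
    weights["bh"] = np.zeros(n_out)
    # start from the unit-integral isotropic FOD so the initial prediction is
    # a physiologic signal (b = 0 rows equal s0_scale * softplus(0)) rather
    # than zero
    weights["bh"][N_KERNEL_HEADS + 1] = 1.0 / np.sqrt(4.0 * np.pi)
    return INRModel(encoding=enc, n_h=n_h, lmax=lmax, weights=weights, seed=seed)


def predict(model: INRModel, coords_vox: np.ndarray, warn_extrapolation: bool = True):
    """Evaluate the model at (possibly fractional) voxel coordinates.

    Returns ``(KernelParams, FODCoefficients)`` with per-coordinate arrays.
    Coordinates mapping outside [-1, 1]^3 trigger an extrapolation warning
    (the representation is only trained inside the volume).
    """
    from .forward import KernelParams

    x = model.scale(coords_vox)
    if warn_extrapolation and np.any(np.abs(x) > 1.0 + 1e-9):
        warnings.warn(
            "coordinates outside the trained [-1, 1]^3 cube: extrapolating",
            stacklevel=2,
        )
    out = model.forward(x)
    params = KernelParams(
        f_i=out[..., 0], D_i=out[..., 1], De_par=out[..., 2],
        De_perp=out[..., 3], S0=out[..., 4],
    )
    fod = FODCoefficients(lmax=model.lmax, coeffs=out[..., N_KERNEL_HEADS + 1 :])
    return params, fod
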