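"""On-disk formats: NIfTI volumes, FSL-style protocols, model containers.

Unit convention: b-values are read from FSL ``bval`` files in s/mm^2 (the
field standard) and stored internally in ms/um^2 (divide by 1000), so that
``b * D`` is dimensionless with diffusivities in um^2/ms.

The B-tensor shape file (``bdelta``) is plain text with one value per volume
in the same ordering as ``bval``; values lie in [-0.5, 1] (1 = linear,
0 = spherical, -0.5 = planar encoding).

The gradient-coil tensor field is a 4-D NIfTI with 9 volumes in row-major
order (L11, L12, L13, L21, ..., L33).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeGrid",
    "AcquisitionProtocol",
    "GradientTensorField",
    "read_protocol",
    "write_protocol",
    "read_volume",
    "write_volume",
    "read_mask",
    "read_gradient_tensor",
    "save_model",
    "load_model",
]


@dataclass
class VolumeGrid:
    """A gridded scalar or vector field with voxel geometry.

    ``data`` has shape ``shape`` (3-D scalar field) or ``shape + (k,)``
    (per-voxel vectors, e.g. a 4-D diffusion-weighted series).
    """

    data: np.ndarray
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]
    voxel_size: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError(f"volume data must be 3-D or 4-D, got {self.data.ndim}-D")
        if self.affine is None:
            self.affine = np.eye(4)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")
        if self.voxel_size is None:
            self.voxel_size = np.linalg.norm(self.affine[:3, :3], axis=0)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        if self.voxel_size.shape != (3,) or np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size must be 3 strictly positive lengths")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return 1 if self.data.ndim == 3 else self.data.shape[3]


@dataclass
class AcquisitionProtocol:
    """Per-measurement b-value (ms/um^2), B-tensor shape and encoding direction.

    ``b0_replaced`` flags measurements whose (zero-norm) b-vector was replaced
    by the placeholder (1, 0, 0) -- only allowed on b = 0 volumes.
    """

    b: np.ndarray
    b_delta: np.ndarray
    u: np.ndarray
    b0_replaced: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float)
        self.b_delta = np.asarray(self.b_delta, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        n = self.b.shape[0]
        if self.b_delta.shape != (n,) or self.u.shape != (n, 3):
            raise ValueError("b, b_delta and u must share the measurement axis")
        if np.any(self.b < 0):
            raise ValueError("b-values must be non-negative")
        if np.any(self.b_delta < -0.5 - 1e-12) or np.any(self.b_delta > 1 + 1e-12):
            raise ValueError("b_delta must lie in [-0.5, 1]")
        dw = self.b > 0
        norms = np.linalg.norm(self.u[dw], axis=1)
        if dw.any() and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("encoding directions must be unit norm on b > 0 volumes")
        if self.b0_replaced is None:
            self.b0_replaced = np.zeros(n, dtype=bool)
        self.b0_replaced = np.asarray(self.b0_replaced, dtype=bool)

    @property
    def n_measurements(self) -> int:
        return self.b.shape[0]

    def fingerprint(self) -> str:
        """Stable hash of (b, b_delta, u) used to tie a model to its protocol."""
        import hashlib

        h = hashlib.sha256()
        for arr in (self.b, self.b_delta, self.u):
            h.update(np.ascontiguousarray(arr, dtype=np.float64).tobytes())
        return h.hexdigest()[:16]


@dataclass
class GradientTensorField:
    """Per-voxel dimensionless 3x3 gradient-coil tensor, aligned with a grid."""

    L: np.ndarray  # (nx, ny, nz, 3, 3)

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        if self.L.ndim != 5 or self.L.shape[3:] != (3, 3):
            raise ValueError("L must have shape (nx, ny, nz, 3, 3)")
        if not np.all(np.isfinite(self.L)):
            raise ValueError("gradient tensors must be finite")

    def is_identity(self) -> bool:
        """True when every voxel's tensor is exactly the identity."""
        eye = np.zeros((3, 3))
        np.fill_diagonal(eye, 1.0)
        return bool(np.array_equal(self.L, np.broadcast_to(eye, self.L.shape)))


def read_protocol(
    bval_path: str, bvec_path: str, bdelta_path: str
) -> AcquisitionProtocol:
    """Read FSL-style bval/bvec plus a per-volume B-tensor-shape file.

    b-values are converted from s/mm^2 to ms/um^2.  Zero-norm b-vectors on
    b = 0 volumes are replaced by (1, 0, 0) and flagged in ``b0_replaced``.
    """
    bval = np.loadtxt(bval_path, ndmin=1, dtype=float).ravel()
    bvec = np.loadtxt(bvec_path, ndmin=2, dtype=float)
    if bvec.shape[0] == 3 and bvec.shape[1] != 3:
        bvec = bvec.T
    elif bvec.shape == (3, 3):
        # ambiguous; FSL convention is 3 rows x N columns
        bvec = bvec.T
    bdelta = np.loadtxt(bdelta_path, ndmin=1, dtype=float).ravel()
    n = bval.shape[0]
    if bvec.shape[0] != n or bdelta.shape[0] != n:
        raise ValueError(
            f"protocol files disagree on the number of volumes: "
            f"bval {n}, bvec {bvec.shape[0]}, bdelta {bdelta.shape[0]}"
        )
    if np.any(bval < 0):
        raise ValueError("negative b-value in bval file")
    if np.any(bdelta < -0.5) or np.any(bdelta > 1):
        raise ValueError("bdelta values must lie in [-0.5, 1]")
    u = bvec.copy()
    norms = np.linalg.norm(u, axis=1)
    replaced = norms < 1e-12
    if np.any(replaced & (bval > 0)):
        raise ValueError("zero-norm b-vector on a b > 0 volume")
    u[replaced] = [1.0, 0.0, 0.0]
    u[~replaced] /= norms[~replaced, None]
    return AcquisitionProtocol(
        b=bval / 1000.0, b_delta=bdelta, u=u, b0_replaced=replaced
    )


def write_protocol(
    protocol: AcquisitionProtocol, bval_path: str, bvec_path: str, bdelta_path: str
) -> None:
    """Inverse of :func:`read_protocol` (b written back in s/mm^2)."""
    np.savetxt(bval_path, protocol.b[None] * 1000.0, fmt="%.8g")
    u = protocol.u.copy()
    u[protocol.b0_replaced] = 0.0
    np.savetxt(bvec_path, u.T, fmt="%.10g")
    np.savetxt(bdelta_path, protocol.b_delta[None], fmt="%.8g")


def read_volume(path: str) -> VolumeGrid:
    """Read a 3-D or 4-D NIfTI volume."""
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim > 4:
        raise ValueError(f"expected a 3-D or 4-D volume, got {data.ndim}-D")
    return VolumeGrid(data=data, affine=np.asarray(img.affine))


def write_volume(grid: VolumeGrid, path: str) -> None:
    """Write a volume as NIfTI-1, preserving the affine exactly."""
    img = nib.Nifti1Image(np.asarray(grid.data, dtype=np.float32), grid.affine)
    nib.save(img, path)


def read_mask(path: str) -> VolumeGrid:
    """Read a 3-D volume and threshold at 0.5 into a boolean field."""
    grid = read_volume(path)
    if grid.data.ndim != 3:
        raise ValueError("mask must be a 3-D volume")
    return VolumeGrid(data=grid.data > 0.5, affine=grid.affine)


def read_gradient_tensor(path: str) -> GradientTensorField:
    """Read a 9-component NIfTI (L11, L12, ..., L33 row-major) tensor field."""
    grid = read_volume(path)
    if grid.data.ndim != 4 or grid.data.shape[3] != 9:
        raise ValueError("gradient tensor file must be 4-D with 9 volumes")
    L = grid.data.astype(float).reshape(grid.shape + (3, 3))
    return GradientTensorField(L=L)


# --- model container -------------------------------------------------------
# Single-file NumPy archive: a JSON metadata entry plus named float64 weight
# blobs.  Inspectable (np.load / unzip) and language-portable.

_CONTAINER_VERSION = 1


def save_model(model, path: str) -> None:
    """Serialize an :class:`~sminr.inr.INRModel` to a single ``.npz`` file."""
    meta = {
        "container_version": _CONTAINER_VERSION,
        "n_p": model.encoding.n_p,
        "sigma2": model.encoding.sigma2,
        "n_h": model.n_h,
        "lmax": model.lmax,
        "seed": model.seed,
        "s0_scale": model.s0_scale,
        "bounds": model.bounds.tolist(),
        "scaler_center": model.scaler_center.tolist(),
        "scaler_factor": model.scaler_factor,
        "voxel_size": model.voxel_size.tolist(),
        "protocol_fingerprint": model.protocol_fingerprint,
        "pin_p00": model.pin_p00,
    }
    arrays = {"A": model.encoding.A}
    for name, arr in model.weights.items():
        arrays[f"w_{name}"] = arr
    opt = getattr(model, "_opt_state", None)
    if opt is not None:
        meta["opt_t"] = opt.t
        meta["opt_lr"] = opt.lr
        meta["opt_betas"] = [opt.b1, opt.b2]
        meta["opt_eps"] = opt.eps
        for name, arr in opt.m.items():
            arrays[f"om_{name}"] = arr
        for name, arr in opt.v.items():
            arrays[f"ov_{name}"] = arr
    np.savez(path, _meta=json.dumps(meta), **arrays)


def load_model(path: str, expect_lmax: int | None = None):
    """Load a model container; reproduces predictions bit-identically."""
    from .inr import FourierEncoding, INRModel

    try:
        with np.load(path, allow_pickle=False) as npz:
            meta = json.loads(str(npz["_meta"]))
            arrays = {k: npz[k] for k in npz.files if k != "_meta"}
    except Exception as exc:  # noqa: BLE001 - any unreadable container
        raise ValueError(f"corrupt or unreadable model container: {exc}") from exc
    if meta.get("container_version") != _CONTAINER_VERSION:
        warnings.warn(
            f"model container version {meta.get('container_version')} differs "
            f"from current {_CONTAINER_VERSION}",
            stacklevel=2,
        )
    if expect_lmax is not None and meta["lmax"] != expect_lmax:
        raise ValueError(
            f"model was fitted with lmax={meta['lmax']}, expected {expect_lmax}"
        )
    enc = FourierEncoding(A=arrays["A"], sigma2=meta["sigma2"], seed=meta["seed"])
    weights = {k[2:]: v for k, v in arrays.items() if k.startswith("w_")}
    model = INRModel(
        encoding=enc,
        n_h=meta["n_h"],
        lmax=meta["lmax"],
        weights=weights,
        seed=meta["seed"],
        s0_scale=meta["s0_scale"],
        bounds=np.asarray(meta["bounds"]),
        scaler_center=np.asarray(meta["scaler_center"]),
        scaler_factor=meta["scaler_factor"],
        protocol_fingerprint=meta.get("protocol_fingerprint"),
        pin_p00=bool(meta.get("pin_p00", False)),
    )
    model.voxel_size = np.asarray(meta.get("voxel_size", [1.0, 1.0, 1.0]), float)
    if "opt_t" in meta:
        from .fitting import AdamState

        opt = AdamState(
            model.weights, betas=tuple(meta["opt_betas"]),
            eps=meta["opt_eps"], lr=meta["opt_lr"],
        )
        opt.t = meta["opt_t"]
        opt.m = {k[3:]: v for k, v in arrays.items() if k.startswith("om_")}
        opt.v = {k[3:]: v for k, v in arrays.items() if k.startswith("ov_")}
        model._opt_state = opt
    return model
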