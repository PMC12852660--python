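"""Evaluation against ground truth: Pearson rho, RMSE, p2 and upsampling.

Metrics are computed inside the ground-truth mask after dropping non-finite
estimates (the number removed is reported).  ``interpolate_map`` provides
the conventional grid-based upsampling (trilinear / tricubic at refined
voxel centers) against which the INR's continuous resampling is compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.stats import pearsonr

__all__ = [
    "MetricReport",
    "pearson_rho",
    "rmse",
    "interpolate_map",
    "compare_methods",
]


@dataclass
class MetricReport:
    """Per-parameter rho / RMSE for one estimation method on one fixture."""

    method: str
    rho: dict[str, float] = field(default_factory=dict)
    rmse: dict[str, float] = field(default_factory=dict)
    n_voxels: int = 0
    n_dropped: int = 0
    mask_description: str = ""

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "rho": self.rho,
            "rmse": self.rmse,
            "n_voxels": self.n_voxels,
            "n_dropped": self.n_dropped,
            "mask_description": self.mask_description,
        }


def _masked_pair(est, truth, mask):
    est = np.asarray(est, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if mask is None:
        mask = np.ones(est.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    e, t = est[mask], truth[mask]
    ok = np.isfinite(e) & np.isfinite(t)
    return e[ok], t[ok], int(np.sum(~ok))


def pearson_rho(est, truth, mask=None) -> float:
    """Product-moment correlation over masked, finite voxels.

    Returns NaN when fewer than 3 voxels remain or either input has zero
    variance (the correlation is undefined there).
    """
    e, t, _ = _masked_pair(est, truth, mask)
    if e.size < 3 or np.std(e) == 0 or np.std(t) == 0:
        return float("nan")
    return float(pearsonr(e, t).statistic)


def rmse(est, truth, mask=None) -> float:
    """Root-mean-squared error over masked, finite voxels (parameter units)."""
    e, t, _ = _masked_pair(est, truth, mask)
    if e.size == 0:
        raise ValueError("no voxels to evaluate")
    return float(np.sqrt(np.mean((e - t) ** 2)))


def interpolate_map(map3d: np.ndarray, factor: int, method: str = "linear"):
    """Separable grid interpolation of a 3-D map at refined voxel centers.

    Refined centers sit at ``(i + 0.5) / factor - 0.5`` in original voxel
    units; ``factor=1`` is the identity.  ``method`` is 'linear' or 'cubic'
    (interpolating cubic B-spline).
    """
    orders = {"linear": 1, "cubic": 3}
    if method not in orders:
        raise ValueError(f"unsupported interpolation method '{method}'")
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    map3d = np.asarray(map3d, dtype=float)
    if map3d.ndim != 3:
        raise ValueError("expected a 3-D map")
    new_shape = tuple(int(s * factor) for s in map3d.shape)
    grids = np.meshgrid(*[np.arange(s) for s in new_shape], indexing="ij")
    coords = [(g + 0.5) / factor - 0.5 for g in grids]
    return map_coordinates(map3d, coords, order=orders[method], mode="nearest")


def compare_methods(*reports: MetricReport) -> dict:
    """Combine reports into a deterministic ranked table (JSON-ready).

    Methods are ranked by mean Pearson rho across parameters (descending,
    ties broken by method name).  All reports must describe the same mask.
    """
    if not reports:
        raise ValueError("need at least one report")
    masks = {r.mask_description for r in reports}
    counts = {r.n_voxels for r in reports}
    if len(masks) > 1 or len(counts) > 1:
        raise ValueError("reports were computed on inconsistent masks")
    rows = []
    for r in reports:
        mean_rho = float(np.nanmean(list(r.rho.values()))) if r.rho else float("nan")
        rows.append({"mean_rho": mean_rho, **r.to_dict()})
    rows.sort(key=lambda row: (-row["mean_rho"], row["method"]))
    return {"ranking": [row["method"] for row in rows], "rows": rows}
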