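"""Self-supervised training of the INR against the measured diffusion signal.

The objective minimized over the network weights is, per masked voxel x_j,

    sum_i L(S(b_i, bD_i, u_i, x_j), S_hat(...)) + Lambda_{x_j}

averaged over voxels, where L is either the mean squared error or the Rician
negative log-likelihood, and Lambda is a non-negativity penalty on the FOD
amplitude (negative amplitudes sampled on a fixed spherical point set are
added to the loss).  Optimization uses Adam (lr 1e-4, betas 0.9/0.999,
eps 1e-8, no weight decay) for 150 epochs with shuffled batches of 500
masked voxel centers; the full dataset is used without a train/test split
because the goal is representation, not generalization to held-out voxels.

All gradients are hand-derived and exact for the implemented forward model:
the Funk-Hecke factors and their a-derivatives come from the same fixed
Gauss-Legendre rule, and the network is a composition of smooth or
piecewise-linear primitives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import i0e, i1e

from .forward import AnalyticForward, NumericForward, effective_protocol_field
from .inr import (
    INRModel,
    N_KERNEL_HEADS,
    init_model,
    voxel_center_coordinates,
)
from .io import AcquisitionProtocol, GradientTensorField, VolumeGrid
from .sh import FODCoefficients, SphereDirections, hemisphere_directions, real_sh_basis

logger = logging.getLogger(__name__)

__all__ = [
    "FitConfig",
    "mse_loss",
    "rician_nll_loss",
    "fod_nonneg_penalty",
    "fit_inr",
    "upsample",
    "AdamState",
]


@dataclass
class FitConfig:
    """Hyperparameters of the INR fit (defaults follow the reference setup)."""

    loss: str = "mse"  # "mse" or "rician"
    epochs: int = 150
    batch_size: int = 500
    learning_rate: float = 1e-4
    adam_betas: tuple[float, float] = (0.9, 0.999)
    adam_eps: float = 1e-8
    weight_decay: float = 0.0
    integration: str = "analytic"  # "analytic" or "numeric"
    lmax: int = 2
    n_p: int = 5000
    n_h: int = 2048
    sigma2: float = 3.5
    nonneg_weight: float = 1.0
    nonneg_directions: int = 300
    pin_p00: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loss not in ("mse", "rician"):
            raise ValueError("loss must be 'mse' or 'rician'")
        if self.integration not in ("analytic", "numeric"):
            raise ValueError("integration must be 'analytic' or 'numeric'")
        if min(self.epochs, self.batch_size, self.n_p, self.n_h) < 1:
            raise ValueError("counts must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


# --- losses ----------------------------------------------------------------


def mse_loss(S_meas: np.ndarray, S_pred: np.ndarray) -> float:
    """Mean squared error between measured and predicted signal vectors."""
    S_meas = np.asarray(S_meas, dtype=float)
    S_pred = np.asarray(S_pred, dtype=float)
    if S_meas.shape != S_pred.shape:
        raise ValueError("signal vectors must have equal shape")
    return float(np.mean((S_meas - S_pred) ** 2))


def _log_i0(x: np.ndarray) -> np.ndarray:
    """log I0(x), overflow-safe: log(i0e(|x|)) + |x| (I0 is even)."""
    ax = np.abs(x)
    return np.log(i0e(ax)) + ax


def rician_nll_loss(
    S_meas: np.ndarray, S_pred: np.ndarray, sigma: np.ndarray
) -> float:
    """Rician negative log-likelihood (terms constant in the prediction dropped).

    Per measurement: ``nu^2 / (2 sigma^2) - log I0(S nu / sigma^2)`` with
    ``nu`` the noise-free prediction; minimizing this over ``nu`` for Rician
    draws recovers the true amplitude, where the MSE minimizer recovers the
    (biased) Rician mean.
    """
    S_meas = np.asarray(S_meas, dtype=float)
    S_pred = np.asarray(S_pred, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    s2 = sigma**2
    return float(np.mean(S_pred**2 / (2.0 * s2) - _log_i0(S_meas * S_pred / s2)))


def _rician_nll_grad(S_meas, S_pred, sigma):
    """d(mean loss)/dS_pred, elementwise before the mean normalization."""
    s2 = sigma**2
    x = S_meas * S_pred / s2
    ratio = np.sign(x) * i1e(np.abs(x)) / i0e(np.abs(x))
    return S_pred / s2 - (S_meas / s2) * ratio


def fod_nonneg_penalty(
    coeffs: FODCoefficients, constraint_dirs: SphereDirections
) -> float | np.ndarray:
    """Lambda = mean over sample directions of max(0, -amplitude).

    Zero iff the FOD is non-negative on the sample set; positively
    homogeneous of degree one in the coefficients.
    """
    basis = real_sh_basis(coeffs.lmax, constraint_dirs)
    amp = coeffs.coeffs @ basis.T
    pen = np.mean(np.maximum(0.0, -amp), axis=-1)
    return float(pen) if np.ndim(pen) == 0 else pen


# --- optimizer -------------------------------------------------------------


class AdamState:
    """Plain Adam with bias correction; state is serializable with the model."""

    def __init__(self, weights: dict[str, np.ndarray], betas=(0.9, 0.999),
                 eps: float = 1e-8, lr: float = 1e-4):
        self.m = {k: np.zeros_like(v) for k, v in weights.items()}
        self.v = {k: np.zeros_like(v) for k, v in weights.items()}
        self.t = 0
        self.b1, self.b2 = betas
        self.eps = eps
        self.lr = lr

    def step(self, weights: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            weights[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )


# --- network backward pass -------------------------------------------------


def _backward(model: INRModel, cache: dict, d_out: np.ndarray) -> dict:
    """Backprop dL/d(head outputs) through heads and MLP; returns weight grads."""
    from scipy.special import expit

    w = model.weights
    pre_heads = cache["pre_heads"]
    lo, hi = model.bounds[:, 0], model.bounds[:, 1]
    d_pre = np.empty_like(d_out)
    sig = expit(pre_heads[..., :N_KERNEL_HEADS])
    d_pre[..., :N_KERNEL_HEADS] = d_out[..., :N_KERNEL_HEADS] * (hi - lo) * sig * (
        1.0 - sig
    )
    s0_sig = expit(pre_heads[..., N_KERNEL_HEADS])
    d_pre[..., N_KERNEL_HEADS] = (
        d_out[..., N_KERNEL_HEADS] * model.s0_scale * s0_sig
    )
    d_pre[..., N_KERNEL_HEADS + 1 :] = d_out[..., N_KERNEL_HEADS + 1 :]
    if model.pin_p00:
        d_pre[..., N_KERNEL_HEADS + 1] = 0.0  # pinned constant, not trained

    z = cache["z"]
    grads = {"Wh": z.T @ d_pre, "bh": d_pre.sum(axis=0)}
    dh = d_pre @ w["Wh"].T
    acts = cache["acts"]  # [gamma, pre1, pre2, pre3, pre4]
    for i in range(4, 0, -1):
        d_pre_i = dh * (acts[i] > 0)
        h_prev = acts[i - 1] if i == 1 else np.maximum(acts[i - 1], 0.0)
        grads[f"W{i}"] = h_prev.T @ d_pre_i
        grads[f"b{i}"] = d_pre_i.sum(axis=0)
        if i > 1:
            dh = d_pre_i @ w[f"W{i}"].T
    return grads


# --- training loop ---------------------------------------------------------


def _split_outputs(out: np.ndarray):
    return (
        out[:, 0], out[:, 1], out[:, 2], out[:, 3], out[:, 4],
        out[:, N_KERNEL_HEADS + 1 :],
    )


def fit_inr(
    dwi: VolumeGrid,
    protocol: AcquisitionProtocol,
    mask: VolumeGrid,
    config: FitConfig,
    sigma_map: VolumeGrid | None = None,
    grad_tensor: GradientTensorField | None = None,
    model: INRModel | None = None,
    start_epoch: int = 0,
) -> tuple[INRModel, list[float]]:
    """Fit an INR to a masked 4-D diffusion dataset.

    Returns the fitted model and the per-epoch mean loss trace.  Deterministic
    given ``config.seed``; passing a previously fitted ``model`` (with its
    stored optimizer state) together with ``start_epoch`` resumes training
    exactly where it stopped.
    """
    if dwi.data.ndim != 4 or dwi.data.shape[3] != protocol.n_measurements:
        raise ValueError("dwi 4th dimension must match the protocol length")
    mask_arr = np.asarray(mask.data, dtype=bool)
    if mask_arr.shape != dwi.shape or not mask_arr.any():
        raise ValueError("mask must be non-empty and match the dwi grid")
    if config.loss == "rician" and sigma_map is None:
        raise ValueError("the Rician likelihood loss requires a sigma map")

    integration = config.integration
    if np.any(protocol.b_delta < 0) and integration == "analytic":
        logger.info("negative b_delta present: switching to numeric integration")
        integration = "numeric"

    vox_idx = np.argwhere(mask_arr)  # (V, 3)
    signals = dwi.data[mask_arr].astype(float)  # (V, M)
    V = signals.shape[0]

    if model is None:
        model = init_model(config.n_p, config.n_h, config.sigma2, config.lmax,
                           config.seed)
        model.pin_p00 = config.pin_p00
        model.attach_grid(dwi)
        b0_mean = float(np.mean(signals[:, protocol.b == 0])) if np.any(
            protocol.b == 0
        ) else float(np.mean(signals))
        model.s0_scale = max(b0_mean, 1e-12) / np.log(2.0)
        model.protocol_fingerprint = protocol.fingerprint()

    x_scaled = model.scale(vox_idx.astype(float))

    sigma = None
    if sigma_map is not None:
        sigma = np.asarray(sigma_map.data, dtype=float)[mask_arr]
        if config.loss == "rician" and np.any(sigma <= 0):
            raise ValueError("sigma must be > 0 inside the mask")

    # per-voxel effective protocols (skipped for an exactly-identity field,
    # where the correction is a no-op)
    per_voxel = None
    if grad_tensor is not None and not grad_tensor.is_identity():
        if grad_tensor.L.shape[:3] != dwi.shape:
            raise ValueError("gradient tensor field must match the dwi grid")
        L_vox = grad_tensor.L[mask_arr]  # (V, 3, 3)
        b_eff, bd_eff, u_eff = effective_protocol_field(protocol, L_vox)
        Y_eff = real_sh_basis(config.lmax, u_eff.reshape(-1, 3)).reshape(
            V, protocol.n_measurements, -1
        )
        per_voxel = (b_eff, bd_eff, u_eff, Y_eff)
        if np.any(bd_eff < 0) and integration == "analytic":
            logger.info("effective b_delta < 0: switching to numeric integration")
            integration = "numeric"

    if per_voxel is None:
        if integration == "analytic":
            shared_fwd = AnalyticForward(protocol, config.lmax)
        else:
            shared_fwd = NumericForward(protocol, config.lmax)
    else:
        shared_fwd = None

    cdirs = hemisphere_directions(config.nonneg_directions, seed=config.seed)
    Bc = real_sh_basis(config.lmax, cdirs)  # (n_dirs, C)

    opt = getattr(model, "_opt_state", None)
    if opt is None:
        opt = AdamState(model.weights, betas=config.adam_betas,
                        eps=config.adam_eps, lr=config.learning_rate)
        model._opt_state = opt

    trace: list[float] = []
    M = protocol.n_measurements
    for epoch in range(start_epoch, config.epochs):
        rng = np.random.default_rng([config.seed, epoch])
        order = rng.permutation(V)
        epoch_loss = 0.0
        n_batches = 0
        for b0 in range(0, V, config.batch_size):
            idx = order[b0 : b0 + config.batch_size]
            xb = x_scaled[idx]
            Sb = signals[idx]
            out, cache = model.forward(xb, cache=True)
            f_i, D_i, De_par, De_perp, S0, p = _split_outputs(out)

            if per_voxel is not None:
                b_eff, bd_eff, u_eff, Y_eff = per_voxel
                if integration == "analytic":
                    fwd = AnalyticForward(
                        (b_eff[idx], bd_eff[idx]), config.lmax, Y=Y_eff[idx]
                    )
                else:
                    fwd = NumericForward(
                        (b_eff[idx], bd_eff[idx]), config.lmax, u=u_eff[idx]
                    )
            else:
                fwd = shared_fwd

            if integration == "analytic":
                S_pred, pgrads = fwd.signal_and_gradients(
                    f_i, D_i, De_par, De_perp, S0, p
                )
            else:
                S_pred, pgrads = fwd.signal(
                    f_i, D_i, De_par, De_perp, S0, p, with_grads=True
                )

            B = Sb.shape[0]
            if config.loss == "mse":
                data_loss = np.mean((S_pred - Sb) ** 2)
                G = 2.0 * (S_pred - Sb) / (B * M)
            else:
                sig_b = sigma[idx][:, None]
                data_loss = float(
                    np.mean(S_pred**2 / (2 * sig_b**2)
                            - _log_i0(Sb * S_pred / sig_b**2))
                )
                G = _rician_nll_grad(Sb, S_pred, sig_b) / (B * M)

            # FOD non-negativity penalty
            amp = p @ Bc.T  # (B, n_dirs)
            neg = amp < 0
            pen = np.mean(np.maximum(0.0, -amp), axis=1)
            pen_loss = float(np.mean(pen))
            d_p_pen = -(neg.astype(float) @ Bc) / Bc.shape[0] / B

            loss_val = data_loss + config.nonneg_weight * pen_loss
            epoch_loss += loss_val
            n_batches += 1

            # assemble dL/d(head outputs)
            d_out = np.zeros_like(out)
            d_out[:, 0] = (G * pgrads["f_i"]).sum(axis=1)
            d_out[:, 1] = (G * pgrads["D_i"]).sum(axis=1)
            d_out[:, 2] = (G * pgrads["De_par"]).sum(axis=1)
            d_out[:, 3] = (G * pgrads["De_perp"]).sum(axis=1)
            d_out[:, 4] = (G * pgrads["S0"]).sum(axis=1)
            if integration == "analytic":
                d_p = fwd.vjp_p(G, pgrads)
            else:
                d_p = fwd.vjp_p(G)
            d_out[:, N_KERNEL_HEADS + 1 :] = (
                d_p + config.nonneg_weight * d_p_pen
            )

            wgrads = _backward(model, cache, d_out)
            opt.step(model.weights, wgrads)

        trace.append(epoch_loss / max(n_batches, 1))
        if (epoch + 1) % 25 == 0 or epoch == config.epochs - 1:
            logger.info("epoch %d/%d mean loss %.6g", epoch + 1, config.epochs,
                        trace[-1])
    model._loss_trace = getattr(model, "_loss_trace", []) + trace
    return model, trace


# --- continuous resampling -------------------------------------------------


def predict_on_grid(
    model: INRModel, shape, factor: int = 1, chunk: int = 16384
) -> np.ndarray:
    """Evaluate the model at the voxel centers of a ``factor``-refined grid.

    Refined voxel centers sit at ``(i + 0.5) / factor - 0.5`` in original
    voxel units, so ``factor=1`` reproduces the training-grid coordinates
    exactly.  Returns ``(fx*nx, fy*ny, fz*nz, n_outputs)``.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    new_shape = tuple(int(s * factor) for s in shape)
    coords = voxel_center_coordinates(new_shape)
    coords = (coords + 0.5) / factor - 0.5
    out = np.empty((coords.shape[0], model.n_outputs))
    for c0 in range(0, coords.shape[0], chunk):
        sl = slice(c0, c0 + chunk)
        out[sl] = model.forward(model.scale(coords[sl]))
    return out.reshape(new_shape + (model.n_outputs,))


def upsample(model: INRModel, grid: VolumeGrid, factor: int = 1) -> VolumeGrid:
    """Continuous upsampling: parameter maps at ``factor``-refined resolution.

    The returned 4-D volume stacks [f_i, D_i, De_par, De_perp, S0, p_l^m...]
    along the last axis, with the affine adjusted to the refined voxel size.
    """
    maps = predict_on_grid(model, grid.shape, factor)
    f = float(factor)
    refine = np.eye(4)
    refine[:3, :3] /= f
    refine[:3, 3] = 0.5 / f - 0.5
    return VolumeGrid(data=maps, affine=grid.affine @ refine)
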