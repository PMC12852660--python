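"""Fit the implicit neural representation to a noisy phantom and score it.

A reduced network (n_p = 512 Fourier features, n_h = 256 hidden units) is
trained for 150 epochs directly against the measured signal through the
Standard Model forward operator — no labeled training data.  Pearson
correlations between the estimated and true kernel parameter maps quantify
recovery; at SNR 20 the network's spatial regularization yields markedly
smoother (and better-correlated) maps than voxel-wise fitting.
"""

import numpy as np

import sminr
from sminr.fitting import FitConfig, fit_inr

phantom = sminr.generate_phantom((12, 12, 12), lmax=2, seed=0)
protocol = sminr.optimized_protocol(seed=0)
clean = sminr.simulate_signals(phantom, protocol)
noisy, _ = sminr.add_noise(
    clean, protocol, sminr.NoiseSpec(kind="gaussian", snr=20, seed=1)
)
mask = sminr.VolumeGrid(data=phantom.mask.astype(float),
                        affine=phantom.grid.affine)

config = FitConfig(
    loss="mse", epochs=150, batch_size=500, lmax=2,
    n_p=512, n_h=256, seed=0,
    sigma2=1.0,          # encoding bandwidth matched to the 12^3 fixture
    learning_rate=3e-4,  # step size matched to the small fixture's budget
)
model, trace = fit_inr(noisy, protocol, mask, config)
print(f"mean loss: epoch 1 {trace[0]:.5f} -> epoch 150 {trace[-1]:.5f}")

coords = np.argwhere(phantom.mask).astype(float)
params, fod = sminr.predict(model, coords)
print("Pearson rho between estimate and ground truth:")
for name in ("f_i", "D_i", "De_par", "De_perp"):
    rho = sminr.pearson_rho(getattr(params, name),
                            getattr(phantom.kernel, name)[phantom.mask])
    print(f"  {name:8s} rho = {rho:.3f}")
p2 = sminr.p2_invariant(fod)
print(f"p2 (orientation coherence) over the mask: "
      f"mean {p2.mean():.3f}, max {p2.max():.3f}")
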