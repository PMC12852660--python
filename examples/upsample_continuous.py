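"""Continuous upsampling: evaluate the fitted INR between voxel centers.

Because the representation is a continuous function of position, parameter
maps can be rendered at any resolution after fitting — no grid
interpolation involved, and no staircase artifacts on structures that cut
across the grid.  Here a model fit on an 8^3 phantom is evaluated at 4x
resolution and scored against the phantom's closed-form ground truth,
alongside trilinear interpolation of the model's own voxel-grid
prediction for reference.
"""

import numpy as np

import sminr
from sminr.fitting import FitConfig, fit_inr
from sminr.metrics import interpolate_map, rmse

phantom = sminr.generate_phantom((8, 8, 8), lmax=2, seed=2,
                                 field_mode="harmonic", mask_type="full")
protocol = sminr.optimized_protocol(seed=0)
clean = sminr.simulate_signals(phantom, protocol)
noisy, _ = sminr.add_noise(clean, protocol,
                           sminr.NoiseSpec(kind="gaussian", snr=50, seed=3))
mask = sminr.VolumeGrid(data=phantom.mask.astype(float),
                        affine=phantom.grid.affine)

config = FitConfig(loss="mse", epochs=150, batch_size=128, lmax=2,
                   n_p=256, n_h=128, seed=0,
                   sigma2=0.5,          # bandwidth matched to the 8^3 fixture
                   learning_rate=3e-4)
model, _ = fit_inr(noisy, protocol, mask, config)

factor = 4
maps = sminr.upsample(model, phantom.grid, factor=factor)
f_inr = maps.data[..., 0]

# trilinear interpolation of the grid-resolution INR prediction
params, _ = sminr.predict(
    model, np.argwhere(np.ones(phantom.mask.shape, bool)).astype(float))
f_grid = params.f_i.reshape(phantom.mask.shape)
f_lin = interpolate_map(f_grid, factor, "linear")

shape = f_inr.shape
g = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
coords = np.stack([(x.ravel() + 0.5) / factor - 0.5 for x in g], axis=-1)
truth = phantom.kernel_truth_at(coords)["f_i"].reshape(shape)
interior = np.zeros(shape, bool)
s = slice(factor, -factor)
interior[s, s, s] = True

print(f"f_i map at {factor}x resolution ({shape[0]}^3 voxels):")
print(f"  continuous INR evaluation RMSE vs truth: "
      f"{rmse(f_inr, truth, interior):.4f}")
print(f"  trilinear interpolation RMSE vs truth:   "
      f"{rmse(f_lin, truth, interior):.4f}")
print("both render the same fitted representation; the continuous "
      "evaluation needs no resampling step and stays artifact-free at "
      "any factor.")
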