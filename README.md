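# sminr — Standard Model fitting with implicit neural representations

`sminr` estimates the two-compartment **Standard Model (SM) of white
matter** from diffusion-weighted MRI by fitting an **implicit neural
representation (INR)**: a coordinate network that maps each spatial
position x to the SM kernel parameters and the fiber orientation
distribution (FOD), trained *self-supervised* — directly against the
measured signal through the SM forward operator, with no labeled training
data and no train/test split.  The sinusoidal encoding of the input
coordinates gives the estimate an inherent spatial regularization that
pays off at low SNR, and the fitted representation is continuous in space,
so parameter maps can be rendered at any resolution.

It is intended for researchers in diffusion MRI microstructure who want a
noise-robust, spatially coherent SM fit (or a reference implementation of
one) plus the standard scaffolding around it: the analytic and numeric SM
forward paths, a voxel-wise NLLS baseline, Rician-likelihood fitting,
per-voxel gradient-non-uniformity correction, a synthetic phantom
generator, and evaluation utilities.

## The model

The signal is the spherical convolution of an axially symmetric kernel
with the FOD P(n):

    S(b, bΔ, u) = S0 ∫_{S²} K(b, bΔ, n·u) P(n) dn

with an intra-axonal stick (fraction f_i, axial diffusivity D_i) and an
extra-axonal zeppelin (De∥, De⊥, fraction 1 − f_i):

    K_zep = exp[⅓·b·bΔ·(D∥−D⊥) − ⅓·b·(D∥+2D⊥) − b·bΔ·(n·u)²·(D∥−D⊥)]

Expanded in real even-order spherical harmonics, the convolution scales
each FOD degree l by the kernel's Legendre projection
r_l(a) = 2π∫P_l(t)e^{−at²}dt (Funk–Hecke), valid for bΔ ≥ 0 and
De∥ > De⊥; a spherical-quadrature path handles negative bΔ.  The network
is γ(x) = [cos 2πAx, sin 2πAx] (A ~ N(0, σ²), fixed) → four ReLU layers of
width n_h → per-parameter heads whose activations enforce the
physiological bounds f_i ∈ [0,1], D_i ∈ [0,4], De∥ ∈ [0,4],
De⊥ ∈ [0,1.5] µm²/ms by construction.  Training minimizes MSE or the
Rician negative log-likelihood plus a FOD non-negativity penalty with Adam.
Everything — network, backpropagation through the forward physics, and the
optimizer — is NumPy with exact hand-derived gradients.

See `docs/methods.md` for the full account (conventions, initialization,
degeneracies, phantom design, limitations).

## Worked example

`examples/fit_inr_phantom.py` generates a 12³ phantom with smooth SM
parameter fields, simulates the 154-measurement optimized multi-shell
B-tensor protocol (b = [0, 1, 2, 8, 5, 2] ms/µm², bΔ = [1, 1, 1, 1, 0.8, 0]),
adds Gaussian noise at SNR 20, fits a reduced INR (n_p = 512, n_h = 256,
150 epochs), and scores it against the ground truth:

```
$ python examples/fit_inr_phantom.py
mean loss: epoch 1 0.00584 -> epoch 150 0.00242
Pearson rho between estimate and ground truth:
  f_i      rho = 0.773
  D_i      rho = 0.720
  De_par   rho = 0.661
  De_perp  rho = 0.821
p2 (orientation coherence) over the mask: mean 0.371, max 0.417
```

The loss falls toward the noise floor (σ² = 0.0025 at SNR 20) and the
correlations quantify how well each kernel parameter map is recovered; on
the same data, voxel-wise NLLS reaches ρ ≈ 0.2–0.7 per parameter (the
acceptance experiments run that comparison).  The other scripts in
`examples/` each demonstrate one capability: phantom simulation, NLLS
identifiability on noiseless voxels, the Rician-vs-MSE estimator effect,
continuous upsampling, and effective protocols under gradient
non-uniformity.

## Command line

A thin CLI mirrors the library for shell pipelines:

```bash
sminr simulate --shape 16,16,16 --snr 20 --out phantom/
sminr fit --dwi phantom/dwi.nii.gz --bval phantom/bval --bvec phantom/bvec \
          --bdelta phantom/bdelta --mask phantom/mask.nii.gz \
          --lmax 2 --loss mse --out model.npz
sminr predict --model model.npz --ref phantom/dwi.nii.gz --factor 2 --out maps/
sminr nlls --dwi phantom/dwi.nii.gz --bval phantom/bval --bvec phantom/bvec \
           --bdelta phantom/bdelta --mask phantom/mask.nii.gz --out nlls_maps/
sminr evaluate --est-dir maps/ --truth-dir phantom/ \
               --mask phantom/mask.nii.gz --out report.json
```

Formats: NIfTI-1 volumes; FSL-style `bval`/`bvec` (b in s/mm², converted
internally to ms/µm²); `bdelta` is plain text, one B-tensor shape per
volume in bval order; the gradient-coil tensor is a 9-volume NIfTI
(L11, L12, L13, L21, …, L33); fitted models are single-file `.npz`
containers (JSON metadata + weight blobs).  SH coefficient volumes use the
real orthonormal basis ordered lexicographically in (l, m), m from −l to l.

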