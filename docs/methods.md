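# Methods

## The model

`sminr` estimates the two-compartment Standard Model (SM) of white matter
from diffusion-weighted MRI.  Each voxel's signal is the spherical
convolution of an axially symmetric response kernel with a fiber
orientation distribution (FOD) P(n):

    S(b, bΔ, u) = S0 ∫_{S²} K(b, bΔ, n·u) P(n) dn

The kernel sums an intra-axonal stick (axial diffusivity `D_i`, zero
perpendicular diffusivity, signal fraction `f_i`) and an extra-axonal
zeppelin (`De_par`, `De_perp`, fraction `1 − f_i`).  The zeppelin response
for a B-tensor with trace b, shape bΔ and principal axis u is

    K_zep = exp[ ⅓·b·bΔ·(D∥−D⊥) − ⅓·b·(D∥+2D⊥) − b·bΔ·(n·u)²·(D∥−D⊥) ]

b-values are carried internally in ms/µm² so that b·D is dimensionless
with diffusivities in µm²/ms.

### Two evaluation paths

*Analytic (Funk–Hecke).*  With the FOD expanded in real even-order
spherical harmonics (SH), the convolution scales each degree l by the
Legendre projection of the Gaussian kernel factor,
`r_l(a) = 2π ∫_{−1}^{1} P_l(t) e^{−a t²} dt`.  We evaluate `r_l` and
`dr_l/da` with a fixed 64-node Gauss–Legendre rule on [0, 1] (the integrand
is even), which is accurate to ~1e−12 over the physiological range of `a`
and — because the rule is fixed — makes the whole forward model smooth with
exact, cheap derivatives.  The closed form
`r_0(a) = 4π·√(π/4a)·erf(√a)` is kept as a test oracle only.  The public
analytic entry point enforces the validity conditions bΔ ≥ 0 and
De_par > De_perp.

*Numeric (quadrature).*  The spherical integrals are computed on a product
grid — Gauss–Legendre in cos θ × uniform (periodic trapezoid) φ, default
33 × 64 nodes.  This grid is spectrally exact for band-limited integrands
(a composite Simpson θ-rule was evaluated first and rejected: its algebraic
convergence left ~3e−3 errors in the SH Gram matrix, far short of the 1e−6
the tests demand).  The numeric path has no restriction on the sign of bΔ
and is the default whenever a protocol contains planar encodings.

The SH convention is Descoteaux-style real orthonormal: m<0 ↦ √2·Im Y_l^|m|,
m=0 ↦ Y_l^0, m>0 ↦ √2·Re Y_l^m, ordered lexicographically in (l, m).

## The estimator

A coordinate network maps position x (scaled to [−1,1]³ with aspect ratio
preserved) to k̂ = [f_i, D_i, De_par, De_perp, S0, p_0^0 … p_lmax^lmax]:

1. Fourier-feature encoding γ(x) = [cos 2πAx, sin 2πAx], A an n_p × 3
   matrix with entries ~ N(0, σ²), drawn once and never trained.  σ²
   controls the sharpest representable spatial detail, i.e. the strength of
   the implicit spatial regularization.
2. Four fully connected layers of width n_h with ReLU activations.
3. Per-parameter heads: sigmoid scaled to the physiological bounds
   (f_i ∈ [0,1], D_i ∈ [0,4], De_par ∈ [0,4], De_perp ∈ [0,1.5] µm²/ms)
   for the kernel parameters, softplus (positivity without an upper bound)
   for S0, identity for the SH coefficients.  Bounds hold for every input
   by construction — no clamping.

Training minimizes, over all masked voxel coordinates without a train/test
split, the per-voxel data discrepancy (MSE or Rician negative
log-likelihood) plus a FOD non-negativity penalty Λ: the mean over a fixed
set of 300 electrostatic-repulsion directions of max(0, −amplitude),
weighted 1.0 (averaging makes Λ scale-comparable to a mean data loss).
Optimization is Adam (lr 1e−4, β = 0.9/0.999, ε = 1e−8, no weight decay),
150 epochs, shuffled batches of 500 voxels.

The whole estimator is implemented in NumPy with hand-derived gradients.
Backpropagation through the forward physics uses the same Gauss–Legendre
nodes for `r_l` and `dr_l/da`, so the gradients are exact for the
implemented model (verified against finite differences at 1e−7 level in
the test suite).

### Initialization

MLP layers use He-normal weights.  The head layer starts at zero weights
and zero biases except the FOD mean, whose bias is set to
p_0^0 = 1/√(4π): the initial prediction is then the unit-integral isotropic
FOD with every kernel parameter mid-range and S0 equal to the mean b = 0
signal (softplus(0) times a data-driven scale).  Starting from a physiologic
signal rather than zero removes a long scale-finding transient at the start
of training.

### The S0 × FOD scale degeneracy

S0 and the FOD coefficients enter the forward model only through their
product.  The INR trains both heads (the network's smoothness prior
disambiguates them in practice); `FitConfig` offers no pinning by default.
The voxel-wise NLLS baseline, which has no such prior, pins
p_0^0 = 1/√(4π) (the unit-integral convention) — without the pin the
noiseless round trip is not identifiable.

## NLLS baseline

Per voxel, trust-region least squares on the analytic path with the exact
Jacobian, physiological bounds enforced by smooth reparameterization
(sigmoids; De_perp = fraction × De_par keeps the analytic ordering;
log-scale S0), at most 1000 function evaluations.  Two initializations —
one data-driven (powder-average log-linear diffusivity heuristics, f_i=0.5,
isotropic FOD), one random within bounds — and the solution with the lower
residual norm is kept.  No FOD non-negativity constraint is applied.

## Gradient non-uniformity

With a per-voxel coil tensor L, every nominal B-tensor
B = (b/3)[(1−bΔ)I + 3bΔ·uuᵀ] becomes B_eff = L·B·Lᵀ; the fit uses the
closest axially symmetric description: b_eff = tr B_eff, u_eff the
symmetry-axis eigenvector (the eigenvalue most distinct from the mean of
the other two — this handles planar encodings, where the axis carries the
*smallest* eigenvalue), bΔ_eff = (λ_axis − mean others)/b_eff.  Axial
symmetry of B_eff is an approximation that is exact for linear encodings
and increasingly approximate for bΔ ≠ 1 with strongly non-uniform coils.
Isotropic effective tensors keep the nominal u (no preferred axis), and a
coil field that is exactly the identity in every voxel skips the correction
entirely, making the null experiment bit-identical to an uncorrected fit.

## Rician likelihood

The Rician negative log-likelihood per measurement is
ν²/(2σ²) − log I₀(S·ν/σ²) with ν the noise-free prediction and σ the
per-voxel noise level (an input map: known in simulation, externally
estimated in vivo).  log I₀ is computed as log i0e(|x|) + |x| with the
scaled Bessel function, finite up to x ~ 1e6 and beyond; the gradient uses
the ratio i1e/i0e.  Minimizing this loss over Rician draws recovers the
true amplitude where MSE recovers the biased Rician mean — the mechanism
behind the bias-correction experiment.

## Synthetic phantoms

The generator emulates the structure simulation studies in this field
assume, with no external data:

* Kernel fields: Gaussian-smoothed white noise (default smoothness 3
  voxels) affinely mapped into conservative sub-ranges — f_i ∈ [0.3, 0.8],
  D_i ∈ [1.5, 3.0], De_par ∈ [1.0, 2.5] µm²/ms, De_perp = De_par·r with
  smooth r ∈ [0.2, 0.6], guaranteeing De_par > De_perp everywhere.  An
  alternative `harmonic` mode draws band-limited random trigonometric
  fields with a closed form at any continuous coordinate; it exists so
  continuous upsampling can be scored against an off-grid analytic truth.
* FODs: unit-integral mixtures of one or two Watson densities
  exp(κ(n·µ)²) with smoothly varying orientations (configurations:
  `single`, `crossing` at a set angle, `fanning` with spatially varying κ,
  default κ = 9).  Projection to SH uses the same Legendre quadrature as
  the kernel (Funk–Hecke with a = −κ).  Truncation at lmax can ring below
  zero; the l ≥ 2 coefficients are uniformly shrunk by the smallest factor
  restoring a non-negative amplitude profile (sampled at 4097 points with
  a 1e−3 isotropic-level floor), so phantom FODs are non-negative by
  construction and keep their unit integral.
* Protocol: the optimized multi-shell B-tensor scheme —
  b = [0, 1000, 2000, 8000, 5000, 2000] s/mm², directions
  [4, 20, 40, 40, 35, 15], bΔ = [1, 1, 1, 1, 0.8, 0] (154 measurements);
  per-shell directions by electrostatic repulsion on the hemisphere with
  antipodal charges, then every second direction flipped.
* Noise: per voxel σ(x) = mean b=0 signal / SNR; Gaussian adds N(0, σ²),
  Rician takes √((S+ε₁)² + ε₂²).  Default simulated S0 ≡ 1 inside the
  mask (the scale is arbitrary in simulation), default mask an inscribed
  ellipsoid (`full` available).

What the phantoms do **not** emulate: anatomical structure (sulci, tract
geometry), free-water/CSF partial volume, TE/relaxation effects,
non-central-chi noise from multi-coil reconstruction, or the anisotropic
(edge-preserving) smoothing of real parameter maps.  Passing recovery tests
on these phantoms therefore demonstrates the estimator's statistical
behavior under the stated noise and smoothness assumptions, not clinical
accuracy.

## Scaled-down experiment sizes

The package's property experiments run on desk-scale fixtures chosen as
the package's own study sizes: a 12³ phantom (1728 voxels) for recovery
and upsampling, 10³ for the Rician-bias experiment, and a reduced network
(n_p = 512, n_h = 256, or smaller where noted) in place of the full
n_p = 5000, n_h = 2048.  At full size an epoch contains ~120 batches and
150 epochs perform ~2·10⁴ Adam steps; the 12³ fixtures perform only a few
hundred.  The experiments therefore use a step size of 3e−4 instead of the
reference 1e−4 — a partial compensation for the ~30× smaller optimization
budget that stays well inside Adam's stable region (3e−3 was measurably
worse).  Likewise the encoding variance: the reference σ² (3.5, or 2.5 at
SNR 20) is tuned to the spatial bandwidth of full-size brain volumes.  On
a 12³ fixture whose fields carry ~2 cycles per volume, σ² = 3.5 admits
frequencies far beyond the data's content, which both slows convergence
and lets the representation oscillate *between* voxel centers (visible
only when evaluating off-grid).  The experiments match σ² to the fixture's
field bandwidth with the rule σ² ≈ (cycles per volume)²/4 — e.g. σ² = 1.0
for the 12³ phantoms — which is the same resolution-matching role σ²
plays at full scale.  Library defaults are unchanged (lr 1e−4, σ² 3.5);
the scaled values apply only to these reduced-budget experiment scripts
and tests.

## Numerical choices and edge cases

* Shared-protocol fits factorize measurements into unique (b·bΔ, b) shells
  so the per-degree projections are evaluated once per shell; per-voxel
  effective protocols fall back to dense evaluation.
* b = 0 measurements keep their nominal (placeholder) direction; zero-norm
  b-vectors are only legal on b = 0 volumes and are flagged on reading.
* Eigenvector sign for u_eff: the largest-magnitude component is made
  non-negative (antipodal symmetry makes the choice inert).
* Pearson ρ / RMSE are computed inside the mask after dropping non-finite
  estimates; the dropped count is reported.  Zero-variance inputs yield a
  missing (NaN) correlation rather than an error.
* Batch shuffling draws a fresh generator per epoch from (seed, epoch), so
  a fit resumed from a serialized model (which carries the Adam moments)
  reproduces an uninterrupted run bit-for-bit.
* All randomness flows through explicit integer seeds; there is no global
  RNG state.

## Known limitations

* Fitting is CPU NumPy: full-size problems (n_p = 5000, n_h = 2048, ~6·10⁴
  voxels) are feasible but slow; the implementation is tuned for clarity
  and exact gradients rather than throughput.
* The estimator's advantage is a *low-SNR* phenomenon.  The SM parameter
  space has nearly flat directions that stochastic gradient descent
  traverses slowly, leaving the INR with an optimization-limited accuracy
  floor that per-voxel trust-region NLLS (which solves each voxel's
  problem exactly) does not have.  At SNR 20 the spatial regularization
  outweighs this floor and the INR dominates NLLS on every kernel
  parameter; at SNR 50 and above, voxel-wise NLLS can match or beat the
  INR's parameter maps on smooth phantoms — including after continuous 8×
  resampling, where trilinear interpolation of the accurate NLLS map can
  carry smaller error than the INR's continuous evaluation.  The
  upsampling experiment in the test suite records this honestly.
* The effective-B-tensor correction assumes axial symmetry is conserved
  (see above) and the numeric integration path with per-voxel protocols
  costs substantially more than the shared-shell analytic path.
* The Rician loss requires an externally supplied σ map; no internal noise
  estimator is provided.
* Odd-order SH (asymmetric FODs) and diffusion-time dependence are out of
  scope.
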