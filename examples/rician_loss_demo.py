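"""Why a Rician likelihood matters at low SNR.

Magnitude MRI noise is Rician: taking the magnitude of a complex signal
with Gaussian noise in both channels biases low-SNR measurements upward.
Minimizing MSE against such data recovers the (biased) Rician mean, while
minimizing the Rician negative log-likelihood recovers the true amplitude.
This script demonstrates both estimators on 100,000 draws.
"""

import numpy as np

from sminr.fitting import mse_loss, rician_nll_loss

rng = np.random.default_rng(0)
true_amplitude = 1.0
sigma = 0.25  # SNR 4 at this amplitude
n = 100_000
draws = np.sqrt(
    (true_amplitude + sigma * rng.standard_normal(n)) ** 2
    + (sigma * rng.standard_normal(n)) ** 2
)
print(f"sample mean of the Rician draws: {draws.mean():.4f} "
      f"(> true amplitude {true_amplitude})")

nus = np.linspace(0.7, 1.4, 701)
mse_curve = [mse_loss(draws, np.full(n, v)) for v in nus]
ric_curve = [rician_nll_loss(draws, np.full(n, v), np.full(n, sigma))
             for v in nus]
print(f"MSE-optimal amplitude:    {nus[int(np.argmin(mse_curve))]:.3f} "
      f"(biased upward)")
print(f"Rician-optimal amplitude: {nus[int(np.argmin(ric_curve))]:.3f} "
      f"(recovers the truth)")
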