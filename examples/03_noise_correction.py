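"""Why magnitude MRI needs a Rician bias correction at low SNR.

Magnitude images have Rician noise: the naive estimate SI/sigma
overestimates the true SNR, worst at low signal.  The Gudbjartsson-Patz
approximation SNR = sqrt(SI^2 - sigma_g^2)/sigma_g removes most of that
bias; sigma_g itself comes from a signal-free ROI via
sigma_g = sigma_m / sqrt(2 - pi/2).
"""

import numpy as np

from fluorox import estimate_noise

rng = np.random.default_rng(0)
sigma = 1.0
n = 200_000

print(f"{'true SNR':>9} {'naive bias':>11} {'corrected bias':>15}")
for true_snr in (1.5, 3.0, 5.0, 10.0):
    si = np.hypot(true_snr + rng.normal(0, sigma, n), rng.normal(0, sigma, n))
    naive = si.mean() - true_snr
    corrected = np.sqrt(np.maximum(si**2 - sigma**2, 0)).mean() - true_snr
    print(f"{true_snr:9.1f} {naive:11.3f} {corrected:15.3f}")

background = np.hypot(rng.normal(0, sigma, (50, 50, 8)),
                      rng.normal(0, sigma, (50, 50, 8)))
est = estimate_noise(background, np.ones_like(background, dtype=bool))
print(f"\nsigma_g estimated from a signal-free ROI: {est.sigma_g:.4f} "
      f"(truth {sigma}) from {est.n_voxels} voxels")
# The corrected estimator's bias is an order of magnitude smaller wherever
# SNR >= 3 — exactly the regime of the short-TR T1-weighted images.
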