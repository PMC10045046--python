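"""Denoise a noisy phantom with the Bayesian-threshold collaborative filter.

Adds sigma = 15 Gaussian noise to a clean phantom, runs the wavelet
BayesShrink + block-matching pipeline, and reports mean squared error and
the filtering-accuracy score (1/MSE * 100) before and after.
"""

import numpy as np

from lungcad import denoise as dn
from lungcad import phantoms

clean = phantoms.make_phantom(phantoms.PhantomSpec(seed=0, image_size=64)).image
noisy = phantoms.add_noise(clean, 15.0, seed=1)
out = dn.denoise_volume(noisy)

mse_noisy = np.mean((noisy - clean) ** 2)
mse_out = np.mean((out - clean) ** 2)
print(f"MSE vs clean:   noisy {mse_noisy:7.2f}   denoised {mse_out:7.2f}")
print(f"filtering accuracy: noisy {dn.filtering_accuracy(clean, noisy):.3f}%"
      f"   denoised {dn.filtering_accuracy(clean, out):.3f}%")

est = dn.estimate_threshold(dn.wavelet_decompose(noisy))
print(f"estimated noise sigma from finest subband: "
      f"{est['HH'].sigma_n:.2f} (true 15.0)")
print("\nThe filter removes most of the added noise energy; the MAD noise "
      "estimate tracks the injected sigma.")
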