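"""High-frequency conductivity from the transceive phase.

Forward-models the B1 transceive phase of a uniform 2 S/m disk by solving
the Poisson equation lap(phi) = 2 mu0 omega sigma, then reconstructs sigma_H
back with the Savitzky-Golay Laplacian kernel and reports the agreement.
"""

import numpy as np

import ctiphantom as cp

layout = cp.PhantomLayout()
truth = cp.make_truth_maps(layout)
truth.sigma_h = np.where(truth.body_mask, 2.0, np.nan)

acq = cp.AcquisitionConfig(noise_model="none")
phase = cp.simulate_transceive_phase(truth, acq, noiseless=True)
print(f"peak |phase| inside the 40 mm body: {np.abs(phase.phase).max():.3f} rad")

cm = cp.laplacian_sigma(phase, kernel_radius=2, pixel_size=layout.pixel_size)
mean = np.nanmean(cm.sigma[cm.mask])
print(f"reconstructed sigma_H over the eroded disk: "
      f"{mean:.4f} S/m (truth 2.0, error {abs(mean - 2) / 2 * 100:.2f} %)")

print("\nsigma_H = lap(phi) / (2 mu0 omega) at omega = 2 pi x 400 MHz; the "
      "generator solves the same physics with an independent 5-point "
      "finite-difference code, so the round trip checks both.")
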