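"""Simulate the four-chamber phantom's diffusion data and recover the
extracellular volume fraction per chamber.

Generates the 13-b-value diffusion series with Rician noise at SNR 40,
runs the two-compartment volume fit (Rician floor correction + masked
denoising + mono/bi model selection), and prints chamber-ROI statistics
against the designed fractions.
"""

import numpy as np

import ctiphantom as cp

layout = cp.PhantomLayout()
acq = cp.AcquisitionConfig(snr=40.0, rng_seed=1)
truth = cp.make_truth_maps(layout)
dwi = cp.simulate_dwi(truth, acq)
maps = cp.fit_volume(dwi)

print(f"{'chamber':<12}{'designed':>9}{'fitted mean':>12}{'SD':>7}{'n':>5}")
for cid, mask in truth.chamber_masks.items():
    designed = truth.alpha[mask].mean()
    st = cp.roi_stats(maps.alpha, mask, cid)
    print(f"{cid:<12}{designed:>9.2f}{st.mean:>12.3f}{st.sd:>7.3f}{st.count:>5}")

print("\nEach row is one 9 mm chamber: the fitted extracellular fraction "
      "tracks the designed vesicle density (denser suspension -> less "
      "extracellular water -> smaller fraction).")
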