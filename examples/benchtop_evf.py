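"""Spectrophotometric extracellular-volume-fraction arithmetic.

Takes the published absorbance readings of the four vesicle-suspension
samples, maps them through the CuSO4 calibration line, applies the dilution
mass balance, and prints the resulting extracellular volume fractions next
to the imaging-derived ones.
"""

import ctiphantom as cp
from ctiphantom.bench import CalibrationStandard
from ctiphantom.phantom import BenchSample

# (sample, absorbance at 650 nm) from the benchtop experiment, and the
# imaging-derived EVF each is compared against
READINGS = [("electrolyte", 0.068, 0.980), ("gvs1", 0.419, 0.634),
            ("gvs2", 0.526, 0.401), ("gvs3", 0.836, 0.176)]

# calibration line recovered from the three vesicle samples' printed
# (absorbance, concentration) pairs
curve = cp.fit_calibration([CalibrationStandard(0.127, 0.419),
                            CalibrationStandard(0.166, 0.526),
                            CalibrationStandard(0.278, 0.836)])
print(f"calibration: molarity = {curve.slope:.4f} * A {curve.intercept:+.4f}"
      f"  (r^2 = {curve.r_squared:.5f})")

samples = [BenchSample(cid, a) for cid, a, _ in READINGS]
results = cp.analyze_samples(curve, samples)
cti = [cp.ROIStats(cid, evf_cti, 0.0, 1) for cid, _, evf_cti in READINGS]
rows = cp.compare_evf(results, cti)

print(f"{'sample':<12}{'A650':>7}{'M (M)':>8}{'ECW (ul)':>10}"
      f"{'EVF':>7}{'EVF CTI':>9}{'err %':>7}")
for res, row in zip(results, rows):
    print(f"{res.sample_id:<12}{samples[results.index(res)].absorbance:>7.3f}"
          f"{res.molarity:>8.3f}{res.ecw:>10.1f}{res.evf:>7.3f}"
          f"{row['evf_cti']:>9.3f}{row['rel_error_pct']:>7.2f}")

print("\nEVF is the fraction of each 1 ml sample that is extracellular "
      "water: the added CuSO4 bolus only dilutes into that water, so the "
      "measured concentration encodes it exactly.")
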