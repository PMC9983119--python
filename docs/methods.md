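# Methods

## What the simulator emulates

The digital phantom is a single 128×128 slice (60 mm field of view,
0.469 mm pixels) of a 40 mm cylinder containing four 9 mm disk chambers,
centred 10 mm off-axis at 90° spacing. Chambers carry piecewise-constant
ground truth: extracellular volume fraction α ∈ {1, 0.6, 0.4, 0.2},
extracellular diffusivity d_e^w ∈ {2.82, 2.63, 2.39, 2.17} µm²/ms,
intracellular diffusivity d_i^w ∈ {0.02, 0.61, 0.69, 0.71} µm²/ms and
high-frequency conductivity σ_H ≈ 2 S/m (1.98/2.00/1.99/2.00) — the
chamber means measured in the benchtop experiment the package mirrors.
Rasterization uses the pixel-centre-in-disk rule; the oil bath between
chambers is a signal void and is never fitted.

Three forward models share one configuration and seed:

* **Diffusion.** Per voxel, the two-pool decay
  S(b) = S₀ [α e^(−b·d_e·u) + (1−α) e^(−b·d_i·u)], u = 10⁻³ for b in
  s/mm² and d in µm²/ms, sampled at the 13 b-values
  0–3500 s/mm². Noise is Rician: independent complex Gaussian
  channels of SD = mean(S(b=0))/SNR followed by the magnitude, applied
  over the whole field of view so the background shows the Rayleigh
  floor a fitter can estimate the noise level from. Default SNR 40.
* **Transceive phase.** The phase-based reconstruction identity
  σ_H = ∇²φ/(2 μ₀ ω) is inverted: φ solves the Poisson problem
  ∇²φ = 2 μ₀ ω σ_H(r) on the body disk with φ = 0 on its boundary
  (5-point finite differences, sparse direct solve, ω = 2π·400 MHz,
  σ = 0 in the oil). The full transceive phase carries the conductivity
  — no factor-of-two split — and that convention is recorded in the
  output manifest. Peak |φ| is ~1.3 rad, so no wrapping occurs.
* **Multi-echo stack.** Echo k has magnitude PD·e^(−TE_k/T2) with
  TE_k = k·15 ms, k = 1…6, PD = 1 inside chambers, and the same
  transceive phase at every echo; complex Gaussian noise per echo. T2 is
  a free simulator parameter with no reference value; 40 ms everywhere
  by default.
* **Benchtop.** Each chamber's 1 ml sample receives 200 µl of 0.5 M
  CuSO₄, which dilutes into the extracellular water ECW = α·1 ml, giving
  concentration C = 0.1/(ECW+0.2) M (volumes in ml). Absorbance follows
  the inverse of the calibration line; the default line
  (slope 0.3619 M per absorbance unit, intercept −0.0246 M) is the
  least-squares line through the three vesicle samples' published
  (absorbance, concentration) pairs, chosen because the experiment's own
  six standards' readings are not available; it maps the electrolyte
  blank's absorbance to ≈0 M, as observed.

What the generator does **not** emulate: multi-slice geometry, gradient
directions (the phantom is isotropic), eddy currents, geometric
distortion, registration error (all stages are born aligned),
susceptibility effects of the oil, coil sensitivity profiles, and any
frequency dependence between 10 Hz and 400 MHz. Passing tests therefore
demonstrate the correctness of the reconstruction arithmetic and its
noise behaviour, not robustness to those acquisition artifacts.

## σ_H reconstruction

Echo phases are combined as a weighted circular mean with weights
proportional to squared echo magnitude — the SNR-optimal weighting when
each echo carries independent complex Gaussian noise and a common phase.
Voxels with all-zero magnitude are dropped.

The Laplacian is a local quadratic (Savitzky–Golay) surface fit over a
(2r+1)² window, default r = 2 px: the kernel is exact for any phase
polynomial of total degree ≤ 2 and averages noise over the window. A
voxel is reconstructed only if its entire window lies inside the
validity mask (erosion, never extrapolation), and inputs are required to
be wrap-free in (−π, π]. Optional Gaussian pre-smoothing exists but is
off by default. Against the independent finite-difference forward
solver, a uniform 2 S/m disk comes back with an ROI mean within 0.3 %
and pointwise within 2 % once the ring influenced by the jagged discrete
boundary (~8 px) is excluded; chamber-ROI means in the default layout
are within ~0.1 %.

## Compartment fitting

Per voxel, bounded nonlinear least squares on the two-pool model with S₀
profiled out linearly, bounds α ∈ [0,1], diffusivities in
[0, 3.2] µm²/ms (just above free water at room temperature), the
ordering d_i ≤ d_e enforced by fitting d_i = f·d_e with f ∈ [0,1], and
three fixed starts (one from a segmented log-linear fit, two generic) so
results are deterministic. Ties and labeling: the reported solution
always satisfies d_e ≥ d_i, which resolves the (α, d_e, d_i) ↔
(1−α, d_i, d_e) swap symmetry.

Two method components matter at realistic noise:

* **Rician floor correction and denoising.** The magnitude bias at high
  b (where the signal approaches the noise floor) systematically
  inflates the fitted α by up to ~0.05 at SNR 40. `fit_volume` therefore
  works on Q = M² − 2σ̂² (unbiased for S² under Rician noise), with σ̂
  estimated from the signal-free background (E[M²] = 2σ² for pure
  noise), smoothed inside the mask by a normalized Gaussian (default
  1.5 px) that never mixes signal across the mask edge. Both steps are
  identity operations on noiseless data.
* **Mono/bi model selection.** A pure-electrolyte voxel is degenerate
  for the two-pool model: the intracellular pool has zero weight, so α
  and d_i trade off freely under noise and the voxel mean of α drifts
  far below 1. Each voxel is therefore also fitted mono-exponentially
  and the two-pool model must beat it under BIC (4 vs 2 parameters);
  otherwise the voxel reports α = 1 with the two-pool d_i retained but
  flagged unidentifiable.

Flags: `boundary` when an estimate sits within 10⁻³ of a bound,
`unidentifiable` when the intracellular signal (1−α)·S₀ is below the
noise floor or the curve shows no decay; flagged d_i voxels are excluded
from ROI d_i statistics. An exhaustive grid minimizer with documented
lexicographic tie-break (`oracle_grid_fit`) serves as an independent
cross-check in the tests; it is exact when the truth lies on the grid.
For off-grid truths the minimizing node can sit several spacings from
the continuous minimum along the model's diagonal RSS valley, which is a
property of the bi-exponential, not of either optimizer — the
equivalence tests therefore draw node-valued truths.

Accuracy at the default conditions (SNR 40): chamber-ROI mean α lands
within ±0.02 of the designed 1/0.6/0.4/0.2 (seed-dependent scatter
~±0.02); noiselessly within 10⁻³. The per-voxel Cramér–Rao bound for α
in the *raw* (uncorrected, unsmoothed) fit is ≈0.35 at α = 0.2, which is
why the preprocessing above is part of the method rather than an
optional nicety.

## CTI combination and statistics

c̄_e and σ_L are computed voxelwise by the formulas in the README, with
β = 1 by default (vesicle interior and exterior hold the same
electrolyte); β is a configurable scalar. c̄_e stays in the composite
unit S·ms/(m·µm²) — it is an *apparent* concentration and no conversion
to mol/L is attempted. Voxels with a non-positive denominator are
invalidated. Provable properties, all tested: 0 ≤ σ_L ≤ σ_H whenever
d_i ≤ d_e and β = 1; σ_L strictly increasing in α; σ_L → σ_H as α → 1
and → 0 as α → 0 with d_i > 0; σ_L ≡ α·c̄_e·d_e.

ROI statistics are the arithmetic mean and sample SD over a chamber mask
intersected with the eroded σ_H validity mask (interface pixels
excluded), NaN/flagged voxels dropped. Note that evaluating the σ_L
formula on *rounded published chamber means* does not reproduce the
published σ_L chamber values (it gives ≈1.76 vs 1.00 S/m for the
low-density chamber); the package documents this inconsistency in a test
and never treats those values as targets.

## Benchtop procedure

The calibration is ordinary least squares of molarity on absorbance —
the direction used for prediction — with r² reported; predictions clamp
at 0 M (blank behaviour). The mass balance
ECW = (0.5 M · 0.2 ml)/C − 0.2 ml is the unique dilution relation
consistent with all three published vesicle rows to printed precision;
C = 0 returns the full sample volume (no dilution detected), C above
the stock concentration raises. EVF = ECW / 1 ml, and the method
comparison reports 100·|EVF_bench − EVF_CTI|/EVF_bench with the benchtop
value as reference. Noise can push ECW marginally above the sample
volume; `analyze_samples` clips it there.

The optional single-shell Maxwell–Wagner model treats vesicles as
spheres (default radius 10 µm, membrane capacitance 10⁻² F/m²) whose
thin insulating shell acts as a series capacitance to the cytosol; the
classic mixture rule then gives the suspension conductivity at volume
fraction p = 1 − EVF. It exists as a forward model for
impedance-analyzer-style spectra and carries property tests only, no
numeric targets.

## Pipeline and numerics

One pydantic-validated config (unknown keys rejected) drives all stages;
every output directory holds NIfTI maps with the pixel spacing in the
header, an FSL-style b-value sidecar, CSV tables shaped like the study's
summary tables, and a JSON report carrying the seed and a config digest.
Runs are bit-reproducible from the seed (no timestamps in any output).
Problem sizes throughout are the native ones (128×128 slice, 13
b-values, 6 echoes); the orchestration tests use a 64×64 layout, which
exercises every code path with ~70 voxels per chamber.

Known limitations: single slice; isotropic conductivity only (no tensor
assembly from directional encoding); no phase unwrapping (out-of-range
inputs raise rather than unwrap); magnitude-domain fitting rather than a
full Rician likelihood; the σ_H map at SNR 40 with the default r = 2
kernel is noisy at the single-voxel level (SD of several S/m — second
derivatives amplify noise), so chamber statistics, not voxel values, are
the meaningful readout there.
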