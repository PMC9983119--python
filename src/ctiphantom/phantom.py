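"""Digital giant-vesicle-suspension (GVS) phantom generator.

Builds a single-slice cylindrical phantom containing disk chambers of
vesicle suspension at different densities, and simulates the three data
streams a conductivity-tensor-imaging (CTI) experiment acquires from it:

* a multi-b-value diffusion-weighted stack following a two-compartment
  (bi-exponential) decay,
* a multi-echo spin-echo complex stack whose transceive phase is consistent
  with a prescribed high-frequency conductivity map (Poisson forward model),
* benchtop spectrophotometric absorbance samples following a linear
  Beer-Lambert calibration and a CuSO4 dilution mass balance.

The oil bath surrounding the chambers is treated as a signal void: the
chamber disks are the only voxels carrying MR signal, while the transceive
phase itself is defined on the whole phantom body.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

MU0 = 4e-7 * np.pi  # vacuum permeability, H/m
LARMOR_HZ = 400e6   # proton Larmor frequency at 9.4 T

#: diffusion-weighting strengths (s/mm^2) of the reference acquisition
DEFAULT_B_VALUES = (0, 50, 150, 300, 500, 700, 1000, 1400, 1800,
                    2200, 2600, 3000, 3500)

#: b (s/mm^2) times d (um^2/ms) carries a factor 1e-3 to become dimensionless
B_D_UNIT = 1e-3


class GeometryError(ValueError):
    """Chamber layout violates containment or disjointness."""


class ConfigError(ValueError):
    """Acquisition or simulation configuration is invalid."""


@dataclass(frozen=True)
class ChamberSpec:
    """One chamber disk with its ground-truth tissue parameters.

    Parameters
    ----------
    chamber_id : str
        Label, e.g. ``"electrolyte"`` or ``"gvs1"``.
    center_xy : (float, float)
        Chamber centre in mm, origin at the phantom centre.
    diameter : float
        Chamber diameter in mm.
    alpha_true : float
        Extracellular volume fraction in [0, 1].
    d_e_true, d_i_true : float
        Extracellular / intracellular water diffusion coefficients, um^2/ms.
    sigma_h_true : float
        High-frequency conductivity, S/m.
    beta : float
        Intra/extracellular ion concentration ratio (1 for vesicles).
    t2 : float
        Transverse relaxation time, ms (free simulator parameter).
    """

    chamber_id: str
    center_xy: tuple[float, float]
    diameter: float
    alpha_true: float
    d_e_true: float
    d_i_true: float
    sigma_h_true: float
    beta: float = 1.0
    t2: float = 40.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_true <= 1.0:
            raise GeometryError(f"alpha_true must be in [0,1]: {self.alpha_true}")
        if not 0.0 <= self.d_i_true <= self.d_e_true:
            raise GeometryError("require 0 <= d_i_true <= d_e_true")
        if self.sigma_h_true <= 0:
            raise GeometryError("sigma_h_true must be positive")
        if self.diameter <= 0:
            raise GeometryError("diameter must be positive")
        if self.beta <= 0:
            raise GeometryError("beta must be positive")


def default_chambers() -> list[ChamberSpec]:
    """The four-chamber reference layout.

    Designed extracellular fractions 1 / 0.6 / 0.4 / 0.2; diffusivities are
    the measured chamber means of the reference experiment; sigma_H is
    essentially 2 S/m everywhere (the NaCl electrolyte is common to all
    chambers, so high-frequency conductivity does not discriminate density).
    """
    r = 10.0  # chamber centres 10 mm off-axis
    return [
        ChamberSpec("electrolyte", (-r, 0.0), 9.0, 1.0, 2.82, 0.02, 1.98),
        ChamberSpec("gvs1", (0.0, r), 9.0, 0.6, 2.63, 0.61, 2.00),
        ChamberSpec("gvs2", (r, 0.0), 9.0, 0.4, 2.39, 0.69, 1.99),
        ChamberSpec("gvs3", (0.0, -r), 9.0, 0.2, 2.17, 0.71, 2.00),
    ]


@dataclass(frozen=True)
class PhantomLayout:
    """Geometry of the phantom slice.

    Default grid is 128 px over a 60 mm field of view (0.469 mm pixels)
    with a 40 mm body disk.
    """

    grid_size: int = 128
    fov: float = 60.0
    body_diameter: float = 40.0
    chambers: tuple[ChamberSpec, ...] = field(
        default_factory=lambda: tuple(default_chambers()))
    background_value: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "chambers", tuple(self.chambers))
        body_r = self.body_diameter / 2.0
        for c in self.chambers:
            cx, cy = c.center_xy
            if np.hypot(cx, cy) + c.diameter / 2.0 >= body_r:
                raise GeometryError(
                    f"chamber {c.chamber_id!r} not strictly inside the body disk")
        for i, a in enumerate(self.chambers):
            for b in self.chambers[i + 1:]:
                d = np.hypot(a.center_xy[0] - b.center_xy[0],
                             a.center_xy[1] - b.center_xy[1])
                if d <= (a.diameter + b.diameter) / 2.0:
                    raise GeometryError(
                        f"chambers {a.chamber_id!r} and {b.chamber_id!r} overlap")

    @property
    def pixel_size(self) -> float:
        """Pixel edge length in mm."""
        return self.fov / self.grid_size

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate rasters (mm) of pixel centres, origin central."""
        n, px = self.grid_size, self.pixel_size
        coords = (np.arange(n) + 0.5) * px - self.fov / 2.0
        return np.meshgrid(coords, coords, indexing="xy")


@dataclass(frozen=True)
class AcquisitionConfig:
    """Simulated acquisition settings shared by the DWI and MEMS streams."""

    b_values: tuple[float, ...] = DEFAULT_B_VALUES
    n_echoes: int = 6
    echo_spacing: float = 15.0          # ms; TE_k = k * echo_spacing
    snr: float = 40.0                   # at b=0 / first echo over signal mask
    noise_model: str = "rician"         # "rician" | "gaussian" | "none"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        if b.size < 1 or b[0] != 0 or np.any(np.diff(b) <= 0):
            raise ConfigError("b_values must start at 0 and increase strictly")
        if self.n_echoes < 1:
            raise ConfigError("n_echoes must be >= 1")
        if self.snr <= 0:
            raise ConfigError("snr must be positive")
        if self.noise_model not in ("rician", "gaussian", "none"):
            raise ConfigError(f"unknown noise_model {self.noise_model!r}")


@dataclass
class TruthMaps:
    """Piecewise-constant ground-truth parameter rasters.

    Background (oil / outside body) is invalid: NaN in the parameter maps,
    excluded from ``signal_mask``.
    """

    label: np.ndarray           # int raster: -1 outside body, 0 body/oil, 1.. chambers
    body_mask: np.ndarray
    chamber_masks: dict[str, np.ndarray]
    alpha: np.ndarray
    d_e: np.ndarray
    d_i: np.ndarray
    sigma_h: np.ndarray
    beta: np.ndarray
    t2: np.ndarray
    pixel_size: float

    @property
    def signal_mask(self) -> np.ndarray:
        """Union of chamber disks — the voxels carrying MR signal."""
        m = np.zeros_like(self.body_mask)
        for cm in self.chamber_masks.values():
            m |= cm
        return m


def rasterize_layout(layout: PhantomLayout) -> tuple[np.ndarray, np.ndarray,
                                                     dict[str, np.ndarray]]:
    """Rasterize the layout to a label map and per-region masks.

    A pixel belongs to a disk iff its centre lies inside the disk; chambers
    are strictly inside the body and pairwise disjoint, so the innermost
    containing disk is unambiguous.

    Returns
    -------
    label : int ndarray
        -1 outside the body, 0 in the body (oil), k >= 1 in chamber k.
    body_mask : bool ndarray
    chamber_masks : dict of chamber_id -> bool ndarray
    """
    x, y = layout.pixel_centers()
    body_r = layout.body_diameter / 2.0
    body_mask = x**2 + y**2 < body_r**2
    label = np.where(body_mask, 0, -1).astype(np.int16)
    chamber_masks: dict[str, np.ndarray] = {}
    for k, c in enumerate(layout.chambers, start=1):
        cx, cy = c.center_xy
        m = (x - cx) ** 2 + (y - cy) ** 2 < (c.diameter / 2.0) ** 2
        label[m] = k
        chamber_masks[c.chamber_id] = m
    return label, body_mask, chamber_masks


def make_truth_maps(layout: PhantomLayout) -> TruthMaps:
    """Paint per-chamber ground-truth values onto the raster grid."""
    label, body_mask, chamber_masks = rasterize_layout(layout)
    shape = label.shape
    nan = np.full(shape, np.nan)
    alpha, d_e, d_i = nan.copy(), nan.copy(), nan.copy()
    sigma_h, beta, t2 = nan.copy(), nan.copy(), nan.copy()
    for c in layout.chambers:
        m = chamber_masks[c.chamber_id]
        alpha[m] = c.alpha_true
        d_e[m] = c.d_e_true
        d_i[m] = c.d_i_true
        sigma_h[m] = c.sigma_h_true
        beta[m] = c.beta
        t2[m] = c.t2
    return TruthMaps(label, body_mask, chamber_masks, alpha, d_e, d_i,
                     sigma_h, beta, t2, layout.pixel_size)


def compartment_signal(b: np.ndarray, alpha: np.ndarray, d_e: np.ndarray,
                       d_i: np.ndarray, s0: float | np.ndarray = 1.0) -> np.ndarray:
    """Two-compartment decay S(b) = S0 [a e^{-b de u} + (1-a) e^{-b di u}].

    ``b`` in s/mm^2, diffusivities in um^2/ms; the 1e-3 unit factor is
    applied internally. Broadcasts b against the parameter rasters.
    """
    b = np.asarray(b, dtype=float)
    bu = b * B_D_UNIT
    return s0 * (alpha * np.exp(-bu * d_e) + (1.0 - alpha) * np.exp(-bu * d_i))


def simulate_dwi(truth: TruthMaps, acq: AcquisitionConfig,
                 s0: float = 1.0) -> "DWIStack":
    """Simulate the multi-b-value DWI stack over the signal mask.

    Noise: per ``acq.noise_model``, with per-channel SD set so that the mean
    b=0 signal over the mask divided by the SD equals ``acq.snr``. Rician
    noise is the magnitude of the complex Gaussian-corrupted signal.
    """
    from .compartments import DWIStack  # container lives with the fitter

    mask = truth.signal_mask
    b = np.asarray(acq.b_values, dtype=float)
    vols = np.zeros((b.size,) + mask.shape)
    a = np.where(mask, truth.alpha, 0.0)
    de = np.where(mask, truth.d_e, 0.0)
    di = np.where(mask, truth.d_i, 0.0)
    for j, bj in enumerate(b):
        vols[j] = np.where(mask, compartment_signal(bj, a, de, di, s0), 0.0)

    if acq.noise_model != "none":
        # noise covers the whole FOV: the signal-free background then shows
        # the Rayleigh floor a fitter can estimate the noise level from
        rng = np.random.default_rng(acq.rng_seed)
        sd = float(np.mean(vols[0][mask])) / acq.snr
        if acq.noise_model == "rician":
            re = vols + rng.normal(0.0, sd, vols.shape)
            im = rng.normal(0.0, sd, vols.shape)
            vols = np.hypot(re, im)
        else:
            vols = vols + rng.normal(0.0, sd, vols.shape)
    return DWIStack(b_values=b, signal=vols, mask=mask)


def _poisson_solve_disk(rhs: np.ndarray, mask: np.ndarray, h_m: float) -> np.ndarray:
    """Solve lap(phi) = rhs on ``mask`` with phi = 0 outside (Dirichlet).

    5-point finite differences at spacing ``h_m`` (metres); sparse direct
    solve. Returns phi (zero outside the mask).
    """
    idx = -np.ones(mask.shape, dtype=np.int64)
    ii, jj = np.nonzero(mask)
    n = ii.size
    idx[ii, jj] = np.arange(n)
    rows, cols, vals = [], [], []
    inv_h2 = 1.0 / h_m**2
    for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        ni, nj = ii + di, jj + dj
        inside = (ni >= 0) & (ni < mask.shape[0]) & (nj >= 0) & (nj < mask.shape[1])
        nbr = np.where(inside, idx[ni % mask.shape[0], nj % mask.shape[1]], -1)
        has = nbr >= 0
        rows.append(np.arange(n)[has])
        cols.append(nbr[has])
        vals.append(np.full(has.sum(), inv_h2))
        # neighbours outside the mask contribute phi=0: nothing to add
    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(np.full(n, -4.0 * inv_h2))
    A = sp.csr_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))), shape=(n, n))
    sol = spla.spsolve(A, rhs[ii, jj])
    phi = np.zeros(mask.shape)
    phi[ii, jj] = sol
    return phi


@dataclass
class PhaseMap:
    """Transceive phase raster (radians) with its validity mask."""

    phase: np.ndarray
    mask: np.ndarray
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.phase[self.mask])):
            raise ValueError("phase must be finite inside the mask")


def simulate_transceive_phase(truth: TruthMaps, acq: AcquisitionConfig,
                              frequency_hz: float = LARMOR_HZ,
                              noiseless: bool = False) -> PhaseMap:
    """Forward-model the B1 transceive phase from the conductivity map.

    Solves the Poisson problem lap(phi) = 2 mu0 omega sigma_H(r) on the body
    disk with phi = 0 on the boundary, at pixel resolution. Conductivity is
    zero where the truth map is invalid (the oil bath). Gaussian phase noise
    of SD 1/snr is added unless ``noiseless``.
    """
    if not truth.body_mask.any():
        raise GeometryError("empty body mask")
    omega = 2.0 * np.pi * frequency_hz
    sigma = np.where(np.isfinite(truth.sigma_h), truth.sigma_h, 0.0)
    rhs = 2.0 * MU0 * omega * sigma
    h_m = truth.pixel_size * 1e-3
    phi = _poisson_solve_disk(rhs, truth.body_mask, h_m)
    noise_sd = 0.0
    if not noiseless and acq.noise_model != "none":
        rng = np.random.default_rng(acq.rng_seed + 1)
        noise_sd = 1.0 / acq.snr
        phi = phi + np.where(truth.body_mask,
                             rng.normal(0.0, noise_sd, phi.shape), 0.0)
    return PhaseMap(phase=phi, mask=truth.body_mask.copy(), noise_sd=noise_sd)


def simulate_mems(truth: TruthMaps, phase: PhaseMap,
                  acq: AcquisitionConfig) -> "MultiEchoStack":
    """Simulate the multi-echo spin-echo complex stack.

    Echo k (1-based) magnitude is PD exp(-TE_k / T2) with TE_k = k *
    echo_spacing; proton density PD = 1 in the chambers and 0 in the oil.
    The transceive phase is identical across echoes. Independent complex
    Gaussian noise per echo, SD = (mean first-echo magnitude)/snr.
    """
    from .ephase import MultiEchoStack

    mask = truth.signal_mask
    pd = mask.astype(float)
    t2 = np.where(mask, truth.t2, np.inf)
    te = acq.echo_spacing * np.arange(1, acq.n_echoes + 1)
    echoes = np.zeros((acq.n_echoes,) + mask.shape, dtype=complex)
    for k, tek in enumerate(te):
        mag = pd * np.exp(-tek / t2)
        echoes[k] = mag * np.exp(1j * phase.phase)
    if acq.noise_model != "none":
        rng = np.random.default_rng(acq.rng_seed + 2)
        sd = float(np.mean(np.abs(echoes[0])[mask])) / acq.snr
        noise = rng.normal(0.0, sd, echoes.shape) + \
            1j * rng.normal(0.0, sd, echoes.shape)
        echoes = echoes + noise
        echoes[:, ~mask] = 0.0
    return MultiEchoStack(echoes=echoes, te_list=te, pixel_size=truth.pixel_size)


# ---------------------------------------------------------------------------
# benchtop sample generator

#: benchtop dilution constants: 1 ml GVS sample, 200 ul of 0.5 M CuSO4 added
V_SAMPLE_ML = 1.0
V_ADDED_ML = 0.2
C_ADDED_M = 0.5

#: default Beer-Lambert line (molarity = slope * absorbance + intercept),
#: the least-squares line through the reference experiment's printed
#: (absorbance, molarity) pairs
DEFAULT_CALIB_SLOPE = 0.3619318
DEFAULT_CALIB_INTERCEPT = -0.0245805


@dataclass(frozen=True)
class BenchSample:
    """One spectrophotometer reading of the extracted extracellular water."""

    sample_id: str
    absorbance: float
    v_sample: float = V_SAMPLE_ML   # ml
    v_added: float = V_ADDED_ML     # ml
    c_added: float = C_ADDED_M      # M

    def __post_init__(self) -> None:
        if self.v_sample <= 0 or self.v_added <= 0:
            raise ConfigError("sample volumes must be positive")
        if self.absorbance < 0:
            raise ConfigError("absorbance must be non-negative")


def bench_concentration_true(alpha: float, v_sample: float = V_SAMPLE_ML,
                             v_added: float = V_ADDED_ML,
                             c_added: float = C_ADDED_M) -> float:
    """CuSO4 concentration after the added stock dilutes into the ECW.

    ECW = alpha * v_sample; the added n = c_added * v_added moles distribute
    over ECW + v_added, so C = n / (ECW + v_added).
    """
    ecw = alpha * v_sample
    return c_added * v_added / (ecw + v_added)


def simulate_bench_samples(layout: PhantomLayout,
                           calib_slope: float = DEFAULT_CALIB_SLOPE,
                           calib_intercept: float = DEFAULT_CALIB_INTERCEPT,
                           seed: int | None = None,
                           absorbance_noise_sd: float = 0.0,
                           ) -> tuple[list[BenchSample], list[tuple[float, float]]]:
    """Generate spectrophotometer readings for each chamber's suspension.

    For each chamber the true extracellular water is alpha * 1 ml; the
    resulting CuSO4 concentration maps to absorbance through the inverse of
    the calibration line ``molarity = slope * A + intercept``. Optional
    Gaussian absorbance noise.

    Returns the samples plus six noiseless calibration standards with
    molarities evenly spaced on [0, 0.5] M.
    """
    if calib_slope == 0:
        raise ConfigError("calibration slope must be nonzero")
    rng = np.random.default_rng(seed)
    samples = []
    for c in layout.chambers:
        conc = bench_concentration_true(c.alpha_true)
        a = (conc - calib_intercept) / calib_slope
        if absorbance_noise_sd > 0:
            a += rng.normal(0.0, absorbance_noise_sd)
        samples.append(BenchSample(c.chamber_id, max(a, 0.0)))
    standards = [(m, (m - calib_intercept) / calib_slope)
                 for m in np.linspace(0.0, C_ADDED_M, 6)]
    return samples, standards


@dataclass
class SyntheticDataset:
    """One complete simulated study: truth, DWI, MEMS, masks, manifest."""

    truth: TruthMaps
    dwi: object            # compartments.DWIStack
    mems: object           # ephase.MultiEchoStack
    phase_true: PhaseMap
    bench_samples: list[BenchSample]
    bench_standards: list[tuple[float, float]]
    manifest: dict


def simulate_dataset(layout: PhantomLayout | None = None,
                     acq: AcquisitionConfig | None = None) -> SyntheticDataset:
    """Run every forward model with one shared configuration and seed."""
    layout = layout or PhantomLayout()
    acq = acq or AcquisitionConfig()
    truth = make_truth_maps(layout)
    dwi = simulate_dwi(truth, acq)
    phase = simulate_transceive_phase(truth, acq)
    mems = simulate_mems(truth, phase, acq)
    samples, standards = simulate_bench_samples(layout, seed=acq.rng_seed + 3)
    manifest = {
        "layout": {"grid_size": layout.grid_size, "fov": layout.fov,
                   "body_diameter": layout.body_diameter,
                   "chambers": [asdict(c) for c in layout.chambers]},
        "acquisition": asdict(acq),
        "units": {"b": "s/mm^2", "d": "um^2/ms", "sigma": "S/m",
                  "phase": "rad", "te": "ms", "pixel": "mm"},
        "phase_convention": "full transceive phase; lap(phi) = 2*mu0*omega*sigma",
    }
    return SyntheticDataset(truth, dwi, mems, phase, samples, standards, manifest)
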