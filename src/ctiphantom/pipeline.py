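"""End-to-end orchestration: simulate -> reconstruct -> fit -> combine -> bench.

One ``RunConfig`` (YAML-serializable, schema-validated, unknown keys
rejected) drives every stage; all stage outputs land in one directory tree
as NIfTI maps, text sidecars and CSV/JSON reports, and every run is
reproducible bit-for-bit from its seed. Stages can be run individually
(each reloads what it needs from the directory) or together via
``run_all``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import bench as bench_mod
from . import io
from .compartments import (DWIStack, FLAG_UNIDENTIFIABLE, fit_volume)
from .cti import ROIStats, ion_concentration, relative_error, roi_stats, sigma_low
from .ephase import MultiEchoStack, combine_echo_phase, laplacian_sigma
from .phantom import (DEFAULT_CALIB_INTERCEPT, DEFAULT_CALIB_SLOPE,
                      AcquisitionConfig, ChamberSpec, PhantomLayout,
                      default_chambers, make_truth_maps, simulate_bench_samples,
                      simulate_dwi, simulate_mems, simulate_transceive_phase)


class ChamberConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    chamber_id: str
    center_xy: tuple[float, float]
    diameter: float = 9.0
    alpha_true: float
    d_e_true: float
    d_i_true: float
    sigma_h_true: float = 2.0
    beta: float = 1.0
    t2: float = 40.0


class LayoutConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    grid_size: int = 128
    fov: float = 60.0
    body_diameter: float = 40.0
    chambers: Optional[list[ChamberConfig]] = None   # None -> reference layout


class AcqConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    b_values: Optional[list[float]] = None           # None -> 13 defaults
    n_echoes: int = 6
    echo_spacing: float = 15.0
    snr: float = 40.0
    noise_model: Literal["rician", "gaussian", "none"] = "rician"


class ReconConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kernel_radius: int = 2
    presmooth_sigma: float = 0.0
    frequency_hz: float = 400e6


class FitConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    noise_floor: float = 0.0
    noise_sd: Optional[float] = None     # None -> Rayleigh-background estimate
    smooth_sigma: float = 1.5            # px; masked pre-fit denoising


class BenchConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    calib_slope: float = DEFAULT_CALIB_SLOPE
    calib_intercept: float = DEFAULT_CALIB_INTERCEPT
    absorbance_noise_sd: float = 0.0


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    layout: LayoutConfig = Field(default_factory=LayoutConfig)
    acquisition: AcqConfig = Field(default_factory=AcqConfig)
    recon: ReconConfig = Field(default_factory=ReconConfig)
    fit: FitConfig = Field(default_factory=FitConfig)
    bench: BenchConfig = Field(default_factory=BenchConfig)

    def to_layout(self) -> PhantomLayout:
        if self.layout.chambers is None:
            chambers = default_chambers()
        else:
            chambers = [ChamberSpec(**c.model_dump()) for c in self.layout.chambers]
        return PhantomLayout(self.layout.grid_size, self.layout.fov,
                             self.layout.body_diameter, tuple(chambers))

    def to_acq(self) -> AcquisitionConfig:
        b = self.acquisition.b_values
        kwargs = {} if b is None else {"b_values": tuple(b)}
        return AcquisitionConfig(n_echoes=self.acquisition.n_echoes,
                                 echo_spacing=self.acquisition.echo_spacing,
                                 snr=self.acquisition.snr,
                                 noise_model=self.acquisition.noise_model,
                                 rng_seed=self.seed, **kwargs)

    def digest(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    import yaml
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


# ---------------------------------------------------------------------------
# stages

def stage_simulate(cfg: RunConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    layout = cfg.to_layout()
    acq = cfg.to_acq()
    truth = make_truth_maps(layout)
    px = layout.pixel_size
    for name in ("alpha", "d_e", "d_i", "sigma_h"):
        io.write_map(out / f"truth_{name}.nii", getattr(truth, name), px)
    io.write_map(out / "label.nii", truth.label.astype(float), px)
    io.write_map(out / "mask_body.nii", truth.body_mask.astype(float), px)
    io.write_map(out / "mask_signal.nii", truth.signal_mask.astype(float), px)
    for cid, m in truth.chamber_masks.items():
        io.write_map(out / f"mask_chamber_{cid}.nii", m.astype(float), px)

    dwi = simulate_dwi(truth, acq)
    io.write_map(out / "dwi.nii", dwi.signal, px)
    io.write_bvals(out / "dwi.bval", dwi.b_values)

    phase = simulate_transceive_phase(truth, acq, cfg.recon.frequency_hz)
    io.write_map(out / "phase_true.nii", phase.phase, px)
    mems = simulate_mems(truth, phase, acq)
    io.write_map(out / "mems_real.nii", mems.echoes.real, px)
    io.write_map(out / "mems_imag.nii", mems.echoes.imag, px)
    io.write_json(out / "mems_te.json", {"te_ms": list(mems.te_list)})

    samples, standards = simulate_bench_samples(
        layout, cfg.bench.calib_slope, cfg.bench.calib_intercept,
        seed=cfg.seed + 3, absorbance_noise_sd=cfg.bench.absorbance_noise_sd)
    pd.DataFrame([{"sample_id": s.sample_id, "absorbance": s.absorbance,
                   "v_sample_ml": s.v_sample, "v_added_ml": s.v_added,
                   "c_added_M": s.c_added} for s in samples]
                 ).to_csv(out / "bench_samples.csv", index=False)
    pd.DataFrame(standards, columns=["molarity_M", "absorbance"]
                 ).to_csv(out / "bench_standards.csv", index=False)

    io.write_json(out / "manifest.json", {
        "config": cfg.model_dump(), "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "chamber_ids": [c.chamber_id for c in layout.chambers],
        "units": {"b": "s/mm^2", "d": "um^2/ms", "sigma": "S/m",
                  "phase": "rad", "te": "ms", "pixel": "mm"},
        "phase_convention": "full transceive; lap(phi)=2*mu0*omega*sigma",
    })


def stage_recon(cfg: RunConfig, out: Path) -> None:
    real, px = io.read_map(out / "mems_real.nii")
    imag, _ = io.read_map(out / "mems_imag.nii")
    te = io.read_json(out / "mems_te.json")["te_ms"]
    mems = MultiEchoStack(real + 1j * imag, np.asarray(te), px)
    phase = combine_echo_phase(mems)
    cmap = laplacian_sigma(phase, kernel_radius=cfg.recon.kernel_radius,
                           pixel_size=px, frequency_hz=cfg.recon.frequency_hz,
                           presmooth_sigma=cfg.recon.presmooth_sigma)
    io.write_map(out / "sigma_h.nii", cmap.sigma, px)
    io.write_map(out / "mask_sigma_h.nii", cmap.mask.astype(float), px)
    io.write_json(out / "recon_report.json", {
        "kernel_radius_px": cmap.kernel_radius, "omega_rad_s": cmap.omega,
        "erosion": "square window fully inside mask",
    })


def stage_fit(cfg: RunConfig, out: Path) -> None:
    signal, px = io.read_map(out / "dwi.nii")
    b = io.read_bvals(out / "dwi.bval")
    mask_arr, _ = io.read_map(out / "mask_signal.nii")
    io.check_same_grid(signal, mask_arr, "dwi.nii", "mask_signal.nii")
    dwi = DWIStack(b, signal, mask_arr > 0.5)
    maps = fit_volume(dwi, noise_floor=cfg.fit.noise_floor,
                      noise_sd=cfg.fit.noise_sd,
                      smooth_sigma=cfg.fit.smooth_sigma)
    for name in ("alpha", "d_e", "d_i", "s0", "rss"):
        io.write_map(out / f"fit_{name}.nii", getattr(maps, name), px)
    io.write_map(out / "fit_flags.nii", maps.flags.astype(float), px)


def stage_cti(cfg: RunConfig, out: Path) -> None:
    sigma_h, px = io.read_map(out / "sigma_h.nii")
    alpha, _ = io.read_map(out / "fit_alpha.nii")
    d_e, _ = io.read_map(out / "fit_d_e.nii")
    d_i, _ = io.read_map(out / "fit_d_i.nii")
    io.check_same_grid(sigma_h, alpha, "sigma_h.nii", "fit_alpha.nii")
    beta = _beta_of(cfg)
    c_e = ion_concentration(sigma_h, alpha, d_e, d_i, beta)
    s_l = sigma_low(alpha, sigma_h, d_e, d_i, beta)
    io.write_map(out / "c_e_bar.nii", c_e, px)
    io.write_map(out / "sigma_l.nii", s_l, px)


def _beta_of(cfg: RunConfig) -> float:
    chambers = cfg.layout.chambers
    if chambers:
        return chambers[0].beta
    return 1.0


def chamber_roi_tables(cfg: RunConfig, out: Path) -> pd.DataFrame:
    """Per-chamber mean +/- SD of every CTI parameter (reference-table shape).

    ROIs are the chamber masks intersected with the eroded sigma_H validity
    mask (interface voxels excluded); d_i statistics additionally exclude
    voxels where the intracellular pool was flagged unidentifiable.
    """
    manifest = io.read_json(out / "manifest.json")
    sig_mask, _ = io.read_map(out / "mask_sigma_h.nii")
    flags, _ = io.read_map(out / "fit_flags.nii")
    maps = {name: io.read_map(out / f"{fname}.nii")[0]
            for name, fname in (("sigma_h", "sigma_h"), ("alpha", "fit_alpha"),
                                ("d_e", "fit_d_e"), ("d_i", "fit_d_i"),
                                ("sigma_l", "sigma_l"))}
    rows = []
    for cid in manifest["chamber_ids"]:
        cm, _ = io.read_map(out / f"mask_chamber_{cid}.nii")
        roi = (cm > 0.5) & (sig_mask > 0.5)
        row = {"chamber": cid}
        for name, arr in maps.items():
            m = roi.copy()
            if name == "d_i":
                m &= flags != FLAG_UNIDENTIFIABLE
            if not m.any():          # all-electrolyte chamber: d_i undefined
                row[f"{name}_mean"] = np.nan
                row[f"{name}_sd"] = np.nan
                row[f"{name}_n"] = 0
                continue
            st = roi_stats(arr, m, cid)
            row[f"{name}_mean"] = st.mean
            row[f"{name}_sd"] = st.sd
            row[f"{name}_n"] = st.count
        rows.append(row)
    return pd.DataFrame(rows)


def stage_bench(cfg: RunConfig, out: Path) -> pd.DataFrame:
    standards = pd.read_csv(out / "bench_standards.csv")
    samples_df = pd.read_csv(out / "bench_samples.csv")
    curve = bench_mod.fit_calibration(
        [bench_mod.CalibrationStandard(r.molarity_M, r.absorbance)
         for r in standards.itertuples()])
    samples = [bench_mod.BenchSample(r.sample_id, r.absorbance, r.v_sample_ml,
                                     r.v_added_ml, r.c_added_M)
               for r in samples_df.itertuples()]
    results = bench_mod.analyze_samples(curve, samples)

    roi_df = chamber_roi_tables(cfg, out)
    cti_stats = [ROIStats(r.chamber, r.alpha_mean, r.alpha_sd, int(r.alpha_n))
                 for r in roi_df.itertuples()]
    comparison = bench_mod.compare_evf(results, cti_stats)
    table = pd.DataFrame([{
        "sample_id": res.sample_id,
        "absorbance": s.absorbance,
        "molarity_M": res.molarity,
        "ecw_ul": res.ecw,
        "evf_spectro": res.evf,
        "evf_cti": c["evf_cti"],
        "rel_error_pct": c["rel_error_pct"],
    } for res, s, c in zip(results, samples, comparison)])
    roi_df.to_csv(out / "roi_stats.csv", index=False, float_format="%.6g")
    table.to_csv(out / "bench_table.csv", index=False, float_format="%.6g")
    return table


def stage_report(cfg: RunConfig, out: Path) -> dict:
    roi = pd.read_csv(out / "roi_stats.csv")
    table = pd.read_csv(out / "bench_table.csv")
    report = {
        "seed": cfg.seed,
        "config_digest": cfg.digest(),
        "cti_parameters": roi.to_dict(orient="records"),
        "bench_comparison": table.to_dict(orient="records"),
        "inputs": ["roi_stats.csv", "bench_table.csv", "manifest.json"],
    }
    io.write_json(out / "report.json", report)
    return report


_STAGES = (("simulate", stage_simulate), ("recon-sigma-h", stage_recon),
           ("fit-compartments", stage_fit), ("cti", stage_cti),
           ("bench", stage_bench), ("report", stage_report))


def run_all(cfg: RunConfig, out: str | Path) -> dict:
    """Run every stage in order; any failure aborts naming the stage."""
    out = Path(out)
    for name, fn in _STAGES:
        try:
            result = fn(cfg, out)
        except Exception as exc:      # noqa: BLE001 - re-raise with stage context
            raise StageError(name, exc) from exc
    return result
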