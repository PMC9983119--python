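"""Benchtop spectrophotometric extracellular-volume-fraction procedure.

The wet-lab reference method: a known bolus of CuSO4 stock (200 ul at
0.5 M) is mixed into each 1 ml vesicle-suspension sample; the stock only
dilutes into the extracellular water (ECW), so the measured CuSO4
concentration of the extracted supernatant encodes the ECW through mass
conservation,

    c_added * v_added = C * (ECW + v_added)   =>   ECW = n_added / C - v_added,

and the extracellular volume fraction is EVF = ECW / v_sample. Absorbance
at 650 nm maps to concentration through a linear Beer-Lambert calibration
fitted on six standards (0-0.5 M).

``maxwell_wagner_sigma`` additionally provides an analytic single-shell
suspension conductivity spectrum (insulating-membrane spheres), useful as a
forward model for impedance-analyzer-style conductivity spectra.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cti import ROIStats, relative_error
from .phantom import BenchSample

EPS0 = 8.8541878128e-12  # vacuum permittivity, F/m


class CalibrationError(ValueError):
    """Calibration standards cannot support a line fit."""


class InconsistencyError(ValueError):
    """A measurement contradicts the dilution mass balance."""


@dataclass(frozen=True)
class CalibrationStandard:
    """One CuSO4 standard: molarity (M) and its absorbance at 650 nm."""

    molarity: float
    absorbance: float

    def __post_init__(self) -> None:
        if self.molarity < 0:
            raise CalibrationError("molarity must be non-negative")


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear map molarity = slope * absorbance + intercept."""

    slope: float
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class BenchResult:
    """Derived quantities for one sample."""

    sample_id: str
    molarity: float     # M
    ecw: float          # ul
    evf: float          # fraction of v_sample


def fit_calibration(standards: Sequence[CalibrationStandard]) -> CalibrationCurve:
    """Ordinary least squares of molarity on absorbance.

    The regression direction matches prediction use: unknown absorbances are
    mapped straight to concentration.
    """
    if len(standards) < 2:
        raise CalibrationError("need at least 2 standards")
    a = np.array([s.absorbance for s in standards], dtype=float)
    m = np.array([s.molarity for s in standards], dtype=float)
    if np.ptp(a) == 0:
        raise CalibrationError("standards have identical absorbances")
    slope, intercept = np.polyfit(a, m, 1)
    pred = slope * a + intercept
    ss_res = float(np.sum((m - pred) ** 2))
    ss_tot = float(np.sum((m - np.mean(m)) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CalibrationCurve(float(slope), float(intercept), r2)


def concentration_from_absorbance(curve: CalibrationCurve,
                                  absorbance: float) -> float:
    """Predicted molarity, clamped below at 0 (blank behaviour)."""
    return max(curve.slope * absorbance + curve.intercept, 0.0)


def ecw_from_concentration(sample: BenchSample, molarity: float) -> float:
    """Extracellular water volume (ul) from the measured concentration.

    Mass conservation of the added CuSO4: ECW = n_added / C - v_added.
    A zero concentration means no dilution was detectable — the sample is
    all water — and returns v_sample.
    """
    if molarity < 0:
        raise InconsistencyError("negative concentration")
    if molarity > sample.c_added:
        raise InconsistencyError(
            "measured concentration exceeds the added stock concentration")
    if molarity == 0:
        return sample.v_sample * 1000.0
    n_added = sample.c_added * sample.v_added          # mmol (M * ml)
    return (n_added / molarity - sample.v_added) * 1000.0


def evf_from_ecw(sample: BenchSample, ecw: float) -> float:
    """Extracellular volume fraction ECW / v_sample (ECW in ul)."""
    v_sample_ul = sample.v_sample * 1000.0
    if not 0.0 <= ecw <= v_sample_ul:
        raise InconsistencyError(
            f"ECW {ecw:.1f} ul outside [0, {v_sample_ul:.0f}] ul")
    return ecw / v_sample_ul


def analyze_samples(curve: CalibrationCurve,
                    samples: Sequence[BenchSample]) -> list[BenchResult]:
    """Absorbance -> concentration -> ECW -> EVF for each sample."""
    out = []
    for s in samples:
        c = concentration_from_absorbance(curve, s.absorbance)
        ecw = ecw_from_concentration(s, c)
        ecw = min(ecw, s.v_sample * 1000.0)  # noise can overshoot full water
        out.append(BenchResult(s.sample_id, c, ecw, evf_from_ecw(s, ecw)))
    return out


def compare_evf(spectro: Sequence[BenchResult],
                cti: Sequence[ROIStats]) -> list[dict]:
    """Method comparison: spectrophotometric vs CTI volume fractions.

    The spectrophotometer value is the reference of the relative error.
    Rows are matched by id; an unmatched id raises.
    """
    cti_by_id = {r.roi_id: r for r in cti}
    rows = []
    for s in spectro:
        if s.sample_id not in cti_by_id:
            raise KeyError(f"no CTI ROI matching sample {s.sample_id!r}")
        c = cti_by_id[s.sample_id]
        rows.append({
            "sample_id": s.sample_id,
            "evf_spectro": s.evf,
            "evf_cti": c.mean,
            "rel_error_pct": relative_error(s.evf, c.mean),
        })
    return rows


def maxwell_wagner_sigma(evf: float, sigma_e: float, frequency: float,
                         vesicle_radius: float = 10e-6,
                         membrane_capacitance: float = 1e-2,
                         sigma_i: float | None = None,
                         eps_rel: float = 80.0) -> float:
    """Single-shell Maxwell-Wagner conductivity of a vesicle suspension.

    Vesicles are spheres of radius ``vesicle_radius`` (m) with a thin
    insulating membrane of areal capacitance ``membrane_capacitance``
    (F/m^2), suspended at volume fraction p = 1 - evf in electrolyte of
    conductivity ``sigma_e`` (S/m). The membrane shorts out as frequency
    rises, so the spectrum increases from the insulating-inclusion limit
    toward the fully transparent suspension.
    """
    if not 0.0 <= evf <= 1.0:
        raise ValueError("evf must be in [0, 1]")
    if sigma_e <= 0 or frequency < 0 or vesicle_radius <= 0 \
            or membrane_capacitance <= 0:
        raise ValueError("physical parameters must be positive")
    p = 1.0 - evf
    if p == 0.0:
        return float(sigma_e)
    omega = 2.0 * np.pi * frequency
    eps = eps_rel * EPS0
    s_e = sigma_e + 1j * omega * eps
    s_cyt = (sigma_i if sigma_i is not None else sigma_e) + 1j * omega * eps
    # thin insulating shell of areal capacitance c_m in series with cytosol
    z = 1j * omega * vesicle_radius * membrane_capacitance
    s_p = s_cyt * z / (s_cyt + z) if abs(s_cyt + z) > 0 else 0.0
    # Maxwell-Wagner mixture rule for dilute-to-moderate sphere suspensions
    k = (s_p - s_e) / (s_p + 2.0 * s_e)
    s_eff = s_e * (1.0 + 2.0 * p * k) / (1.0 - p * k)
    return float(s_eff.real)
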