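"""Conductivity-tensor-imaging parameter combination and ROI statistics.

CTI infers the low-frequency conductivity of a tissue-like medium without
injecting current, by combining the high-frequency conductivity sigma_H
(membranes are transparent at the Larmor frequency) with the compartment
structure seen by diffusion MRI:

    sigma_L = alpha * sigma_e = alpha * c_e_bar * mu_e,
    c_e_bar = sigma_H / (alpha d_e + (1 - alpha) d_i beta),

where alpha is the extracellular volume fraction, d_e and d_i the
extracellular / intracellular water diffusivities standing in for ion
mobility, and beta the intra/extracellular ion concentration ratio (1 for
the vesicle phantom). Substituting gives the isotropic low-frequency map

    sigma_L = alpha * sigma_H * d_e / (alpha d_e + (1 - alpha) d_i beta).

c_e_bar is an *apparent* concentration kept in the composite unit
S.ms/(m.um^2); no conversion to mol/L is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ROIStats:
    """Mean / SD / count of one parameter over one region of interest."""

    roi_id: str
    mean: float
    sd: float
    count: int


def _denominator(alpha, d_e, d_i, beta):
    return alpha * d_e + (1.0 - alpha) * d_i * beta


def ion_concentration(sigma_h, alpha, d_e, d_i, beta=1.0):
    """Apparent extracellular ion concentration c_e_bar, voxelwise.

    Voxels with a non-positive denominator alpha*d_e + (1-alpha)*d_i*beta
    are returned as NaN (invalid), matching their exclusion downstream.
    """
    sigma_h = np.asarray(sigma_h, dtype=float)
    den = _denominator(np.asarray(alpha, dtype=float),
                       np.asarray(d_e, dtype=float),
                       np.asarray(d_i, dtype=float), beta)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, sigma_h / np.where(den > 0, den, 1.0), np.nan)
    return out if out.ndim else float(out)


def sigma_low(alpha, sigma_h, d_e, d_i, beta=1.0):
    """Low-frequency isotropic conductivity sigma_L, voxelwise.

    Identically alpha * c_e_bar * d_e; within [0, sigma_H] whenever
    0 <= alpha <= 1, d_i <= d_e and beta = 1.
    """
    alpha = np.asarray(alpha, dtype=float)
    d_e = np.asarray(d_e, dtype=float)
    out = alpha * ion_concentration(sigma_h, alpha, d_e, d_i, beta) * d_e
    return out if out.ndim else float(out)


def roi_stats(values: np.ndarray, roi_mask: np.ndarray,
              roi_id: str = "roi") -> ROIStats:
    """Arithmetic mean and sample SD over a mask, NaN voxels excluded."""
    m = np.asarray(roi_mask, dtype=bool)
    if not m.any():
        raise ValueError("empty ROI mask")
    v = np.asarray(values, dtype=float)[m]
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError(f"ROI {roi_id!r} has no valid voxels")
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return ROIStats(roi_id, float(np.mean(v)), sd, int(v.size))


def relative_error(reference: float, estimate: float) -> float:
    """Percent relative error 100 |reference - estimate| / reference."""
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return 100.0 * abs(reference - estimate) / reference
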