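"""Phase-based electrical properties tomography at the Larmor frequency.

The transceive phase of a spin-echo acquisition carries the conductivity at
the imaging frequency through the identity

    sigma_H = lap(phi) / (2 mu0 omega),

so reconstruction amounts to (i) combining the echoes of a multi-echo stack
into one low-noise phase map and (ii) applying a noise-tolerant discrete
Laplacian. The Laplacian here is a local quadratic (Savitzky-Golay) surface
fit over a (2r+1)^2 window, which is exact for polynomial phase of total
degree <= 2 and averages noise over the window. Voxels whose window crosses
the validity mask are excluded (erosion), never extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import ndimage

from .phantom import MU0, LARMOR_HZ, PhaseMap


class PhaseWrapError(ValueError):
    """Phase wraps detected inside the mask; unwrapping is out of scope."""


@dataclass
class MultiEchoStack:
    """Complex spin-echo images at increasing echo times."""

    echoes: np.ndarray        # (n_echoes, ny, nx) complex
    te_list: np.ndarray       # ms, strictly increasing
    pixel_size: float         # mm

    def __post_init__(self) -> None:
        self.echoes = np.asarray(self.echoes, dtype=complex)
        self.te_list = np.asarray(self.te_list, dtype=float)
        if self.echoes.ndim != 3:
            raise ValueError("echoes must be (n_echoes, ny, nx)")
        if self.te_list.size != self.echoes.shape[0]:
            raise ValueError("te_list length must equal echo count")
        if np.any(np.diff(self.te_list) <= 0):
            raise ValueError("te_list must increase strictly")


@dataclass
class ConductivityMap:
    """Reconstructed sigma_H raster with its eroded validity mask."""

    sigma: np.ndarray
    mask: np.ndarray
    omega: float
    kernel_radius: int


def combine_echo_phase(mems: MultiEchoStack) -> PhaseMap:
    """Combine echo phases into one map with magnitude-squared weights.

    The per-voxel combination is the weighted circular mean

        phi = arg( sum_k |S_k|^2 * S_k / |S_k| ),

    i.e. unit phasors weighted by squared echo magnitude — the SNR-optimal
    weighting when each echo carries independent complex Gaussian noise and
    phase is echo-independent. Voxels where every echo magnitude is zero
    are dropped from the validity mask.
    """
    mag = np.abs(mems.echoes)
    with np.errstate(invalid="ignore", divide="ignore"):
        phasors = np.where(mag > 0, mems.echoes / mag, 0.0)
    combined = np.sum(mag**2 * phasors, axis=0)
    mask = np.sum(mag, axis=0) > 0
    phase = np.where(mask, np.angle(combined), 0.0)
    return PhaseMap(phase=phase, mask=mask)


@lru_cache(maxsize=8)
def _sg_laplacian_kernel(radius: int) -> np.ndarray:
    """Savitzky-Golay Laplacian kernel (units of px^-2) for a square window.

    Least-squares fit of c0 + c1 x + c2 y + c3 xy + c4 x^2 + c5 y^2 over the
    (2r+1)^2 window; the kernel returns 2 (c4 + c5). Exact for quadratics.
    """
    if radius < 1:
        raise ValueError("kernel_radius must be >= 1 px")
    offs = np.arange(-radius, radius + 1)
    xx, yy = np.meshgrid(offs, offs, indexing="xy")
    x, y = xx.ravel(), yy.ravel()
    design = np.column_stack(
        [np.ones_like(x), x, y, x * y, x**2, y**2]).astype(float)
    pinv = np.linalg.pinv(design)
    kernel = 2.0 * (pinv[4] + pinv[5])
    return kernel.reshape(xx.shape)


def laplacian_sigma(phase: PhaseMap, mask: np.ndarray | None = None,
                    kernel_radius: int = 2, pixel_size: float = 1.0,
                    frequency_hz: float = LARMOR_HZ,
                    presmooth_sigma: float = 0.0) -> ConductivityMap:
    """Reconstruct sigma_H = lap(phi) / (2 mu0 omega).

    Parameters
    ----------
    phase : PhaseMap
        Transceive phase in radians; must be wrap-free inside the mask.
    mask : bool ndarray, optional
        Validity mask; defaults to the phase map's own.
    kernel_radius : int
        Half-width r of the quadratic-fit window, pixels.
    pixel_size : float
        Pixel edge length in mm (converts the px^-2 kernel to m^-2).
    presmooth_sigma : float
        Optional Gaussian pre-smoothing SD in px (0 = off).
    """
    mask = phase.mask if mask is None else (phase.mask & mask)
    ph = phase.phase
    if np.any(np.abs(ph[mask]) > np.pi):
        raise PhaseWrapError("phase outside (-pi, pi] inside the mask")
    jumps = np.zeros_like(ph, dtype=bool)
    inner = mask & np.roll(mask, 1, 0) & np.roll(mask, -1, 0)
    jumps[inner] = np.abs(np.diff(ph, axis=0, prepend=ph[:1]))[inner] > np.pi
    if jumps.any():
        raise PhaseWrapError("phase wraps detected inside the mask")

    work = np.where(mask, ph, 0.0)
    if presmooth_sigma > 0:
        # normalized masked smoothing so the void outside does not bleed in
        num = ndimage.gaussian_filter(work, presmooth_sigma)
        den = ndimage.gaussian_filter(mask.astype(float), presmooth_sigma)
        with np.errstate(invalid="ignore", divide="ignore"):
            work = np.where(den > 1e-12, num / den, 0.0)

    kernel = _sg_laplacian_kernel(kernel_radius)
    h_m = pixel_size * 1e-3
    lap = ndimage.convolve(work, kernel, mode="constant") / h_m**2
    # a voxel is valid only if its whole window lies inside the mask
    footprint = np.ones(kernel.shape, dtype=bool)
    eroded = ndimage.binary_erosion(mask, structure=footprint)
    omega = 2.0 * np.pi * frequency_hz
    sigma = np.where(eroded, lap / (2.0 * MU0 * omega), np.nan)
    return ConductivityMap(sigma=sigma, mask=eroded,
                           omega=omega, kernel_radius=kernel_radius)
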