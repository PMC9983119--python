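"""NIfTI-1 and sidecar I/O for the phantom pipeline.

Single-slice 2-D rasters are stored as (nx, ny, 1) NIfTI volumes and
stacks (DWI, multi-echo) as 4-D volumes, with the in-plane pixel spacing
in the header. b-values travel as an FSL-style whitespace-separated text
sidecar; echo times and unit metadata as JSON sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np


class GridMismatchError(ValueError):
    """Two stage inputs disagree on grid shape or spacing."""


def _affine(pixel_size: float) -> np.ndarray:
    aff = np.diag([pixel_size, pixel_size, 1.0, 1.0])
    return aff


def write_map(path: str | Path, data: np.ndarray, pixel_size: float) -> Path:
    """Write a 2-D raster or (n, ny, nx) stack as NIfTI-1.

    Stacks are moved to (nx, ny, 1, n) so the volume index is the NIfTI
    4th dimension.
    """
    path = Path(path)
    arr = np.asarray(data)
    if arr.ndim == 2:
        vol = arr.T[:, :, None]
    elif arr.ndim == 3:
        vol = np.transpose(arr, (2, 1, 0))[:, :, None, :]
    else:
        raise ValueError("expected a 2-D map or a 3-D stack")
    img = nib.Nifti1Image(vol.astype(np.float64), _affine(pixel_size))
    img.header.set_zooms((pixel_size, pixel_size, 1.0) + ((1.0,) if arr.ndim == 3 else ()))
    nib.save(img, str(path))
    return path


def read_map(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a NIfTI written by ``write_map``; returns (array, pixel_size)."""
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj, dtype=np.float64)
    px = float(img.header.get_zooms()[0])
    if vol.ndim == 3:
        return vol[:, :, 0].T, px
    if vol.ndim == 4:
        return np.transpose(vol[:, :, 0, :], (2, 1, 0)), px
    raise ValueError(f"unexpected NIfTI dimensionality in {path}")


def check_same_grid(a: np.ndarray, b: np.ndarray,
                    name_a: str, name_b: str) -> None:
    if a.shape[-2:] != b.shape[-2:]:
        raise GridMismatchError(
            f"grid mismatch between {name_a} {a.shape[-2:]} and "
            f"{name_b} {b.shape[-2:]}")


def write_bvals(path: str | Path, b_values) -> Path:
    path = Path(path)
    path.write_text(" ".join(f"{b:g}" for b in np.asarray(b_values)) + "\n")
    return path


def read_bvals(path: str | Path) -> np.ndarray:
    return np.array([float(t) for t in Path(path).read_text().split()])


def write_json(path: str | Path, obj: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
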