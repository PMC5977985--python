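"""Registered-volume I/O, Gaussian smoothing, and masked flattening.

Volumes are assumed to be already registered to a common space and (for the
tissue channels) already segmented into probability maps; this module only
reads, smooths and vectorizes them.

Voxel ordering convention
-------------------------
Wherever a 3D grid is flattened into a feature vector, voxels are taken in
C order with 0-based indices: the last axis varies fastest.  The same
ordering is used when back-projecting importance values onto the grid, so
feature index <-> voxel coordinate is a fixed, documented bijection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "VolumeGrid",
    "BrainMask",
    "read_volume",
    "write_volume",
    "fwhm_to_sigma",
    "smooth_volume",
    "flatten_masked",
    "unflatten",
]

#: FWHM = sigma * 2*sqrt(2*ln 2) for a Gaussian kernel.
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

CHANNELS = ("whole_brain", "GM", "WM")


@dataclass
class VolumeGrid:
    """A single registered 3D volume with its spatial metadata.

    Parameters
    ----------
    intensities : (i, j, k) float array
        Voxel intensities; must be finite.
    voxel_size_mm : tuple of 3 positive floats
        Physical voxel dimensions along each axis.
    channel : str
        One of ``whole_brain``, ``GM``, ``WM``.
    affine : (4, 4) float array
        Voxel-to-world coordinate mapping.
    """

    intensities: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    channel: str = "whole_brain"
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError(
                f"expected a 3D volume, got {self.intensities.ndim} dimensions"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("volume contains non-finite intensities")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"invalid voxel size {self.voxel_size_mm}")
        if self.affine is None:
            self.affine = np.diag([*self.voxel_size_mm, 1.0])
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {self.affine.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]


@dataclass
class BrainMask:
    """Boolean inclusion mask congruent with a :class:`VolumeGrid`."""

    include: np.ndarray

    def __post_init__(self) -> None:
        self.include = np.asarray(self.include).astype(bool)
        if self.include.ndim != 3:
            raise ValueError("mask must be a 3D boolean grid")

    @property
    def n_voxels(self) -> int:
        return int(self.include.sum())


def read_volume(path: str | Path) -> VolumeGrid:
    """Read a 3D NIfTI-1 volume; no resampling is performed.

    Raises
    ------
    ValueError
        If the file is not a readable 3D NIfTI image (malformed header,
        truncated data, or a 4D/time-series input).
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
    except ValueError:
        raise
    except Exception as exc:  # nibabel raises several format-error types
        raise ValueError(f"could not read NIfTI volume {path}: {exc}") from exc
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3D volume, got shape {data.shape}"
        )
    zooms = img.header.get_zooms()[:3]
    return VolumeGrid(
        intensities=data,
        voxel_size_mm=tuple(float(z) for z in zooms),
        affine=np.asarray(img.affine, dtype=float),
    )


def write_volume(v: VolumeGrid, path: str | Path) -> Path:
    """Serialize a volume as NIfTI-1, preserving the affine and voxel sizes."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(v.intensities, dtype=np.float64), v.affine)
    img.header.set_zooms(v.voxel_size_mm)
    nib.save(img, str(path))
    return path


def fwhm_to_sigma(fwhm_mm: float, voxel_size_mm: float) -> float:
    """Convert an isotropic FWHM in mm to a per-axis sigma in voxel units."""
    return fwhm_mm / FWHM_PER_SIGMA / voxel_size_mm


def smooth_volume(v: VolumeGrid, fwhm_mm: float) -> VolumeGrid:
    """Smooth with a separable isotropic Gaussian of the given FWHM (mm).

    The kernel is unit-sum (total intensity conserved) and boundaries are
    handled by reflection.  ``fwhm_mm == 0`` returns the input unchanged.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be non-negative, got {fwhm_mm}")
    if fwhm_mm == 0:
        return v
    sigma = [fwhm_to_sigma(fwhm_mm, s) for s in v.voxel_size_mm]
    smoothed = ndimage.gaussian_filter(v.intensities, sigma=sigma, mode="reflect")
    return VolumeGrid(
        intensities=smoothed,
        voxel_size_mm=v.voxel_size_mm,
        channel=v.channel,
        affine=v.affine,
    )


def smooth_array(data: np.ndarray, voxel_size_mm, fwhm_mm: float) -> np.ndarray:
    """Array-level smoothing used by the pipeline's cached feature builder."""
    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be non-negative, got {fwhm_mm}")
    if fwhm_mm == 0:
        return data
    sigma = [fwhm_to_sigma(fwhm_mm, s) for s in voxel_size_mm]
    return ndimage.gaussian_filter(data, sigma=sigma, mode="reflect")


def flatten_masked(v: VolumeGrid, mask: BrainMask) -> np.ndarray:
    """Vector of masked intensities in the fixed C-order voxel ordering."""
    if mask.include.shape != v.shape:
        raise ValueError(
            f"mask shape {mask.include.shape} incongruent with volume {v.shape}"
        )
    if not mask.include.any():
        raise ValueError("mask selects no voxels")
    return v.intensities[mask.include]


def unflatten(values: np.ndarray, mask: BrainMask, fill: float = 0.0) -> np.ndarray:
    """Inverse of :func:`flatten_masked` on the masked support."""
    values = np.asarray(values, dtype=float)
    if values.shape != (mask.n_voxels,):
        raise ValueError(
            f"expected {mask.n_voxels} values, got {values.shape}"
        )
    out = np.full(mask.include.shape, fill, dtype=float)
    out[mask.include] = values
    return out
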