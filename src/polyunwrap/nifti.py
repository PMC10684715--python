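"""NIfTI reading/writing and mask generation."""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .core import WrappedVolume, wrap_to_principal

__all__ = [
    "read_phase_volume",
    "read_volume",
    "write_volume",
    "generate_mask",
]


def read_volume(path) -> tuple:
    """Load a 3D NIfTI image; returns ``(data float64, affine)``."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {data.shape}")
    return data, img.affine


def read_phase_volume(path, magnitude_path=None, mask_path=None,
                      rescale: bool = False) -> WrappedVolume:
    """Read a wrapped-phase NIfTI volume (plus optional magnitude and mask).

    Values outside ``(-pi, pi]`` are re-wrapped with a warning.  With
    ``rescale=True`` the stored value range is first mapped linearly onto
    ``(-pi, pi]`` — some scanners export phase as scaled integers.  NaN
    voxels inside the mask are rejected.
    """
    data, affine = read_volume(path)
    mask = None
    if mask_path is not None:
        m, _ = read_volume(mask_path)
        mask = m > 0
    magnitude = None
    if magnitude_path is not None:
        magnitude, _ = read_volume(magnitude_path)
    check = data[mask] if mask is not None else data
    if np.any(np.isnan(check)):
        raise ValueError(f"{path}: NaN phase values inside the mask")
    if rescale:
        # map the stored range linearly onto [-pi, pi]; the single value
        # landing exactly on -pi is folded to +pi by the wrap below
        lo, hi = float(np.nanmin(data)), float(np.nanmax(data))
        if hi > lo:
            data = -np.pi + (data - lo) / (hi - lo) * (2 * np.pi)
            data = wrap_to_principal(data)
    finite = np.isfinite(data)
    out_of_range = finite & ((data <= -np.pi) | (data > np.pi))
    if np.any(out_of_range):
        warnings.warn(
            f"{path}: {int(out_of_range.sum())} voxels outside (-pi, pi]; "
            "re-wrapping to the principal interval", stacklevel=2)
        data = np.where(finite, wrap_to_principal(np.where(finite, data, 0.0)),
                        data)
    data = np.nan_to_num(data, nan=0.0, posinf=0.0, neginf=0.0)
    return WrappedVolume(data, magnitude=magnitude, mask=mask, affine=affine)


def write_volume(data: np.ndarray, path, affine: Optional[np.ndarray] = None,
                 dtype=None) -> Path:
    """Write a 3D array as NIfTI; integer dtypes round-trip losslessly."""
    path = Path(path)
    arr = np.asarray(data)
    if dtype is not None:
        arr = arr.astype(dtype)
    elif arr.dtype == bool:
        arr = arr.astype(np.uint8)
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(arr, affine)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def generate_mask(magnitude: np.ndarray, strategy: str = "threshold",
                  fraction: float = 1.0) -> np.ndarray:
    """ROI mask from a magnitude image.

    ``strategy="full"`` returns the all-true mask.  The default
    ``"threshold"`` strategy thresholds at ``fraction`` times the Otsu
    level, keeps the largest 26-connected component and fills holes slice
    by slice — a standard surrogate when no externally produced mask is
    supplied (a user-provided mask always takes precedence upstream).
    """
    magnitude = np.asarray(magnitude, dtype=float)
    if strategy == "full":
        return np.ones(magnitude.shape, dtype=bool)
    if strategy != "threshold":
        raise ValueError("strategy must be 'threshold' or 'full'")
    if magnitude.max() == magnitude.min():
        return np.ones(magnitude.shape, dtype=bool)
    level = threshold_otsu(magnitude) * fraction
    mask = magnitude > level
    if not mask.any():
        raise ValueError("mask empty after thresholding; lower the fraction")
    # Otsu assumes an air/object bimodal histogram; on an image without an
    # air background it merely splits the noise in half.  When the two
    # classes are not clearly separated, keep the whole volume.
    bg = magnitude[~mask]
    if bg.size == 0 or bg.mean() > 0.5 * magnitude[mask].mean():
        return np.ones(magnitude.shape, dtype=bool)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), bool))
    if n > 1:
        counts = np.bincount(labels.ravel())[1:]
        mask = labels == (int(np.argmax(counts)) + 1)
    for z in range(mask.shape[2]):
        mask[:, :, z] = ndimage.binary_fill_holes(mask[:, :, z])
    return mask
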