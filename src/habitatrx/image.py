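"""Volume containers, NIfTI I/O and preprocessing.

Preprocessing mirrors the standard bp-MRI radiomics recipe: resample every
volume to isotropic 1 mm spacing, correct the low-frequency intensity bias
inside the gland, then pull the masked voxels out as flat arrays.  The bias
corrector is a log-domain polynomial fit — a deliberately simple smooth-field
model with a hook (``corrector=``) so an external N4-style implementation can
be substituted for real scanner data.  Registration is out of scope: volume
pairs are expected to be co-registered already (phantoms are aligned by
construction).

Coordinate convention: voxel indices are 0-based and world coordinates are
``index * spacing`` (no direction matrix, no origin offset).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Literal, Optional

import nibabel as nib
import numpy as np
from scipy import ndimage


@dataclass
class VolumePair:
    """Co-registered T2W and ADC volumes with a binary lesion mask.

    Both arrays share one grid: shape, spacing and (implicitly) origin.
    ``gland_mask`` is optional and, when present, is the support used for
    bias-field estimation.
    """

    t2: np.ndarray
    adc: np.ndarray
    spacing: tuple[float, float, float]
    lesion_mask: np.ndarray
    patient_id: str
    gland_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t2 = np.asarray(self.t2, dtype=np.float64)
        self.adc = np.asarray(self.adc, dtype=np.float64)
        self.lesion_mask = np.asarray(self.lesion_mask).astype(bool)
        if not (self.t2.shape == self.adc.shape == self.lesion_mask.shape):
            raise ValueError("t2, adc and lesion_mask must share one shape")
        if self.gland_mask is not None:
            self.gland_mask = np.asarray(self.gland_mask).astype(bool)
            if self.gland_mask.shape != self.t2.shape:
                raise ValueError("gland_mask shape mismatch")
        if min(self.spacing) <= 0:
            raise ValueError("spacing must be positive")
        if not self.lesion_mask.any():
            raise ValueError("lesion mask is empty")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.t2.shape


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_nifti(volume: np.ndarray, spacing: tuple[float, float, float], path: str | Path) -> None:
    """Write a 3-D array as NIfTI-1 with a diagonal spacing affine."""
    arr = np.asarray(volume)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    img = nib.Nifti1Image(arr, _affine(spacing))
    nib.save(img, str(path))


def load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI volume; returns (array, voxel spacing in mm)."""
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), spacing


def resample_isotropic(
    volume: np.ndarray,
    spacing: tuple[float, float, float],
    target: float = 1.0,
    interp: Literal["trilinear", "nearest"] = "trilinear",
) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Resample a volume to isotropic ``target`` mm spacing.

    Output dimensions are ``round(dim * spacing / target)``; output voxel i
    sits at world coordinate ``i * target`` and is interpolated from the
    input grid (``trilinear`` for images, ``nearest`` for masks and label
    maps, which therefore stay integer-valued).
    """
    vol = np.asarray(volume, dtype=np.float64)
    out_shape = tuple(
        int(round(d * s / target)) for d, s in zip(vol.shape, spacing)
    )
    if min(out_shape) < 1:
        raise ValueError(f"resampling to {target} mm yields empty output {out_shape}")
    grids = np.meshgrid(
        *[np.arange(n) * target / s for n, s in zip(out_shape, spacing)],
        indexing="ij",
    )
    order = 1 if interp == "trilinear" else 0
    out = ndimage.map_coordinates(
        vol, np.stack(grids), order=order, mode="nearest"
    )
    if interp == "nearest":
        out = np.round(out).astype(volume.dtype if np.asarray(volume).dtype != bool else np.uint8)
    return out, (target, target, target)


def correct_bias(
    volume: np.ndarray,
    mask: np.ndarray,
    poly_order: int = 3,
    corrector: Optional[Callable[[np.ndarray, np.ndarray], np.ndarray]] = None,
) -> np.ndarray:
    """Remove a smooth multiplicative intensity bias inside ``mask``.

    Fits a polynomial of total degree ``poly_order`` to the log-intensities
    on the masked voxels (least squares), divides the whole volume by the
    exponentiated fit and rescales so the masked mean is preserved.  Pass
    ``corrector(volume, mask) -> volume`` to substitute an external
    implementation (e.g. a full N4 correction).
    """
    vol = np.asarray(volume, dtype=np.float64)
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("bias correction mask is empty")
    if corrector is not None:
        return corrector(vol, mask)
    if mask.sum() < 4:
        warnings.warn("mask too small for bias estimation; returning input unchanged")
        return vol.copy()
    vals = vol[mask]
    if np.any(vals <= 0):
        raise ValueError("bias correction requires positive intensities inside the mask")

    idx = np.argwhere(mask).astype(np.float64)
    # normalise coordinates to [-1, 1] for a well-conditioned design matrix
    lo, hi = idx.min(axis=0), idx.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    u = 2.0 * (idx - lo) / span - 1.0

    powers = [
        (i, j, k)
        for i in range(poly_order + 1)
        for j in range(poly_order + 1)
        for k in range(poly_order + 1)
        if i + j + k <= poly_order
    ]
    design = np.column_stack(
        [u[:, 0] ** i * u[:, 1] ** j * u[:, 2] ** k for i, j, k in powers]
    )
    logv = np.log(vals)
    coef, *_ = np.linalg.lstsq(design, logv, rcond=None)

    # evaluate the fitted field on the full grid
    grid = np.indices(vol.shape).reshape(3, -1).T.astype(np.float64)
    ug = 2.0 * (grid - lo) / span - 1.0
    field_flat = sum(
        c * ug[:, 0] ** i * ug[:, 1] ** j * ug[:, 2] ** k
        for c, (i, j, k) in zip(coef, powers)
    )
    bias = np.exp(field_flat.reshape(vol.shape) - field_flat.mean())
    corrected = vol / bias
    corrected *= vals.mean() / corrected[mask].mean()
    return corrected


def masked_coords(mask: np.ndarray) -> np.ndarray:
    """Indices of the true voxels of ``mask``, x varying fastest, as (n, 3)."""
    return np.argwhere(np.asarray(mask).astype(bool).transpose(2, 1, 0))[:, ::-1]


def extract_masked_voxels(
    pair: VolumePair,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flatten the lesion voxels of a pair to (coords, t2, adc) arrays.

    Rows are ordered with x varying fastest (Fortran-style scan of the
    index grid), one row per masked voxel.
    """
    if not pair.lesion_mask.any():
        raise ValueError("empty lesion mask")
    coords = masked_coords(pair.lesion_mask)
    x, y, z = coords[:, 0], coords[:, 1], coords[:, 2]
    return coords, pair.t2[x, y, z], pair.adc[x, y, z]


def preprocess_pair(
    pair: VolumePair,
    target_spacing: float = 1.0,
    bias_poly_order: int = 3,
    corrector: Optional[Callable[[np.ndarray, np.ndarray], np.ndarray]] = None,
) -> VolumePair:
    """Bias-correct then resample a pair to isotropic spacing."""
    support = pair.gland_mask if pair.gland_mask is not None else pair.lesion_mask
    t2 = correct_bias(pair.t2, support, bias_poly_order, corrector)
    adc = correct_bias(pair.adc, support, bias_poly_order, corrector)
    t2r, sp = resample_isotropic(t2, pair.spacing, target_spacing, "trilinear")
    adcr, _ = resample_isotropic(adc, pair.spacing, target_spacing, "trilinear")
    maskr, _ = resample_isotropic(pair.lesion_mask, pair.spacing, target_spacing, "nearest")
    glandr = None
    if pair.gland_mask is not None:
        glandr, _ = resample_isotropic(pair.gland_mask, pair.spacing, target_spacing, "nearest")
    return VolumePair(
        t2=t2r,
        adc=adcr,
        spacing=sp,
        lesion_mask=maskr.astype(bool),
        patient_id=pair.patient_id,
        gland_mask=None if glandr is None else glandr.astype(bool),
    )
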