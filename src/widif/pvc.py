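"""Geometric partial-volume correction of the carotid blood curve.

The correction is mask-based: with a binary carotid mask M and the
scanner-matched Gaussian kernel G,

* spill-out  alpha = sum(G(M) * M) / sum(M)   — the fraction of true
  in-mask signal retained inside the mask after blurring;
* spill-in   beta  = sum(G(1-M) * M) / sum(M) — the fraction of the
  measured in-mask signal contributed by surrounding tissue.

With a constant-preserving boundary these are complementary
(alpha + beta = 1) since G(M) + G(1-M) = G(1) = 1 voxelwise.  The
surrounding-tissue activity C_T is estimated in a "sleeve" shell (outer
minus inner morphological dilation of the mask) and the corrected blood
curve is  C_B = (C_B_PET - beta * C_T) / alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from widif.curves import windowed_integral
from widif.image_io import Mask3D, TimeSeriesCurve

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548
KERNEL_TRUNCATE_SIGMA = 4.0


@dataclass(frozen=True)
class PVCFactors:
    """Spill-out alpha, spill-in beta, and the kernel FWHM that produced them."""

    alpha: float
    beta: float
    kernel_fwhm_mm: float

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1 + 1e-9:
            raise ValueError("alpha must be in (0, 1]")
        if not 0 <= self.beta < 1:
            raise ValueError("beta must be in [0, 1)")


def gaussian_smooth(volume: np.ndarray, fwhm_mm: float, voxel_size_mm) -> np.ndarray:
    """Separable Gaussian smoothing in physical units.

    Per-axis sigma = (fwhm / 2.3548) / voxel_size.  The boundary mode is
    replicate ('nearest'), which preserves constants so that the
    complementarity alpha + beta = 1 holds exactly; the kernel is
    truncated at 4 sigma.  fwhm = 0 is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be non-negative")
    volume = np.asarray(volume, dtype=float)
    if fwhm_mm == 0:
        return volume.copy()
    sigmas = [(fwhm_mm / FWHM_PER_SIGMA) / v for v in voxel_size_mm]
    return ndimage.gaussian_filter(
        volume, sigma=sigmas, mode="nearest", truncate=KERNEL_TRUNCATE_SIGMA
    )


def spillout_alpha(mask: Mask3D, fwhm_mm: float) -> float:
    """alpha = sum(smooth(M) * M) / sum(M)."""
    m = mask.voxels.astype(float)
    n = m.sum()
    if n == 0:
        raise ValueError("mask is empty")
    sm = gaussian_smooth(m, fwhm_mm, mask.voxel_size_mm)
    return float((sm * m).sum() / n)


def spillin_beta(mask: Mask3D, fwhm_mm: float) -> float:
    """beta = sum(smooth(1 - M) * M) / sum(M)."""
    m = mask.voxels.astype(float)
    n = m.sum()
    if n == 0:
        raise ValueError("mask is empty")
    sm = gaussian_smooth(1.0 - m, fwhm_mm, mask.voxel_size_mm)
    return float((sm * m).sum() / n)


def compute_pvc_factors(mask: Mask3D, fwhm_mm: float) -> PVCFactors:
    return PVCFactors(
        alpha=spillout_alpha(mask, fwhm_mm),
        beta=spillin_beta(mask, fwhm_mm),
        kernel_fwhm_mm=fwhm_mm,
    )


_STRUCTURES = {6: 1, 18: 2, 26: 3}


def sleeve_tissue_mask(
    mask: Mask3D, inner: int = 8, outer: int = 10, connectivity: int = 6
) -> Mask3D:
    """Shell of surrounding tissue: dilate(M, outer) minus dilate(M, inner).

    Dilation is ``n`` iterations of a unit binary dilation (default
    6-connected / face neighbours; 18 and 26 also supported), counted in
    voxels and clipped at the image bounds.  The default 8-to-10-voxel
    shell sits outside the carotid spill-over range while staying in the
    neck.
    """
    if not (outer > inner >= 1):
        raise ValueError("need outer > inner >= 1")
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    m = mask.voxels
    if not m.any():
        raise ValueError("mask is empty")
    structure = ndimage.generate_binary_structure(3, _STRUCTURES[connectivity])
    inner_d = ndimage.binary_dilation(m, structure=structure, iterations=inner)
    outer_d = ndimage.binary_dilation(inner_d, structure=structure, iterations=outer - inner)
    sleeve = outer_d & ~inner_d
    if not sleeve.any():
        raise ValueError("sleeve is empty: mask dilation fills the grid")
    return Mask3D(sleeve.astype(int), mask.voxel_size_mm)


def correct_blood_curve(
    carotid_tac: TimeSeriesCurve,
    tissue_tac: TimeSeriesCurve,
    factors: PVCFactors,
) -> TimeSeriesCurve:
    """Apply C_B = (C_B_PET - beta * C_T) / alpha pointwise.

    Negative outputs are permitted (noise can drive individual frames
    negative) but a warning is raised if the early AUC (0-60 s) of the
    corrected curve is negative, which indicates a failed correction.
    """
    if factors.alpha <= 0:
        raise ValueError("alpha must be positive")
    if len(carotid_tac) != len(tissue_tac) or not np.allclose(
        carotid_tac.time_s, tissue_tac.time_s
    ):
        raise ValueError("carotid and tissue curves must share the same time grid")
    corrected = (carotid_tac.value - factors.beta * tissue_tac.value) / factors.alpha
    out = TimeSeriesCurve(carotid_tac.time_s, corrected)
    t_end = min(60.0, out.time_s[-1])
    if t_end > out.time_s[0] and windowed_integral(out, out.time_s[0], t_end) < 0:
        warnings.warn("corrected blood curve has negative early AUC")
    return out
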