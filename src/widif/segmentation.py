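"""Carotid segmentation from early frames by slice-max-median thresholding.

During the first ~30 s of a water scan the tracer is in the carotids but
not yet in brain tissue, so the arteries can be isolated by intensity
thresholding.  The workflow: crop to the neck (bottom third of the FoV),
average the operator-chosen early frames, tabulate the maximum intensity
of each axial slice within a box VOI around the carotids, take the
median of those per-slice maxima as the reference intensity, and keep
voxels above a percentage (default 42%) of that reference.  The binary
mask is then overlaid on the full time series to extract the carotid
time-activity curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from widif.image_io import DynamicImage, FrameSchedule, Mask3D, TimeSeriesCurve, frame_mid_times


@dataclass(frozen=True)
class VoiBox:
    """Axis-aligned box of 0-based half-open index ranges."""

    x0: int
    x1: int
    y0: int
    y1: int
    z0: int
    z1: int

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 >= 0 and self.y1 > self.y0 >= 0 and self.z1 > self.z0 >= 0):
            raise ValueError("VOI ranges must be non-empty and non-negative")

    @classmethod
    def full(cls, shape) -> "VoiBox":
        return cls(0, shape[0], 0, shape[1], 0, shape[2])

    def check_within(self, shape) -> None:
        if self.x1 > shape[0] or self.y1 > shape[1] or self.z1 > shape[2]:
            raise ValueError(f"VOI {self} exceeds image shape {tuple(shape)}")

    def slices(self) -> tuple[slice, slice, slice]:
        return (slice(self.x0, self.x1), slice(self.y0, self.y1), slice(self.z0, self.z1))


@dataclass
class SegmentationConfig:
    """Operator choices for the carotid mask: early frames, threshold, VOI."""

    early_frame_indices: list[int]
    threshold_pct: float = 42.0
    voi: VoiBox | None = None
    min_component_voxels: int = 0  # optional small-component filter, off by default

    def __post_init__(self) -> None:
        if not 0 < self.threshold_pct <= 100:
            raise ValueError("threshold_pct must be in (0, 100]")


def crop_neck(image: DynamicImage) -> tuple[DynamicImage, VoiBox]:
    """Restrict to the bottom third of the axial FoV (the neck region).

    Assumes canonical orientation (inferior at low axial index); returns
    the sub-image of slices [0, floor(nz/3)) and the box used.
    """
    nz = image.shape3[2]
    if nz < 3:
        raise ValueError("image has fewer than 3 axial slices")
    z1 = nz // 3
    box = VoiBox(0, image.shape3[0], 0, image.shape3[1], 0, z1)
    sub = DynamicImage(image.voxels[:, :, :z1, :].copy(), image.voxel_size_mm, image.schedule)
    return sub, box


def suggest_early_frames(
    image: DynamicImage, max_frame: int = 6, neck_voi: VoiBox | None = None
) -> list[int]:
    """Advisory heuristic for the early carotid-only frames.

    The actual choice is an operator decision made by visual inspection;
    this helper returns, among frames [0..max_frame], the contiguous run
    of frames whose within-neck maximum exceeds 20% of the overall
    within-neck maximum of those frames, restricted to frames before the
    whole-image total activity peaks (tracer not yet in the brain).
    Returns an empty list (with a warning) if nothing qualifies.
    """
    neck, box = crop_neck(image)
    if neck_voi is not None:
        neck_vox = neck.voxels[neck_voi.slices()]
    else:
        neck_vox = neck.voxels
    max_frame = min(max_frame, image.n_frames - 1)
    per_frame_max = np.array(
        [neck_vox[..., j].max() for j in range(max_frame + 1)]
    )
    global_max = per_frame_max.max()
    totals = image.voxels.sum(axis=(0, 1, 2))
    peak_frame = int(np.argmax(totals))
    candidate = (per_frame_max > 0.2 * global_max) if global_max > 0 else np.zeros(
        max_frame + 1, dtype=bool
    )
    candidate &= np.arange(max_frame + 1) < max(peak_frame, 1)
    if not candidate.any():
        warnings.warn("no early frame qualifies; supply frame indices manually")
        return []
    # longest contiguous run of qualifying frames
    best, cur = [], []
    for j in range(max_frame + 1):
        if candidate[j]:
            cur.append(j)
            if len(cur) > len(best):
                best = list(cur)
        else:
            cur = []
    return best


def average_frames(image: DynamicImage, indices) -> np.ndarray:
    """Unweighted voxelwise mean of the selected frames."""
    indices = list(indices)
    if not indices:
        raise ValueError("no frame indices given")
    if len(set(indices)) != len(indices):
        raise ValueError("duplicate frame indices")
    if min(indices) < 0 or max(indices) >= image.n_frames:
        raise ValueError("frame index out of range")
    return image.voxels[..., indices].mean(axis=3)


def slice_max_reference(volume: np.ndarray, voi: VoiBox) -> float:
    """Median over axial slices of the per-slice maximum within the VOI.

    For an even number of slices the mean of the two central values is
    used (standard median convention).
    """
    voi.check_within(volume.shape)
    sub = volume[voi.slices()]
    maxima = sub.max(axis=(0, 1))
    if np.all(sub == 0):
        raise ValueError("no signal inside the VOI")
    return float(np.median(maxima))


def threshold_carotid_mask(
    volume: np.ndarray,
    voi: VoiBox,
    threshold_pct: float = 42.0,
    voxel_size_mm=(1.0, 1.0, 1.0),
    min_component_voxels: int = 0,
) -> Mask3D:
    """Binarise at threshold_pct % of the slice-max-median reference.

    Voxels strictly above the threshold and inside the VOI are kept;
    everything outside the VOI is zero.  Optionally drops connected
    components smaller than ``min_component_voxels`` (off by default).
    """
    reference = slice_max_reference(volume, voi)
    cut = (threshold_pct / 100.0) * reference
    mask = np.zeros(volume.shape, dtype=bool)
    sl = voi.slices()
    mask[sl] = volume[sl] > cut
    if min_component_voxels > 0 and mask.any():
        labels, n = ndimage.label(mask)
        keep = np.flatnonzero(np.bincount(labels.ravel())[1:] >= min_component_voxels) + 1
        mask = np.isin(labels, keep)
    if not mask.any():
        raise ValueError(
            f"empty carotid mask at threshold {threshold_pct}% (reference {reference:g})"
        )
    return Mask3D(mask.astype(int), voxel_size_mm)


def extract_tac(image: DynamicImage, mask: Mask3D) -> TimeSeriesCurve:
    """Mean activity over the mask per frame, stamped at frame mid-times."""
    if mask.voxels.shape != image.shape3:
        raise ValueError("mask and image grids differ")
    if not mask.voxels.any():
        raise ValueError("mask is empty")
    values = image.voxels[mask.voxels].mean(axis=0)
    return TimeSeriesCurve(frame_mid_times(image.schedule), values)


def segment_carotids(
    image: DynamicImage, config: SegmentationConfig
) -> tuple[Mask3D, TimeSeriesCurve, np.ndarray]:
    """Full segmentation: neck crop, frame average, threshold, TAC.

    The mask is built on the cropped neck volume and re-embedded into the
    full grid before TAC extraction.  Returns (mask, carotid TAC, the
    averaged early-frame volume on the full grid).
    """
    neck, neck_box = crop_neck(image)
    voi = config.voi if config.voi is not None else VoiBox.full(neck.shape3)
    voi.check_within(neck.shape3)
    avg = average_frames(neck, config.early_frame_indices)
    neck_mask = threshold_carotid_mask(
        avg,
        voi,
        config.threshold_pct,
        image.voxel_size_mm,
        config.min_component_voxels,
    )
    full = np.zeros(image.shape3, dtype=int)
    full[:, :, : neck_box.z1] = neck_mask.voxels
    mask = Mask3D(full, image.voxel_size_mm)
    tac = extract_tac(image, mask)
    avg_full = np.zeros(image.shape3)
    avg_full[:, :, : neck_box.z1] = avg
    return mask, tac, avg_full
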