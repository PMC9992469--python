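"""Domain containers and file I/O for dynamic PET volumes, masks and curves.

Conventions
-----------
* Activity concentration is always Bq/ml; times are seconds.
* Images are kept in a canonical voxel-axis order: the third axis is the
  axial (inferior-superior) direction with the inferior (neck) end at
  index 0.  ``read_dynamic`` reorients arbitrary NIfTI orientations into
  this frame via the closest-canonical (RAS) transform.
* Frame timing travels in a JSON sidecar (``frame_start_s`` /
  ``frame_duration_s``) because NIfTI-1 has no standard per-frame timing.
* Curves are TSV with header columns ``time_s`` and ``activity_Bq_ml``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """A file's structure does not match the expected layout."""


@dataclass(frozen=True)
class FrameSchedule:
    """Per-frame acquisition timing: start times and durations in seconds."""

    start_s: np.ndarray
    duration_s: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.start_s, dtype=float)
        dur = np.asarray(self.duration_s, dtype=float)
        object.__setattr__(self, "start_s", start)
        object.__setattr__(self, "duration_s", dur)
        if start.ndim != 1 or dur.ndim != 1 or len(start) != len(dur):
            raise ValueError("start_s and duration_s must be 1-D and equal length")
        if len(start) == 0:
            return
        if np.any(dur <= 0):
            raise ValueError("frame durations must be positive")
        if np.any(np.diff(start) < 0):
            raise ValueError("frame start times must be non-decreasing")
        if np.any(start[1:] - (start[:-1] + dur[:-1]) < -1e-6):
            raise ValueError("frames must not overlap")

    def __len__(self) -> int:
        return len(self.start_s)

    @property
    def end_s(self) -> np.ndarray:
        return self.start_s + self.duration_s

    @property
    def span_s(self) -> float:
        """Total time covered, from first frame start to last frame end."""
        if len(self) == 0:
            return 0.0
        return float(self.end_s[-1] - self.start_s[0])

    @classmethod
    def from_durations(cls, durations_s, t0: float = 0.0) -> "FrameSchedule":
        """Build a contiguous schedule from a list of durations."""
        dur = np.asarray(durations_s, dtype=float)
        start = t0 + np.concatenate([[0.0], np.cumsum(dur)[:-1]])
        return cls(start, dur)


def default_frame_schedule() -> FrameSchedule:
    """The 26-frame variable-duration schedule used throughout:
    8x5 s, 4x10 s, 1x15 s, 4x20 s, 2x30 s, 7x60 s (655 s total)."""
    durations = [5.0] * 8 + [10.0] * 4 + [15.0] + [20.0] * 4 + [30.0] * 2 + [60.0] * 7
    return FrameSchedule.from_durations(durations)


def frame_mid_times(schedule: FrameSchedule) -> np.ndarray:
    """Frame mid-point times, start + duration/2, in seconds."""
    return schedule.start_s + schedule.duration_s / 2.0


@dataclass
class DynamicImage:
    """4-D activity-concentration volume (x, y, axial, frame) in Bq/ml."""

    voxels: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    schedule: FrameSchedule

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 4:
            raise ValueError(f"expected a 4-D array, got {self.voxels.ndim}-D")
        if self.voxels.shape[3] != len(self.schedule):
            raise SchemaError(
                f"frame axis length {self.voxels.shape[3]} does not match "
                f"schedule length {len(self.schedule)}"
            )
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("image contains non-finite values")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)

    @property
    def shape3(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.voxels.shape[3]


@dataclass
class Mask3D:
    """Binary volume on the image grid."""

    voxels: np.ndarray
    voxel_size_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError(f"expected a 3-D array, got {vox.ndim}-D")
        uniq = np.unique(vox)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be 0 or 1")
        self.voxels = vox.astype(bool)
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


@dataclass
class TimeSeriesCurve:
    """Time-stamped activity curve (times s, values Bq/ml)."""

    time_s: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        v = np.asarray(self.value, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or len(t) != len(v):
            raise ValueError("time_s and value must be 1-D and equal length")
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(v)) or not np.all(np.isfinite(t)):
            raise ValueError("curve contains non-finite values")
        self.time_s = t
        self.value = v

    def __len__(self) -> int:
        return len(self.time_s)

    def interp(self, times) -> np.ndarray:
        """Linear interpolation, constant extrapolation at the ends."""
        return np.interp(np.asarray(times, dtype=float), self.time_s, self.value)


# ---------------------------------------------------------------------------
# NIfTI images
# ---------------------------------------------------------------------------


def _canonical_data(img: nib.Nifti1Image) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Reorient to RAS (closest canonical): third axis axial, inferior at 0."""
    can = nib.as_closest_canonical(img)
    data = np.asarray(can.dataobj, dtype=float)
    zooms = can.header.get_zooms()[:3]
    return data, tuple(float(z) for z in zooms)


def read_schedule(path) -> FrameSchedule:
    """Read a frame-timing JSON sidecar (frame_start_s / frame_duration_s)."""
    with open(path) as fh:
        meta = json.load(fh)
    for key in ("frame_start_s", "frame_duration_s"):
        if key not in meta:
            raise SchemaError(f"schedule sidecar is missing key {key!r}")
    return FrameSchedule(meta["frame_start_s"], meta["frame_duration_s"])


def write_schedule(schedule: FrameSchedule, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "frame_start_s": schedule.start_s.tolist(),
                "frame_duration_s": schedule.duration_s.tolist(),
            },
            fh,
            indent=1,
        )


def read_dynamic(image_path, schedule_path) -> DynamicImage:
    """Read a 4-D NIfTI plus its JSON frame-timing sidecar.

    The volume is reoriented into the canonical axis order and the frame
    count is checked against the sidecar.
    """
    img = nib.load(str(image_path))
    if img.ndim != 4:
        raise ValueError(f"expected a 4-D image, got {img.ndim}-D")
    data, zooms = _canonical_data(img)
    schedule = read_schedule(schedule_path)
    if data.shape[3] != len(schedule):
        raise SchemaError(
            f"image has {data.shape[3]} frames but schedule lists {len(schedule)}"
        )
    return DynamicImage(data, zooms, schedule)


def write_dynamic(image: DynamicImage, image_path, schedule_path=None) -> None:
    write_volume(image.voxels, image.voxel_size_mm, image_path)
    if schedule_path is not None:
        write_schedule(image.schedule, schedule_path)


def write_volume(volume: np.ndarray, voxel_size_mm, path) -> None:
    """Write a 3-D/4-D array as NIfTI-1 with a diagonal RAS affine."""
    volume = np.asarray(volume)
    if not np.all(np.isfinite(volume)):
        raise ValueError("volume contains non-finite values")
    if volume.ndim not in (3, 4):
        raise ValueError("only 3-D or 4-D volumes are supported")
    affine = np.diag(list(voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(volume.astype(np.float64), affine), str(path))


def read_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a 3-D (or 4-D) NIfTI in canonical orientation."""
    img = nib.load(str(path))
    return _canonical_data(img)


def read_mask(path) -> Mask3D:
    data, zooms = read_volume(path)
    return Mask3D(np.rint(data).astype(int), zooms)


def write_mask(mask: Mask3D, path) -> None:
    affine = np.diag(list(mask.voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(mask.voxels.astype(np.uint8), affine), str(path))


# ---------------------------------------------------------------------------
# Curves (TSV)
# ---------------------------------------------------------------------------

_CURVE_COLUMNS = ("time_s", "activity_Bq_ml")


def read_curve(path) -> TimeSeriesCurve:
    """Read a TSV curve with columns ``time_s`` and ``activity_Bq_ml``."""
    df = pd.read_csv(path, sep="\t")
    for col in _CURVE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"curve file is missing column {col!r}")
    df = df.sort_values("time_s")
    if df["time_s"].duplicated().any():
        raise ValueError("curve contains duplicated time stamps")
    return TimeSeriesCurve(df["time_s"].to_numpy(), df["activity_Bq_ml"].to_numpy())


def write_curve(curve: TimeSeriesCurve, path) -> None:
    pd.DataFrame({"time_s": curve.time_s, "activity_Bq_ml": curve.value}).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
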