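"""Basis-function single-tissue-compartment fitting of CBF.

The model is dC_T/dt = F*C_a - k2*C_T with k2 = F/Vd, i.e.
C_T(t) = F * (C_a conv exp(-k2 t)).  For each k2 on a fixed grid the
convolution basis B(t; k2) is precomputed once from the input function
(exact piecewise-linear convolution on a fine grid, then frame
averaged), reducing the fit per region or voxel to a family of
1-parameter weighted linear least-squares problems; the k2 with the
smallest weighted residual sum of squares wins.  For water, extraction
is ~1 so K1 equals perfusion F.

Units: F and k2 are carried in per-minute units externally
(ml/cm^3/min, 1/min) and converted to per-second internally to match
the second-based time axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from widif.image_io import DynamicImage, FrameSchedule, Mask3D, TimeSeriesCurve, frame_mid_times
from widif.phantom import expconv

DEFAULT_K2_GRID_PER_MIN = np.logspace(np.log10(0.01), np.log10(3.0), 100)
DEFAULT_FIT_WINDOW_S = 300.0


@dataclass
class BasisSet:
    """Precomputed frame-averaged convolution bases over a k2 grid."""

    k2_grid_per_min: np.ndarray
    basis: np.ndarray  # (n_frames, n_k2), frame-averaged C_a conv exp(-k2 t)
    frame_mid_s: np.ndarray
    frame_duration_s: np.ndarray
    input_curve: TimeSeriesCurve
    fine_times_s: np.ndarray


@dataclass
class KineticResult:
    """Fitted single-tissue-compartment parameters for one TAC."""

    flow_ml_per_cm3_min: float
    vd_ml_per_cm3: float
    k2_per_min: float
    weighted_rss: float
    n_frames_used: int
    delay_s: float = 0.0
    clamped: bool = False


def make_basis(
    input_curve: TimeSeriesCurve,
    schedule: FrameSchedule,
    k2_grid_per_min=None,
    fine_dt_s: float = 0.5,
) -> BasisSet:
    """Build the basis set B_i = frame-average of C_a conv exp(-k2_i t).

    The input curve must cover the schedule span; it is resampled onto a
    uniform fine grid (default 0.5 s) where the exponential convolution
    is evaluated exactly for the piecewise-linear interpolant, then
    averaged over each frame interval.
    """
    if k2_grid_per_min is None:
        k2_grid_per_min = DEFAULT_K2_GRID_PER_MIN
    k2 = np.asarray(k2_grid_per_min, dtype=float)
    if np.any(k2 < 0) or np.any(np.diff(k2) <= 0):
        raise ValueError("k2 grid must be non-negative and strictly increasing")
    end = schedule.end_s[-1]
    mids = frame_mid_times(schedule)
    # frame-mid-sampled curves (IDIF/BSIF) cover only up to the last mid
    # time; values are extrapolated as constant over the last half frame
    if input_curve.time_s[-1] < mids[-1] - 1e-6:
        raise ValueError("input curve does not cover the frame schedule span")
    t_fine = np.arange(0.0, end + fine_dt_s, fine_dt_s)
    c_fine = input_curve.interp(t_fine)
    conv = expconv(t_fine, c_fine, k2 / 60.0)  # (n_fine, n_k2)

    n_frames = len(schedule)
    basis = np.empty((n_frames, len(k2)))
    # frame-average the fine-grid bases by trapezoid over each interval
    for i, (s, d) in enumerate(zip(schedule.start_s, schedule.duration_s)):
        sel = (t_fine >= s - 1e-9) & (t_fine <= s + d + 1e-9)
        tt = t_fine[sel]
        basis[i] = np.trapezoid(conv[sel], tt, axis=0) / (tt[-1] - tt[0])
    return BasisSet(
        k2_grid_per_min=k2,
        basis=basis,
        frame_mid_s=frame_mid_times(schedule),
        frame_duration_s=schedule.duration_s.copy(),
        input_curve=input_curve,
        fine_times_s=t_fine,
    )


def _fit_window(basis: BasisSet, fit_window_s: float):
    sel = basis.frame_mid_s <= fit_window_s
    if not sel.any():
        raise ValueError("no frames inside the fit window")
    return sel


def fit_1tcm(
    tac: TimeSeriesCurve,
    basis: BasisSet,
    weights=None,
    fit_window_s: float = DEFAULT_FIT_WINDOW_S,
) -> KineticResult:
    """Fit one TAC: weighted linear LS in F for each k2, pick best k2.

    Frames with mid-time beyond ``fit_window_s`` (default 300 s — only
    the early part of the scan carries flow information for water) are
    excluded.  Weights default to frame durations.  A negative fitted F
    is clamped to zero and flagged.
    """
    if not np.allclose(tac.time_s, basis.frame_mid_s):
        raise ValueError("TAC must be sampled at the basis frame mid-times")
    sel = _fit_window(basis, fit_window_s)
    y = tac.value[sel]
    b = basis.basis[sel]  # (n_sel, n_k2)
    w = basis.frame_duration_s[sel] if weights is None else np.asarray(weights)[sel]
    if np.all(y == 0):
        return KineticResult(0.0, np.nan, np.nan, 0.0, int(sel.sum()), clamped=True)
    if np.all(basis.input_curve.value == 0):
        raise ValueError("input curve is identically zero")

    bwb = np.einsum("fk,f,fk->k", b, w, b)
    bwy = np.einsum("fk,f,f->k", b, w, y)
    with np.errstate(divide="ignore", invalid="ignore"):
        coef = np.where(bwb > 0, bwy / bwb, 0.0)
    rss = float(np.dot(w, y**2)) - coef * bwy  # = sum w (y - c b)^2 at optimum
    best = int(np.argmin(rss))
    f_per_s = coef[best]
    clamped = False
    if f_per_s < 0:
        f_per_s, clamped = 0.0, True
    k2 = float(basis.k2_grid_per_min[best])
    flow = f_per_s * 60.0
    vd = flow / k2 if k2 > 0 else np.inf
    return KineticResult(
        flow_ml_per_cm3_min=float(flow),
        vd_ml_per_cm3=float(vd),
        k2_per_min=k2,
        weighted_rss=float(rss[best]),
        n_frames_used=int(sel.sum()),
        clamped=clamped,
    )


def fit_1tcm_voxelwise(
    image: DynamicImage,
    input_curve: TimeSeriesCurve,
    brain_mask: Mask3D,
    k2_grid_per_min=None,
    fit_window_s: float = DEFAULT_FIT_WINDOW_S,
):
    """Voxelwise fit sharing a single basis set; returns (F, Vd, k2) maps.

    Voxels outside the mask are zero in all three maps.  The per-voxel
    problem is solved for all voxels at once per k2 (closed-form
    1-parameter weighted LS), so the cost is one (n_vox x n_k2) pass.
    """
    if not brain_mask.voxels.any():
        raise ValueError("brain mask is empty")
    basis = make_basis(input_curve, image.schedule, k2_grid_per_min)
    sel = _fit_window(basis, fit_window_s)
    b = basis.basis[sel]
    w = basis.frame_duration_s[sel]
    y = image.voxels[brain_mask.voxels][:, sel]  # (n_vox, n_sel)

    bwb = np.einsum("fk,f,fk->k", b, w, b)  # (n_k2,)
    bwy = y * w[None, :] @ b  # (n_vox, n_k2)
    with np.errstate(divide="ignore", invalid="ignore"):
        coef = np.where(bwb[None, :] > 0, bwy / bwb[None, :], 0.0)
    ywy = (y**2 * w[None, :]).sum(axis=1)  # (n_vox,)
    rss = ywy[:, None] - coef * bwy
    best = np.argmin(rss, axis=1)
    f_per_s = np.clip(coef[np.arange(len(best)), best], 0.0, None)
    k2_best = basis.k2_grid_per_min[best]
    flow = f_per_s * 60.0
    with np.errstate(divide="ignore", invalid="ignore"):
        vd = np.where(k2_best > 0, flow / k2_best, 0.0)

    shape = image.shape3
    f_map = np.zeros(shape)
    vd_map = np.zeros(shape)
    k2_map = np.zeros(shape)
    f_map[brain_mask.voxels] = flow
    vd_map[brain_mask.voxels] = vd
    k2_map[brain_mask.voxels] = np.where(flow > 0, k2_best, 0.0)
    return f_map, vd_map, k2_map


def region_mean(volume: np.ndarray, mask: Mask3D) -> float:
    """Unweighted mean of a map over a binary region."""
    if not mask.voxels.any():
        raise ValueError("mask is empty")
    return float(np.asarray(volume)[mask.voxels].mean())
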