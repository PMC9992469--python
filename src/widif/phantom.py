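"""Digital phantoms for dynamic brain PET and the static tube validation.

The dynamic phantom emulates a 15O-water head/neck acquisition: two
carotid-like tubes carrying a bolus-shaped arterial curve, brain tissue
(grey-matter shell, white-matter core) obeying single-tissue-compartment
kinetics, low-flow neck soft tissue, Gaussian point-spread blurring,
frame averaging over a variable-duration schedule, and frame-duration
dependent Gaussian noise.  The static phantom is a 6-mm activity-filled
tube in a zero-activity water cylinder, used to validate the threshold +
partial-volume-correction chain against a known concentration.

All simulation is performed at the image level (no sinogram physics):
the scanner point-spread function is modelled as a stationary separable
Gaussian applied to the noise-free activity distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from widif.curves import frame_average_curve
from widif.image_io import (
    DynamicImage,
    FrameSchedule,
    Mask3D,
    TimeSeriesCurve,
    default_frame_schedule,
)
from widif.pvc import gaussian_smooth

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class InputFunctionModel:
    """Gamma-variate bolus plus exponential recirculation tail.

    The first-pass bolus is the peak-normalised gamma variate
    ``A * x**shape * exp(shape*(1-x))`` with ``x = (t-t0)/(shape*scale)``,
    so the peak value is exactly A at ``t = t0 + shape*scale``.  The
    recirculation tail rises with the bolus time constant and decays
    slowly: ``tail_fraction*A*(1-exp(-(t-t0)/scale))*exp(-tail_decay*(t-t0))``.
    """

    amplitude: float = 50_000.0  # Bq/ml at the bolus peak
    t0_s: float = 10.0  # tracer appearance time
    shape: float = 3.0
    scale_s: float = 5.0  # peak at t0 + shape*scale = 25 s
    tail_fraction: float = 0.15
    tail_decay_per_s: float = 0.004

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.scale_s <= 0:
            raise ValueError("scale must be positive")
        if not 0 <= self.tail_fraction < 1:
            raise ValueError("tail_fraction must be in [0, 1)")


def model_input_function(model: InputFunctionModel, times) -> TimeSeriesCurve:
    """Evaluate the arterial input model at the given times (s)."""
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    dt = t - model.t0_s
    out = np.zeros_like(t)
    pos = dt > 0
    x = dt[pos] / (model.shape * model.scale_s)
    bolus = model.amplitude * x**model.shape * np.exp(model.shape * (1.0 - x))
    tail = (
        model.tail_fraction
        * model.amplitude
        * (1.0 - np.exp(-dt[pos] / model.scale_s))
        * np.exp(-model.tail_decay_per_s * dt[pos])
    )
    out[pos] = bolus + tail
    return TimeSeriesCurve(t, out)


def expconv(times, values, k_per_s):
    """Convolution ``(C * k-kernel)``: y(t) = int_0^t C(s) exp(-k (t-s)) ds.

    Exact for a piecewise-linear C between the sample times; this is the
    workhorse for both tissue simulation and the basis-function fit.
    ``k_per_s`` may be a scalar or a 1-D grid; the result then has shape
    (n_times,) or (n_times, n_k).
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(values, dtype=float)
    k = np.atleast_1d(np.asarray(k_per_s, dtype=float))
    if np.any(k < 0):
        raise ValueError("rate constants must be non-negative")
    n = len(t)
    y = np.zeros((n, len(k)))
    small = k < 1e-12
    for i in range(n - 1):
        dt = t[i + 1] - t[i]
        a, b = c[i], c[i + 1]
        e = np.exp(-k * dt)
        with np.errstate(divide="ignore", invalid="ignore"):
            seg = a * (1.0 - e) / k + (b - a) / dt * (dt / k - (1.0 - e) / k**2)
        # k -> 0 limit: plain trapezoid of the segment
        seg[small] = 0.5 * (a + b) * dt
        y[i + 1] = y[i] * e + seg
    if np.isscalar(k_per_s) or np.ndim(k_per_s) == 0:
        return y[:, 0]
    return y


def tissue_response(
    input_curve: TimeSeriesCurve,
    flow_ml_per_cm3_min: float,
    vd_ml_per_cm3: float,
    times=None,
) -> TimeSeriesCurve:
    """Single-tissue-compartment response to an arterial input.

    ``C_T(t) = F int_0^t C_a(s) exp(-(F/Vd)(t-s)) ds`` with F converted
    to per-second units internally.  Evaluated on ``times`` (default: the
    input curve's own grid, which should be dense, <= 0.5 s steps).
    """
    if flow_ml_per_cm3_min <= 0 or vd_ml_per_cm3 <= 0:
        raise ValueError("F and Vd must be positive")
    if times is None:
        t = input_curve.time_s
        c = input_curve.value
    else:
        t = np.asarray(times, dtype=float)
        c = input_curve.interp(t)
    f_per_s = flow_ml_per_cm3_min / 60.0
    k2_per_s = f_per_s / vd_ml_per_cm3
    return TimeSeriesCurve(t, f_per_s * expconv(t, c, k2_per_s))


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------


def _fine_disk_indicator(shape_xy, voxel_xy_mm, centers_mm, radius_mm, supersample=8):
    """Supersampled in-plane indicator of one or more disks.

    Returns the (nx*s, ny*s) binary array sampled at sub-voxel centres
    (voxel centre at index*d), used both for partial-volume-accurate
    fractional maps and for continuous-space blurring.
    """
    nx, ny = shape_xy
    dx, dy = voxel_xy_mm
    s = int(supersample)
    off = (np.arange(s) + 0.5) / s - 0.5
    xs = (np.arange(nx)[:, None] + off[None, :]).reshape(-1) * dx
    ys = (np.arange(ny)[:, None] + off[None, :]).reshape(-1) * dy
    fine = np.zeros((nx * s, ny * s), dtype=bool)
    for cx, cy in centers_mm:
        fine |= (xs[:, None] - cx) ** 2 + (ys[None, :] - cy) ** 2 <= radius_mm**2
    return fine


def _downsample2d(fine: np.ndarray, supersample: int) -> np.ndarray:
    s = int(supersample)
    nx, ny = fine.shape[0] // s, fine.shape[1] // s
    return fine.reshape(nx, s, ny, s).mean(axis=(1, 3)).astype(float)


def _disk_fraction(shape_xy, voxel_xy_mm, center_mm, radius_mm, supersample=8):
    """In-plane area fraction of each voxel covered by a disk."""
    fine = _fine_disk_indicator(shape_xy, voxel_xy_mm, [center_mm], radius_mm, supersample)
    return _downsample2d(fine, supersample)


def _blurred_disk_fraction(
    shape_xy, voxel_xy_mm, centers_mm, radius_mm, fwhm_mm, supersample=8
):
    """Disks blurred in continuous space: supersample the indicator, apply
    the Gaussian at sub-voxel resolution, then average back to the grid.

    The point-spread function acts on the underlying activity
    distribution, not on the voxelised image, so the blur is applied
    before downsampling (requires isotropic in-plane voxels)."""
    fine = _fine_disk_indicator(shape_xy, voxel_xy_mm, centers_mm, radius_mm, supersample).astype(float)
    if fwhm_mm > 0:
        d = voxel_xy_mm[0] / supersample
        sigma = (fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))) / d
        from scipy import ndimage

        fine = ndimage.gaussian_filter(fine, sigma=sigma, mode="nearest", truncate=4.0)
    return _downsample2d(fine, supersample)


def _ellipsoid_mask(shape, voxel_mm, center_mm, radii_mm):
    coords = [
        (np.arange(n) * d - c) / r
        for n, d, c, r in zip(shape, voxel_mm, center_mm, radii_mm)
    ]
    xx = coords[0][:, None, None] ** 2
    yy = coords[1][None, :, None] ** 2
    zz = coords[2][None, None, :] ** 2
    return (xx + yy + zz) <= 1.0


# ---------------------------------------------------------------------------
# Dynamic phantom
# ---------------------------------------------------------------------------


@dataclass
class DynamicPhantomSpec:
    """Geometry, kinetics and acquisition settings for the dynamic phantom.

    Defaults mimic the target acquisition: ~5.5 mm carotid tubes on a
    0.98 x 0.98 x 2.79 mm grid, 2.3 mm FWHM effective resolution, and the
    26-frame variable-duration schedule.  Brain flow defaults are
    physiological grey/white-matter values (F in ml/cm^3/min, Vd in
    ml/cm^3).
    """

    grid_shape: tuple[int, int, int] = (96, 96, 48)
    voxel_size_mm: tuple[float, float, float] = (0.98, 0.98, 2.79)
    tube_diameter_mm: float = 5.5
    tube_separation_mm: float = 24.0
    tube_z_extent: tuple[int, int] = (0, 30)  # half-open slice range
    regions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "gm": (0.64, 0.9),
            "wm": (0.20, 0.8),
            "neck": (0.05, 0.8),
        }
    )
    psf_fwhm_mm: float = 2.3
    noise_scale: float = 30.0
    schedule: FrameSchedule = field(default_factory=default_frame_schedule)
    input_model: InputFunctionModel = field(default_factory=InputFunctionModel)
    seed: int = 0
    fine_dt_s: float = 0.5
    supersample: int = 8

    def __post_init__(self) -> None:
        if self.tube_diameter_mm <= 0:
            raise ValueError("tube diameter must be positive")
        for name, (f, vd) in self.regions.items():
            if f <= 0 or vd <= 0:
                raise ValueError(f"region {name!r}: F and Vd must be positive")
        if self.psf_fwhm_mm < 0:
            raise ValueError("psf_fwhm_mm must be non-negative")


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom."""

    input_curve: TimeSeriesCurve  # fine time grid
    carotid_mask: Mask3D
    tube_fraction: np.ndarray
    f_map: np.ndarray
    vd_map: np.ndarray
    region_masks: dict[str, np.ndarray]
    noise_free_image: DynamicImage


def _phantom_geometry(spec: DynamicPhantomSpec):
    """Fractional tube map and binary region masks on the phantom grid.

    Objects are centred on the central voxel centre (clean symmetric
    geometry); the two tubes sit at +- half the separation along x.
    """
    nx, ny, nz = spec.grid_shape
    dx, dy, dz = spec.voxel_size_mm
    cx, cy = (nx // 2) * dx, (ny // 2) * dy
    radius = spec.tube_diameter_mm / 2.0
    half_sep = spec.tube_separation_mm / 2.0
    centers = [(cx - half_sep, cy), (cx + half_sep, cy)]

    fine = _fine_disk_indicator((nx, ny), (dx, dy), centers, radius, spec.supersample)
    tube2d = _downsample2d(fine, spec.supersample)
    tube_frac = np.zeros(spec.grid_shape)
    z0, z1 = spec.tube_z_extent
    tube_frac[:, :, z0:z1] = tube2d[:, :, None]
    if radius * 2 < 2 * min(dx, dy):
        warnings.warn("tube diameter below two in-plane voxels: sub-resolution object")

    masks: dict[str, np.ndarray] = {}
    # brain: ellipsoid in the upper part of the FoV; GM = shell, WM = core
    if "gm" in spec.regions or "wm" in spec.regions:
        bc = (cx, cy, (nz - 10) * dz)
        outer = _ellipsoid_mask(
            spec.grid_shape, spec.voxel_size_mm, bc, (0.38 * nx * dx, 0.38 * ny * dy, 11 * dz)
        )
        inner = _ellipsoid_mask(
            spec.grid_shape, spec.voxel_size_mm, bc, (0.24 * nx * dx, 0.24 * ny * dy, 7 * dz)
        )
        if "gm" in spec.regions:
            masks["gm"] = outer & ~inner
        if "wm" in spec.regions:
            masks["wm"] = inner
    # neck soft tissue: cylinder around the tubes over the tube extent
    if "neck" in spec.regions:
        neck2d = _disk_fraction(
            (nx, ny), (dx, dy), (cx, cy), 0.40 * nx * dx, supersample=2
        ) > 0.5
        neck = np.zeros(spec.grid_shape, dtype=bool)
        neck[:, :, z0:z1] = neck2d[:, :, None]
        neck &= tube_frac < 1e-9
        for m in masks.values():
            neck &= ~m
        masks["neck"] = neck
    return tube_frac, masks


def generate_dynamic_phantom(spec: DynamicPhantomSpec):
    """Simulate a dynamic scan; returns ``(DynamicImage, PhantomTruth)``.

    Pipeline: noise-free fractional truth (tubes carry the arterial curve,
    tissue regions carry their compartment response) -> separable Gaussian
    blur at ``psf_fwhm_mm`` -> average over frame intervals -> additive
    zero-mean Gaussian noise with SD = noise_scale * sqrt(max(v,0)/dur).
    Blur and frame averaging are both linear, so they are applied to the
    per-region frame-averaged values and mixed through the fraction maps.
    """
    sched = spec.schedule
    t_fine = np.arange(0.0, sched.span_s + spec.fine_dt_s, spec.fine_dt_s)
    c_a = model_input_function(spec.input_model, t_fine)

    tube_frac, region_masks = _phantom_geometry(spec)
    # tissue fractions: regions are binary and disjoint from the tubes
    frame_values = {"tube": frame_average_curve(c_a, sched)}
    for name, (f, vd) in spec.regions.items():
        if name in region_masks:
            ct = tissue_response(c_a, f, vd)
            frame_values[name] = frame_average_curve(ct, sched)

    # Blur each (time-independent) component map once; frames are linear
    # mixtures of the maps, so this equals blurring every frame.  The tube
    # boundary is blurred in continuous space (supersampled indicator).
    blurred = {}
    if spec.psf_fwhm_mm > 0:
        nx, ny, _ = spec.grid_shape
        dx, dy, dz = spec.voxel_size_mm
        cx, cy = (nx // 2) * dx, (ny // 2) * dy
        half_sep = spec.tube_separation_mm / 2.0
        tube2d_blur = _blurred_disk_fraction(
            (nx, ny),
            (dx, dy),
            [(cx - half_sep, cy), (cx + half_sep, cy)],
            spec.tube_diameter_mm / 2.0,
            spec.psf_fwhm_mm,
            spec.supersample,
        )
        tube_blur = np.zeros(spec.grid_shape)
        z0, z1 = spec.tube_z_extent
        tube_blur[:, :, z0:z1] = tube2d_blur[:, :, None]
        sigma_z = (spec.psf_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))) / dz
        from scipy import ndimage

        blurred["tube"] = ndimage.gaussian_filter1d(
            tube_blur, sigma=sigma_z, axis=2, mode="nearest", truncate=4.0
        )
        for name, mask in region_masks.items():
            blurred[name] = gaussian_smooth(
                mask.astype(float), spec.psf_fwhm_mm, spec.voxel_size_mm
            )
    else:
        blurred["tube"] = tube_frac
        for name, mask in region_masks.items():
            blurred[name] = mask.astype(float)

    nframes = len(sched)
    noise_free = np.zeros(spec.grid_shape + (nframes,))
    for j in range(nframes):
        frame = blurred["tube"] * frame_values["tube"][j]
        for name in region_masks:
            frame = frame + blurred[name] * frame_values[name][j]
        noise_free[..., j] = frame

    rng = np.random.default_rng(spec.seed)
    if spec.noise_scale > 0:
        sd = spec.noise_scale * np.sqrt(
            np.maximum(noise_free, 0.0) / sched.duration_s[None, None, None, :]
        )
        voxels = noise_free + rng.standard_normal(noise_free.shape) * sd
    else:
        voxels = noise_free.copy()

    f_map = np.zeros(spec.grid_shape)
    vd_map = np.zeros(spec.grid_shape)
    for name, mask in region_masks.items():
        f, vd = spec.regions[name]
        f_map[mask] = f
        vd_map[mask] = vd

    truth = PhantomTruth(
        input_curve=c_a,
        carotid_mask=Mask3D((tube_frac >= 0.5).astype(int), spec.voxel_size_mm),
        tube_fraction=tube_frac,
        f_map=f_map,
        vd_map=vd_map,
        region_masks=region_masks,
        noise_free_image=DynamicImage(noise_free, spec.voxel_size_mm, sched),
    )
    return DynamicImage(voxels, spec.voxel_size_mm, sched), truth


# ---------------------------------------------------------------------------
# Static tube phantom
# ---------------------------------------------------------------------------


@dataclass
class StaticPhantomSpec:
    """6-mm activity-filled tube submerged in a zero-activity water cylinder."""

    tube_diameter_mm: float = 6.0
    tube_concentration_bq_ml: float = 2.1e6
    cylinder_diameter_mm: float = 200.0
    background_bq_ml: float = 0.0
    grid_shape: tuple[int, int, int] = (64, 64, 24)
    voxel_size_mm: tuple[float, float, float] = (0.98, 0.98, 2.79)
    psf_fwhm_mm: float = 2.1
    noise_scale: float = 0.0
    seed: int = 0
    supersample: int = 8

    def __post_init__(self) -> None:
        if self.tube_diameter_mm <= 0:
            raise ValueError("tube diameter must be positive")


@dataclass
class StaticPhantomTruth:
    tube_fraction: np.ndarray
    tube_mask: Mask3D
    cylinder_mask: np.ndarray
    true_concentration_bq_ml: float
    unblurred: np.ndarray


def generate_static_tube_phantom(spec: StaticPhantomSpec):
    """Simulate the static validation phantom; returns ``(3-D array, truth)``.

    The tube runs parallel to the axial axis through the whole grid (the
    replicate boundary used by the smoothing makes this equivalent to the
    central portion of a longer tube).  The analytic tube boundary is
    handled by sub-voxel supersampling of the indicator before blurring.
    """
    nx, ny, nz = spec.grid_shape
    dx, dy, dz = spec.voxel_size_mm
    cx, cy = (nx // 2) * dx, (ny // 2) * dy
    frac2d = _disk_fraction(
        (nx, ny), (dx, dy), (cx, cy), spec.tube_diameter_mm / 2.0, spec.supersample
    )
    tube_frac = np.repeat(frac2d[:, :, None], nz, axis=2)
    cyl2d = _disk_fraction(
        (nx, ny), (dx, dy), (cx, cy), spec.cylinder_diameter_mm / 2.0, supersample=2
    ) > 0.5
    cylinder = np.repeat(cyl2d[:, :, None], nz, axis=2)

    unblurred = (
        spec.tube_concentration_bq_ml * tube_frac
        + spec.background_bq_ml * (cylinder & (tube_frac < 1e-9))
    )
    if spec.psf_fwhm_mm > 0:
        # blur the supersampled indicator (the PSF acts on the continuous
        # activity distribution), then average back to the voxel grid; the
        # tube is z-invariant so a 2-D in-plane blur is exact
        blur2d = _blurred_disk_fraction(
            (nx, ny),
            (dx, dy),
            [(cx, cy)],
            spec.tube_diameter_mm / 2.0,
            spec.psf_fwhm_mm,
            spec.supersample,
        )
        image = np.repeat(
            (spec.tube_concentration_bq_ml * blur2d)[:, :, None], nz, axis=2
        )
        if spec.background_bq_ml:
            bg = spec.background_bq_ml * (cylinder & (tube_frac < 1e-9)).astype(float)
            image = image + gaussian_smooth(bg, spec.psf_fwhm_mm, spec.voxel_size_mm)
    else:
        image = unblurred.copy()
    if spec.noise_scale > 0:
        rng = np.random.default_rng(spec.seed)
        image = image + rng.standard_normal(image.shape) * spec.noise_scale

    truth = StaticPhantomTruth(
        tube_fraction=tube_frac,
        tube_mask=Mask3D((tube_frac >= 0.5).astype(int), spec.voxel_size_mm),
        cylinder_mask=cylinder,
        true_concentration_bq_ml=spec.tube_concentration_bq_ml,
        unblurred=unblurred,
    )
    return image, truth
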