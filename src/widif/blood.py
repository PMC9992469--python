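"""Conditioning of blood-sampler curves (BSIF preparation).

An automated sampler measures whole-blood activity downstream of the
artery, so the raw curve must be (1) calibrated against discrete
well-counter samples, (2) corrected for dispersion in the tubing and
vasculature, modelled as convolution with a monoexponential kernel of
time constant tau (default 13 s), (3) shifted to remove the transit
delay relative to the brain, and (4) resampled to the PET frame times.
Image-derived input functions need none of these corrections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from widif.curves import frame_average_curve, windowed_integral
from widif.image_io import FrameSchedule, TimeSeriesCurve, frame_mid_times


@dataclass(frozen=True)
class DispersionModel:
    """Monoexponential dispersion: measured = true convolved with
    (1/tau) exp(-t/tau)."""

    tau_s: float = 13.0

    def __post_init__(self) -> None:
        if self.tau_s < 0:
            raise ValueError("tau must be non-negative")


@dataclass(frozen=True)
class CalibrationSample:
    """A discrete well-counter blood sample."""

    time_s: float
    activity_bq_ml: float


def calibrate_curve(
    curve: TimeSeriesCurve, samples: list[CalibrationSample]
) -> tuple[TimeSeriesCurve, float]:
    """Scale the sampler curve onto the well-counter samples.

    The factor is the mean over samples of (sample value / interpolated
    curve value); a single multiplicative factor is applied (mean of
    per-sample ratios, not a regression — typically only two samples
    exist).
    """
    if not samples:
        raise ValueError("at least one calibration sample required")
    ratios = []
    for s in samples:
        cv = float(curve.interp(s.time_s))
        if cv <= 0:
            raise ValueError(f"curve value at t={s.time_s}s is not positive")
        ratios.append(s.activity_bq_ml / cv)
    factor = float(np.mean(ratios))
    return TimeSeriesCurve(curve.time_s, curve.value * factor), factor


def dispersion_correct(curve: TimeSeriesCurve, model: DispersionModel) -> TimeSeriesCurve:
    """Invert monoexponential dispersion: c_true = c_meas + tau * dc/dt.

    The derivative is a 3-point central difference taken after a
    3-sample moving-average pre-smooth (the tau*dc/dt term amplifies
    sampler noise).  tau = 0 is the identity.
    """
    if len(curve) < 3:
        raise ValueError("need at least 3 samples for the derivative")
    if model.tau_s == 0:
        return TimeSeriesCurve(curve.time_s, curve.value.copy())
    v = curve.value
    smoothed = v.copy()
    smoothed[1:-1] = (v[:-2] + v[1:-1] + v[2:]) / 3.0
    deriv = np.gradient(smoothed, curve.time_s)
    return TimeSeriesCurve(curve.time_s, v + model.tau_s * deriv)


def disperse(curve: TimeSeriesCurve, model: DispersionModel) -> TimeSeriesCurve:
    """Forward model: convolve with (1/tau) exp(-t/tau) on the curve's grid.

    Exact for a piecewise-linear curve (used for simulation and the
    round-trip check of the correction).
    """
    from widif.phantom import expconv  # local import to avoid a cycle

    if model.tau_s == 0:
        return TimeSeriesCurve(curve.time_s, curve.value.copy())
    y = expconv(curve.time_s, curve.value, 1.0 / model.tau_s) / model.tau_s
    return TimeSeriesCurve(curve.time_s, y)


def estimate_delay(
    curve: TimeSeriesCurve,
    reference_tac: TimeSeriesCurve,
    delays=None,
    window_s: float = 60.0,
) -> float:
    """Grid-search alignment delay between sampler curve and a brain TAC.

    Both curves are peak-normalised; the delay (from a discrete grid,
    default -5..+15 s in 0.5 s steps) minimising the sum of squared
    differences over the first ``window_s`` seconds of overlap is
    returned.  Positive delay means the blood arrives at the sampler
    later than at the brain.
    """
    if delays is None:
        delays = np.arange(-5.0, 15.0 + 0.25, 0.5)
    delays = np.asarray(delays, dtype=float)
    lo = max(curve.time_s[0], reference_tac.time_s[0])
    hi = min(curve.time_s[-1], reference_tac.time_s[-1])
    if hi <= lo:
        raise ValueError("curve and reference do not overlap in time")
    hi = min(hi, lo + window_s)
    t_eval = np.linspace(lo, hi, 241)
    c_peak = np.abs(curve.value).max()
    r_peak = np.abs(reference_tac.value).max()
    if c_peak == 0 or r_peak == 0:
        raise ValueError("cannot align all-zero curves")
    ref = reference_tac.interp(t_eval) / r_peak
    costs = [
        float(np.sum((np.interp(t_eval + d, curve.time_s, curve.value) / c_peak - ref) ** 2))
        for d in delays
    ]
    return float(delays[int(np.argmin(costs))])


def shift_curve(curve: TimeSeriesCurve, delay_s: float) -> TimeSeriesCurve:
    """Shift the curve earlier by ``delay_s`` (positive measured delay).

    Values are re-interpolated onto the original time grid; times before
    the shifted support are zero-filled, and support that would move
    before t = 0 is truncated with a warning.
    """
    if delay_s == 0:
        return TimeSeriesCurve(curve.time_s, curve.value.copy())
    shifted_t = curve.time_s - delay_s
    if shifted_t[0] < 0 and curve.time_s[0] >= 0:
        warnings.warn("curve support truncated at t=0 after delay shift")
    values = np.interp(
        curve.time_s, shifted_t, curve.value, left=0.0, right=curve.value[-1]
    )
    return TimeSeriesCurve(curve.time_s, values)


def resample_to_frames(curve: TimeSeriesCurve, schedule: FrameSchedule) -> TimeSeriesCurve:
    """Average the curve over each frame interval, stamped at mid-times."""
    if schedule.start_s[0] < curve.time_s[0] - 1e-9 or schedule.end_s[-1] > curve.time_s[-1] + 1e-9:
        raise ValueError("schedule extends beyond curve support")
    return TimeSeriesCurve(frame_mid_times(schedule), frame_average_curve(curve, schedule))


def prepare_bsif(
    curve: TimeSeriesCurve,
    samples: list[CalibrationSample] | None,
    model: DispersionModel,
    schedule: FrameSchedule,
    reference_tac: TimeSeriesCurve | None = None,
) -> tuple[TimeSeriesCurve, dict]:
    """Full sampler-curve conditioning chain.

    Calibration (if samples given) -> dispersion correction -> delay
    estimation against a brain TAC (if given) and shift -> resampling to
    the frame schedule.  Returns the prepared curve and a report dict.
    """
    report: dict = {}
    out = curve
    if samples:
        out, factor = calibrate_curve(out, samples)
        report["calibration_factor"] = factor
    out = dispersion_correct(out, model)
    report["dispersion_tau_s"] = model.tau_s
    if reference_tac is not None:
        delay = estimate_delay(out, reference_tac)
        out = shift_curve(out, delay)
        report["delay_s"] = delay
    out = resample_to_frames(out, schedule)
    return out, report
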