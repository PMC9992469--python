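"""Shared curve arithmetic: windowed trapezoidal integrals and frame averages."""

from __future__ import annotations

import numpy as np

from widif.image_io import FrameSchedule, TimeSeriesCurve


def windowed_integral(curve: TimeSeriesCurve, t0: float, t1: float) -> float:
    """Integral of the linear interpolant of ``curve`` over [t0, t1].

    Endpoint values at exactly t0 and t1 are obtained by interpolation;
    the window must lie within the curve's support.
    """
    if t1 <= t0:
        raise ValueError("window end must exceed window start")
    t, v = curve.time_s, curve.value
    if t0 < t[0] - 1e-9 or t1 > t[-1] + 1e-9:
        raise ValueError(
            f"window [{t0}, {t1}] outside curve support [{t[0]}, {t[-1]}]"
        )
    inside = (t > t0) & (t < t1)
    tt = np.concatenate([[t0], t[inside], [t1]])
    vv = np.concatenate([[curve.interp(t0)], v[inside], [curve.interp(t1)]])
    return float(np.trapezoid(vv, tt))


def frame_average_curve(curve: TimeSeriesCurve, schedule: FrameSchedule) -> np.ndarray:
    """Time-average of the linear interpolant over each frame interval."""
    out = np.empty(len(schedule))
    for i, (s, d) in enumerate(zip(schedule.start_s, schedule.duration_s)):
        out[i] = windowed_integral(curve, s, s + d) / d
    return out
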