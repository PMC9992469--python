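"""Input-curve AUC metrics, threshold x kernel grid search, and agreement
statistics (Pearson, orthogonal/Deming regression, Bland-Altman, CoV).

The grid search reproduces the optimisation workflow: for every
combination of mask threshold and PVC kernel width, run segmentation ->
partial-volume correction -> corrected input curve -> grey-matter CBF,
and tabulate the relative bias of peak AUC (0-60 s), tail AUC
(60-300 s), peak-to-tail ratio and GM CBF against a reference input
function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from widif.curves import windowed_integral
from widif.image_io import DynamicImage, Mask3D, TimeSeriesCurve
from widif.kinetics import fit_1tcm, make_basis, region_mean
from widif.pvc import compute_pvc_factors, correct_blood_curve, sleeve_tissue_mask
from widif.segmentation import SegmentationConfig, extract_tac, segment_carotids

PEAK_WINDOW_S = (0.0, 60.0)
TAIL_WINDOW_S = (60.0, 300.0)


def auc(curve: TimeSeriesCurve, t0: float, t1: float) -> float:
    """Trapezoidal area under the linear interpolant over [t0, t1] (Bq*s/ml)."""
    return windowed_integral(curve, t0, t1)


def ensure_origin(curve: TimeSeriesCurve, value: float = 0.0) -> TimeSeriesCurve:
    """Prepend a t=0 sample if the curve starts later (frame-sampled TACs
    start at the first frame mid-time; the pre-bolus activity is zero)."""
    if curve.time_s[0] <= 0:
        return curve
    return TimeSeriesCurve(
        np.concatenate([[0.0], curve.time_s]), np.concatenate([[value], curve.value])
    )


@dataclass
class AucMetrics:
    """Peak/tail AUC of a curve and relative bias (%) vs a reference."""

    peak_auc: float
    tail_auc: float
    peak_to_tail: float
    peak_bias_pct: float
    tail_bias_pct: float
    ratio_bias_pct: float


def auc_metrics(test: TimeSeriesCurve, reference: TimeSeriesCurve) -> AucMetrics:
    """Peak (0-60 s) and tail (60-300 s) AUC bias of ``test`` vs ``reference``.

    Relative bias is 100 * (test - reference) / reference per metric.
    """
    t_peak = auc(test, *PEAK_WINDOW_S)
    t_tail = auc(test, *TAIL_WINDOW_S)
    r_peak = auc(reference, *PEAK_WINDOW_S)
    r_tail = auc(reference, *TAIL_WINDOW_S)
    if r_peak == 0 or r_tail == 0:
        raise ValueError("reference AUC is zero")
    if t_tail == 0:
        raise ValueError("test tail AUC is zero; peak-to-tail undefined")
    ratio, r_ratio = t_peak / t_tail, r_peak / r_tail
    return AucMetrics(
        peak_auc=t_peak,
        tail_auc=t_tail,
        peak_to_tail=ratio,
        peak_bias_pct=100.0 * (t_peak - r_peak) / r_peak,
        tail_bias_pct=100.0 * (t_tail - r_tail) / r_tail,
        ratio_bias_pct=100.0 * (ratio - r_ratio) / r_ratio,
    )


@dataclass
class GridSearchResult:
    """Bias tables over the threshold x kernel grid (rows = thresholds)."""

    thresholds_pct: np.ndarray
    kernels_mm: np.ndarray
    peak_bias_pct: np.ndarray
    tail_bias_pct: np.ndarray
    ratio_bias_pct: np.ndarray
    gm_cbf_bias_pct: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, th in enumerate(self.thresholds_pct):
            for j, k in enumerate(self.kernels_mm):
                rows.append(
                    {
                        "threshold_pct": th,
                        "kernel_mm": k,
                        "peak_bias_pct": self.peak_bias_pct[i, j],
                        "tail_bias_pct": self.tail_bias_pct[i, j],
                        "ratio_bias_pct": self.ratio_bias_pct[i, j],
                        "gm_cbf_bias_pct": self.gm_cbf_bias_pct[i, j],
                    }
                )
        return pd.DataFrame(rows)


def idif_from_mask(
    image: DynamicImage,
    mask: Mask3D,
    kernel_fwhm_mm: float,
    sleeve_inner: int = 8,
    sleeve_outer: int = 10,
):
    """Uncorrected carotid TAC, sleeve tissue TAC and PVC-corrected IDIF."""
    carotid_tac = extract_tac(image, mask)
    sleeve = sleeve_tissue_mask(mask, sleeve_inner, sleeve_outer)
    tissue_tac = extract_tac(image, sleeve)
    factors = compute_pvc_factors(mask, kernel_fwhm_mm)
    corrected = correct_blood_curve(carotid_tac, tissue_tac, factors)
    return carotid_tac, tissue_tac, corrected, factors


def grid_search(
    image: DynamicImage,
    reference_input: TimeSeriesCurve,
    config_template: SegmentationConfig,
    thresholds_pct=None,
    kernels_mm=None,
    gm_mask: Mask3D | None = None,
    fit_window_s: float = 300.0,
) -> GridSearchResult:
    """Sweep threshold x kernel and tabulate IDIF and GM CBF biases.

    Default ranges: thresholds 38-46% in 1% steps, kernels 2.0-2.4 mm in
    0.1 mm steps.  Cells whose mask comes out empty are NaN and the
    sweep continues.  The reference CBF is obtained by fitting the GM
    TAC with ``reference_input``.
    """
    thresholds = (
        np.arange(38.0, 46.0 + 0.5, 1.0) if thresholds_pct is None else np.asarray(thresholds_pct, float)
    )
    kernels = (
        np.arange(2.0, 2.4 + 0.05, 0.1) if kernels_mm is None else np.asarray(kernels_mm, float)
    )
    ref = ensure_origin(reference_input)

    gm_tac = extract_tac(image, gm_mask) if gm_mask is not None else None
    ref_cbf = np.nan
    if gm_tac is not None:
        ref_basis = make_basis(ref, image.schedule)
        ref_cbf = fit_1tcm(gm_tac, ref_basis, fit_window_s=fit_window_s).flow_ml_per_cm3_min

    shape = (len(thresholds), len(kernels))
    tables = {k: np.full(shape, np.nan) for k in ("peak", "tail", "ratio", "cbf")}
    for i, th in enumerate(thresholds):
        config = SegmentationConfig(
            early_frame_indices=list(config_template.early_frame_indices),
            threshold_pct=float(th),
            voi=config_template.voi,
            min_component_voxels=config_template.min_component_voxels,
        )
        try:
            mask, _, _ = segment_carotids(image, config)
        except ValueError:
            continue  # empty mask at this threshold: row stays NaN
        for j, kernel in enumerate(kernels):
            _, _, corrected, _ = idif_from_mask(image, mask, float(kernel))
            idif = ensure_origin(corrected)
            metrics = auc_metrics(idif, ref)
            tables["peak"][i, j] = metrics.peak_bias_pct
            tables["tail"][i, j] = metrics.tail_bias_pct
            tables["ratio"][i, j] = metrics.ratio_bias_pct
            if gm_tac is not None:
                basis = make_basis(idif, image.schedule)
                cbf = fit_1tcm(gm_tac, basis, fit_window_s=fit_window_s).flow_ml_per_cm3_min
                tables["cbf"][i, j] = 100.0 * (cbf - ref_cbf) / ref_cbf
    return GridSearchResult(
        thresholds_pct=thresholds,
        kernels_mm=kernels,
        peak_bias_pct=tables["peak"],
        tail_bias_pct=tables["tail"],
        ratio_bias_pct=tables["ratio"],
        gm_cbf_bias_pct=tables["cbf"],
    )


# ---------------------------------------------------------------------------
# Agreement statistics
# ---------------------------------------------------------------------------


@dataclass
class AgreementStats:
    """Pairwise agreement between two sets of measurements."""

    r_squared: float
    slope: float
    intercept: float
    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    cov_pct: float
    percent: bool


def deming_regression(x, y) -> tuple[float, float]:
    """Orthogonal (Deming, variance ratio 1) regression slope and intercept."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need n >= 3 paired values")
    sxx = np.var(x, ddof=1)
    syy = np.var(y, ddof=1)
    sxy = np.cov(x, y, ddof=1)[0, 1]
    if sxx == 0 and syy == 0:
        raise ValueError("no variance in either variable")
    if sxy == 0:
        slope = 0.0 if syy < sxx else np.inf
    else:
        slope = (syy - sxx + np.sqrt((syy - sxx) ** 2 + 4 * sxy**2)) / (2 * sxy)
    intercept = float(np.mean(y) - slope * np.mean(x))
    return float(slope), intercept


def bland_altman(x, y, percent: bool = True) -> tuple[float, float, float, float]:
    """Bland-Altman bias and 1.96-SD limits of agreement.

    Percent mode uses 100*(y-x)/pairwise-mean differences (plotted
    against the pairwise mean); absolute mode uses y-x.  Returns
    (bias, loa_low, loa_high, sd).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(x) != len(y):
        raise ValueError("need n >= 2 paired values")
    if percent:
        means = (x + y) / 2.0
        if np.any(means == 0):
            raise ValueError("pairwise mean of zero in percent mode")
        diffs = 100.0 * (y - x) / means
    else:
        diffs = y - x
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1)) if len(diffs) > 1 else 0.0
    return bias, bias - 1.96 * sd, bias + 1.96 * sd, sd


def cov_of_differences(x, y, percent: bool = True) -> float:
    """Coefficient of variation of paired differences, in %.

    Default (percent convention): the sample SD of the pairwise
    percentage differences 100*(y-x)/pairwise-mean — already a
    percentage, so no further normalisation.  The absolute variant
    (percent=False) is 100 * SD(y-x) / mean of all measurements.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(x) != len(y):
        raise ValueError("need n >= 2 paired values")
    if percent:
        means = (x + y) / 2.0
        if np.any(means == 0):
            raise ValueError("pairwise mean of zero")
        return float(np.std(100.0 * (y - x) / means, ddof=1))
    grand = np.mean(np.concatenate([x, y]))
    if grand == 0:
        raise ValueError("zero mean")
    return float(100.0 * np.std(y - x, ddof=1) / grand)


def agreement_stats(x, y, percent: bool = True) -> AgreementStats:
    """All agreement statistics between paired measurement sets x and y."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    r = np.corrcoef(x, y)[0, 1]
    slope, intercept = deming_regression(x, y)
    bias, lo, hi, sd = bland_altman(x, y, percent=percent)
    return AgreementStats(
        r_squared=float(r**2),
        slope=slope,
        intercept=intercept,
        bias=bias,
        loa_low=lo,
        loa_high=hi,
        sd_diff=sd,
        cov_pct=cov_of_differences(x, y, percent=percent),
        percent=percent,
    )
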