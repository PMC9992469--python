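"""End-to-end orchestration: segment -> PVC -> IDIF -> (BSIF) -> CBF -> report.

A run is driven by a :class:`RunConfig` (YAML-loadable).  Defaults are
the method's chosen operating point: 42% threshold, 2.1 mm PVC kernel,
8-to-10-voxel sleeve, 13 s dispersion constant, 300 s fit window.  The
report is a plain JSON dict with every resolved setting, the PVC
factors, AUC metrics and CBF summaries, so a run is reproducible from
its own output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

import widif
from widif import image_io
from widif.blood import CalibrationSample, DispersionModel, prepare_bsif
from widif.evaluate import auc_metrics, ensure_origin, idif_from_mask
from widif.image_io import DynamicImage, Mask3D, TimeSeriesCurve
from widif.kinetics import fit_1tcm, fit_1tcm_voxelwise, make_basis, region_mean
from widif.phantom import DynamicPhantomSpec, generate_dynamic_phantom
from widif.segmentation import SegmentationConfig, VoiBox, segment_carotids


class StageError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Resolved settings for one pipeline run."""

    image: str
    schedule: str
    out_dir: str = "widif_out"
    early_frames: list[int] = field(default_factory=list)
    threshold_pct: float = 42.0
    voi: list[int] | None = None  # x0,x1,y0,y1,z0,z1 on the neck crop
    kernel_fwhm_mm: float = 2.1
    sleeve_inner: int = 8
    sleeve_outer: int = 10
    dispersion_tau_s: float = 13.0
    blood_curve: str | None = None
    blood_samples: str | None = None
    brain_mask: str | None = None
    gm_mask: str | None = None
    k2_min_per_min: float = 0.01
    k2_max_per_min: float = 3.0
    n_k2: int = 100
    fit_window_s: float = 300.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _k2_grid(config: RunConfig) -> np.ndarray:
    return np.logspace(
        np.log10(config.k2_min_per_min), np.log10(config.k2_max_per_min), config.n_k2
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full chain and write report.json plus output files.

    Any stage failure aborts with :class:`StageError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "software": {"name": "widif", "version": widif.__version__},
        "config": asdict(config),
    }

    try:
        image = image_io.read_dynamic(config.image, config.schedule)
    except Exception as exc:  # noqa: BLE001
        raise StageError("load", exc) from exc

    try:
        if not config.early_frames:
            raise ValueError("early_frames must be provided (operator choice)")
        voi = VoiBox(*config.voi) if config.voi else None
        seg_config = SegmentationConfig(
            early_frame_indices=list(config.early_frames),
            threshold_pct=config.threshold_pct,
            voi=voi,
        )
        mask, carotid_tac, _ = segment_carotids(image, seg_config)
        image_io.write_mask(mask, out / "carotid_mask.nii.gz")
        report["segmentation"] = {
            "n_mask_voxels": mask.n_voxels,
            "threshold_pct": config.threshold_pct,
            "early_frames": list(config.early_frames),
        }
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("segmentation", exc) from exc

    try:
        carotid_tac, tissue_tac, idif, factors = idif_from_mask(
            image, mask, config.kernel_fwhm_mm, config.sleeve_inner, config.sleeve_outer
        )
        image_io.write_curve(carotid_tac, out / "carotid_tac.tsv")
        image_io.write_curve(tissue_tac, out / "sleeve_tac.tsv")
        image_io.write_curve(idif, out / "idif.tsv")
        report["pvc"] = {
            "alpha": factors.alpha,
            "beta": factors.beta,
            "kernel_fwhm_mm": factors.kernel_fwhm_mm,
            "sleeve": [config.sleeve_inner, config.sleeve_outer],
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("pvc", exc) from exc

    bsif = None
    if config.blood_curve:
        try:
            raw = image_io.read_curve(config.blood_curve)
            samples = None
            if config.blood_samples:
                sc = image_io.read_curve(config.blood_samples)
                samples = [
                    CalibrationSample(t, v) for t, v in zip(sc.time_s, sc.value)
                ]
            bsif, blood_report = prepare_bsif(
                raw,
                samples,
                DispersionModel(config.dispersion_tau_s),
                image.schedule,
                reference_tac=None,
            )
            image_io.write_curve(bsif, out / "bsif.tsv")
            report["bsif"] = blood_report
        except Exception as exc:  # noqa: BLE001
            raise StageError("bsif", exc) from exc

    try:
        reference = bsif if bsif is not None else None
        idif0 = ensure_origin(idif)
        if reference is not None:
            report["auc_vs_bsif"] = asdict(auc_metrics(idif0, ensure_origin(reference)))
        cbf_summary = {}
        if config.brain_mask:
            brain = image_io.read_mask(config.brain_mask)
            f_map, vd_map, k2_map = fit_1tcm_voxelwise(
                image, idif0, brain, _k2_grid(config), config.fit_window_s
            )
            image_io.write_volume(f_map, image.voxel_size_mm, out / "cbf_f.nii.gz")
            image_io.write_volume(vd_map, image.voxel_size_mm, out / "cbf_vd.nii.gz")
            image_io.write_volume(k2_map, image.voxel_size_mm, out / "cbf_k2.nii.gz")
            cbf_summary["brain_mean_f"] = region_mean(f_map, brain)
        if config.gm_mask:
            gm = image_io.read_mask(config.gm_mask)
            from widif.segmentation import extract_tac

            gm_tac = extract_tac(image, gm)
            basis = make_basis(idif0, image.schedule, _k2_grid(config))
            fit = fit_1tcm(gm_tac, basis, fit_window_s=config.fit_window_s)
            cbf_summary["gm_f_idif"] = fit.flow_ml_per_cm3_min
            cbf_summary["gm_vd_idif"] = fit.vd_ml_per_cm3
            if reference is not None:
                rbasis = make_basis(ensure_origin(reference), image.schedule, _k2_grid(config))
                rfit = fit_1tcm(gm_tac, rbasis, fit_window_s=config.fit_window_s)
                cbf_summary["gm_f_bsif"] = rfit.flow_ml_per_cm3_min
        report["cbf"] = cbf_summary
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("cbf", exc) from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    return report


def write_demo_phantom(out_dir, seed: int = 0, spec: DynamicPhantomSpec | None = None):
    """Generate the default dynamic phantom and write scan + truth files.

    Returns (RunConfig pointing at the files, PhantomTruth).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if spec is None:
        spec = DynamicPhantomSpec(seed=seed)
    image, truth = generate_dynamic_phantom(spec)
    image_io.write_dynamic(image, out / "phantom.nii.gz", out / "phantom.json")
    image_io.write_curve(truth.input_curve, out / "true_input.tsv")
    image_io.write_mask(truth.carotid_mask, out / "true_carotid_mask.nii.gz")
    gm = truth.region_masks.get("gm")
    if gm is not None:
        image_io.write_mask(Mask3D(gm.astype(int), spec.voxel_size_mm), out / "gm_mask.nii.gz")
    config = RunConfig(
        image=str(out / "phantom.nii.gz"),
        schedule=str(out / "phantom.json"),
        out_dir=str(out / "results"),
        early_frames=[2, 3, 4],
        gm_mask=str(out / "gm_mask.nii.gz") if gm is not None else None,
        seed=seed,
    )
    return config, truth
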