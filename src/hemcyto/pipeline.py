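"""End-to-end orchestration: image -> detections -> per-event mixture
fits with cluster refinement -> QC -> measurement table and scatter plot.

Each detected event is processed independently (the output is identical
regardless of processing order), by extracting a padded patch around the
detection, fitting one Gaussian plus the local uniform background,
recursively splitting under BIC control, vetting every surviving
component against the covariance QC rules, and recording per-cell
fluorescence and FWHM diameter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import cluster_refine, detector as det_mod, hem_core
from .cluster_refine import QcLimits
from .detector import LdaDetector, SpotEvent
from .simgen import RasterImage

logger = logging.getLogger(__name__)

# Reference constants of the three-tier MESF bead calibration experiment:
# manufacturer-reference intensities and the matching measured mean
# fluorescences (dimmest tier first).
TABLE1_REFERENCE_MESF = (18_882.0, 138_201.0, 624_803.0)
TABLE1_MEAN_FLUORESCENCE = (372.3, 1197.4, 4851.3)

EVENT_TABLE_COLUMNS = [
    "image_id",
    "event_id",
    "component_id",
    "row",
    "col",
    "fluorescence",
    "sigma_eff_px",
    "diameter_um",
    "background_weight",
    "n_iterations",
    "converged",
    "qc_status",
    "edge",
    "bbox_r0",
    "bbox_c0",
    "bbox_r1",
    "bbox_c1",
]


@dataclass
class PipelineConfig:
    pixel_size_um: float = 3.0
    window_size: int = det_mod.DEFAULT_WINDOW
    threshold: float | None = None  # None -> use the model's stored threshold
    tol: float = hem_core.DEFAULT_TOL
    max_iter: int = hem_core.DEFAULT_MAX_ITER
    cov_floor: float = hem_core.DEFAULT_COV_FLOOR
    init_diameter_um: float = hem_core.DEFAULT_INIT_DIAMETER_UM
    offset: float = 0.0  # camera offset subtracted (clamped at 0) before fitting
    bic_drop_threshold: float = cluster_refine.DEFAULT_BIC_DROP
    n_eff_mode: str = "intensity"
    qc: QcLimits | None = None
    background_scope: str = "local"  # 'local' per-patch; 'global' full frame
    seed: int = 0  # simulation subcommands only

    def qc_limits(self) -> QcLimits:
        return self.qc or QcLimits.for_pixel_size(self.pixel_size_um)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        qc_data = data.pop("qc", None)
        cfg = cls(**data)
        if qc_data:
            cfg.qc = QcLimits(**qc_data)
        return cfg


def table1_linearity_check(
    mean_fluorescences: Sequence[float] = TABLE1_MEAN_FLUORESCENCE,
    reference_mesf: Sequence[float] = TABLE1_REFERENCE_MESF,
) -> float:
    """Squared Pearson correlation of the three tier-mean fluorescences
    against the three reference intensities, rounded to 4 decimals."""
    f = np.asarray(mean_fluorescences, dtype=float)
    m = np.asarray(reference_mesf, dtype=float)
    if f.shape != (3,) or m.shape != (3,):
        raise ValueError("expected exactly three paired values")
    if f.std() == 0 or m.std() == 0:
        raise ValueError("zero variance in one of the vectors")
    r = float(np.corrcoef(f, m)[0, 1])
    return round(r * r, 4)


def _extract_patch(image: RasterImage, event: SpotEvent) -> tuple[np.ndarray, tuple[int, int], bool]:
    """Patch pixels, patch origin, and whether the event touches the border."""
    r0, c0, r1, c1 = event.bbox
    h, w = image.shape
    edge = r0 <= 0 or c0 <= 0 or r1 >= h or c1 >= w
    return image.pixels[r0:r1, c0:c1], (r0, c0), edge


def process_event(
    image: RasterImage, event: SpotEvent, config: PipelineConfig, image_id: str = "", event_id: int = 0
) -> list[dict]:
    """Fit, refine and measure one detected event; returns table rows."""
    patch, origin, edge = _extract_patch(image, event)
    patch = np.clip(patch.astype(float) - config.offset, 0.0, None)
    if patch.sum() <= 0:
        return [
            {
                "image_id": image_id,
                "event_id": event_id,
                "component_id": -1,
                "row": event.centroid[0],
                "col": event.centroid[1],
                "fluorescence": np.nan,
                "sigma_eff_px": np.nan,
                "diameter_um": np.nan,
                "background_weight": np.nan,
                "n_iterations": 0,
                "converged": False,
                "qc_status": "failed(empty_patch)",
                "edge": edge,
                "bbox_r0": event.bbox[0],
                "bbox_c0": event.bbox[1],
                "bbox_r1": event.bbox[2],
                "bbox_c1": event.bbox[3],
            }
        ]
    local_center = (event.centroid[0] - origin[0], event.centroid[1] - origin[1])
    init = hem_core.initial_fit(
        patch.shape, [local_center], config.pixel_size_um, config.init_diameter_um
    )
    limits = config.qc_limits()
    try:
        fit = cluster_refine.refine_event(
            patch,
            init,
            bic_drop_threshold=config.bic_drop_threshold,
            limits=limits,
            tol=config.tol,
            max_iter=config.max_iter,
            cov_floor=config.cov_floor,
            n_eff_mode=config.n_eff_mode,
        )
    except FloatingPointError as exc:  # keep going; flag the event
        logger.warning("event %s fit failed: %s", event_id, exc)
        return [
            {
                "image_id": image_id,
                "event_id": event_id,
                "component_id": -1,
                "row": event.centroid[0],
                "col": event.centroid[1],
                "fluorescence": np.nan,
                "sigma_eff_px": np.nan,
                "diameter_um": np.nan,
                "background_weight": np.nan,
                "n_iterations": 0,
                "converged": False,
                "qc_status": f"failed({exc})",
                "edge": edge,
                "bbox_r0": event.bbox[0],
                "bbox_c0": event.bbox[1],
                "bbox_r1": event.bbox[2],
                "bbox_c1": event.bbox[3],
            }
        ]
    rows: list[dict] = []
    fluor = hem_core.measure_all_fluorescences(fit, patch)
    for ci, comp in enumerate(fit.components):
        status = cluster_refine.validate_component(comp, limits)
        diam = (
            hem_core.estimate_diameter(fit, ci, config.pixel_size_um)
            if status == "valid"
            else np.nan
        )
        rows.append(
            {
                "image_id": image_id,
                "event_id": event_id,
                "component_id": ci,
                "row": comp.mean[0] + origin[0],
                "col": comp.mean[1] + origin[1],
                "fluorescence": float(fluor[ci]),
                "sigma_eff_px": comp.sigma_eff_px,
                "diameter_um": diam,
                "background_weight": fit.background.weight,
                "n_iterations": fit.n_iterations,
                "converged": fit.converged,
                "qc_status": status,
                "edge": edge,
                "bbox_r0": event.bbox[0],
                "bbox_c0": event.bbox[1],
                "bbox_r1": event.bbox[2],
                "bbox_c1": event.bbox[3],
            }
        )
    if not rows:
        rows.append(
            {
                "image_id": image_id,
                "event_id": event_id,
                "component_id": -1,
                "row": event.centroid[0],
                "col": event.centroid[1],
                "fluorescence": np.nan,
                "sigma_eff_px": np.nan,
                "diameter_um": np.nan,
                "background_weight": fit.background.weight,
                "n_iterations": fit.n_iterations,
                "converged": fit.converged,
                "qc_status": "rejected(no_component)",
                "edge": edge,
                "bbox_r0": event.bbox[0],
                "bbox_c0": event.bbox[1],
                "bbox_r1": event.bbox[2],
                "bbox_c1": event.bbox[3],
            }
        )
    return rows


def _run_global_background(
    image: RasterImage, events: list[SpotEvent], config: PipelineConfig, image_id: str
) -> list[dict]:
    """Joint full-frame fit: one uniform over the whole frame plus one
    Gaussian per detected event, fit together.

    Fitting the frame-normalized uniform inside a local patch is not
    coherent (the background weight saturates), so global mode fits the
    frame as a single mixture.  Recursive splitting is a local-mode
    feature; global mode reports one component per event.
    """
    limits = config.qc_limits()
    pixels = np.clip(image.pixels.astype(float) - config.offset, 0.0, None)
    init = hem_core.initial_fit(
        pixels.shape,
        [e.centroid for e in events],
        config.pixel_size_um,
        config.init_diameter_um,
    )
    fit = hem_core.fit_hem(pixels, init, tol=config.tol, max_iter=config.max_iter, cov_floor=config.cov_floor)
    fluor = hem_core.measure_all_fluorescences(fit, pixels)
    rows: list[dict] = []
    h, w = image.shape
    for eid, (event, comp) in enumerate(zip(events, fit.components)):
        status = cluster_refine.validate_component(comp, limits)
        diam = (
            hem_core.estimate_diameter(fit, eid, config.pixel_size_um)
            if status == "valid"
            else np.nan
        )
        r0, c0, r1, c1 = event.bbox
        rows.append(
            {
                "image_id": image_id,
                "event_id": eid,
                "component_id": 0,
                "row": comp.mean[0],
                "col": comp.mean[1],
                "fluorescence": float(fluor[eid]),
                "sigma_eff_px": comp.sigma_eff_px,
                "diameter_um": diam,
                "background_weight": fit.background.weight,
                "n_iterations": fit.n_iterations,
                "converged": fit.converged,
                "qc_status": status,
                "edge": r0 <= 0 or c0 <= 0 or r1 >= h or c1 >= w,
                "bbox_r0": r0,
                "bbox_c0": c0,
                "bbox_r1": r1,
                "bbox_c1": c1,
            }
        )
    return rows


def run_pipeline(
    image: RasterImage,
    detector: LdaDetector,
    config: PipelineConfig | None = None,
    image_id: str = "",
) -> pd.DataFrame:
    """Full pipeline on one field of view; returns the event table.

    QC-rejected components are flagged in qc_status, never dropped.
    """
    config = config or PipelineConfig(pixel_size_um=image.pixel_size_um)
    prob_map = det_mod.scan(image, detector)
    threshold = config.threshold if config.threshold is not None else detector.threshold
    events = det_mod.detect(prob_map, threshold)
    rows: list[dict] = []
    if config.background_scope == "global" and events:
        rows = _run_global_background(image, events, config, image_id)
    else:
        for eid, event in enumerate(events):
            rows.extend(process_event(image, event, config, image_id=image_id, event_id=eid))
    table = pd.DataFrame(rows, columns=EVENT_TABLE_COLUMNS)
    n_valid = int((table["qc_status"] == "valid").sum()) if len(table) else 0
    logger.info(
        "pipeline: %d events -> %d rows (%d valid)", len(events), len(table), n_valid
    )
    return table


def write_event_table(table: pd.DataFrame, path: str | Path) -> None:
    """CSV with the documented column set; numeric fields round-trip at 17
    significant digits."""
    out = table.reindex(columns=EVENT_TABLE_COLUMNS)
    out.to_csv(path, index=False, float_format="%.17g")


def read_event_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    return table.reindex(columns=EVENT_TABLE_COLUMNS)


def plot_scatter(table: pd.DataFrame, out_path: str | Path, log_fluorescence: bool = True) -> bool:
    """Fluorescence-vs-diameter scatter of valid, non-edge rows.

    Returns True if a figure was written; warns and writes nothing when
    no valid rows exist.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    valid = table[(table["qc_status"] == "valid") & (~table["edge"].astype(bool))]
    if valid.empty:
        valid = table[table["qc_status"] == "valid"]
    if valid.empty:
        logger.warning("no valid rows; not writing %s", out_path)
        return False
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(valid["diameter_um"], valid["fluorescence"], s=8, alpha=0.5, edgecolors="none")
    ax.set_xlabel("diameter (µm)")
    ax.set_ylabel("fluorescence (intensity sum)")
    if log_fluorescence and (valid["fluorescence"] > 0).all():
        ax.set_yscale("log")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return True


def read_tiff(path: str | Path, pixel_size_um: float = 3.0) -> RasterImage:
    """First page of a (possibly multi-page) grayscale TIFF."""
    import tifffile

    arr = tifffile.imread(path)
    if arr.ndim == 3:
        logger.warning("multi-page TIFF %s: using first page", path)
        arr = arr[0]
    return RasterImage(arr.astype(float), pixel_size_um=pixel_size_um, source_id=str(path))
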