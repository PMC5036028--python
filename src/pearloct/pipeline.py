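"""End-to-end grading pipeline and batch driver.

``run_pipeline`` chains denoise -> surface detection -> polynomial fit
-> flatten -> median smooth -> crop -> downscale -> power law ->
graph segmentation -> gradient thresholding, and records the geometric
bookkeeping (column shifts, crop window, scale) needed to map
full-resolution ground-truth rows into the segmented frame.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import grade, graphseg, preprocess
from .config import PipelineConfig
from .grade import GradeResult
from .graphseg import Boundary
from .image import BScanImage, load_image, save_image

logger = logging.getLogger("pearloct")


@dataclass
class PipelineGeometry:
    """Coordinate bookkeeping from raw frame to segmented frame."""

    flat_row: int
    col_start: int
    shifts: np.ndarray  # per raw column, rows shifted up during flattening
    scale: int  # total downscale factor (2**downscale_steps)

    def truth_to_segmented(self, truth_rows: np.ndarray) -> np.ndarray:
        """Map per-raw-column boundary rows into segmented-frame rows.

        Returns one fractional row per segmented column.
        """
        n_cols = len(self.shifts)
        seg_cols = np.arange(self.col_start, self.col_start + self._crop_cols, self.scale)
        seg_cols = seg_cols[seg_cols < n_cols]
        flattened = truth_rows[seg_cols] - self.shifts[seg_cols]
        return (flattened - self.flat_row) / self.scale

    _crop_cols: int = 300


@dataclass
class PipelineResult:
    grade: GradeResult
    up: Boundary
    down: Boundary
    geometry: PipelineGeometry
    segmented: BScanImage  # the image segmentation actually saw
    raw_gradient: np.ndarray
    timings: dict[str, float] = field(default_factory=dict)
    intermediates: dict[str, BScanImage] = field(default_factory=dict)
    source: str | None = None

    def report(self) -> dict:
        rep = {"file": self.source, **self.grade.to_dict()}
        rep["timings_s"] = {k: round(v, 4) for k, v in self.timings.items()}
        return rep


def run_pipeline(
    image: BScanImage | str | Path,
    config: PipelineConfig | None = None,
    keep_intermediates: bool = False,
) -> PipelineResult:
    """Grade a single B-scan."""
    cfg = config or PipelineConfig()
    source = None
    if not isinstance(image, BScanImage):
        source = str(image)
        image = load_image(image)

    timings: dict[str, float] = {}
    inter: dict[str, BScanImage] = {}

    def stage(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        out = fn(*args, **kwargs)
        timings[name] = time.perf_counter() - t0
        logger.debug("stage %-12s %.3fs", name, timings[name])
        return out

    stats = stage("background", preprocess.background_stats, image, cfg.n_background_rows, cfg.k_sigma)
    denoised = stage("denoise", preprocess.threshold_denoise, image, stats)
    curve = stage(
        "surface",
        preprocess.detect_surface,
        denoised,
        sigma=cfg.canny_sigma,
        low_pct=cfg.canny_low_pct,
        high_pct=cfg.canny_high_pct,
        min_edge_columns=cfg.poly_degree + 1,
    )
    fitted = stage("fit", preprocess.fit_surface, curve, cfg.poly_degree)
    flattened, flat_row = stage("flatten", preprocess.flatten, denoised, fitted)
    smoothed = stage("median", preprocess.median_smooth, flattened, cfg.median_window)
    cropped = stage("crop", preprocess.crop_roi, smoothed, flat_row, cfg.crop_size)
    t0 = time.perf_counter()
    small = cropped
    for _ in range(cfg.downscale_steps):
        small = preprocess.downscale_half(small)
    timings["downscale"] = time.perf_counter() - t0
    enhanced = stage("power_law", preprocess.power_law, small, cfg.power_C, cfg.power_gamma)

    t0 = time.perf_counter()
    up, down = graphseg.segment_layer(
        enhanced, w_min=cfg.w_min, endpoint_weight=cfg.endpoint_weight
    )
    timings["segment"] = time.perf_counter() - t0

    raw = graphseg.vertical_gradient(enhanced)
    up_mean = grade.boundary_mean_gradient(raw, up)
    down_mean = grade.boundary_mean_gradient(raw, down)
    result = grade.classify(
        up_mean,
        down_mean,
        up_threshold=cfg.up_threshold,
        down_threshold=cfg.down_threshold,
        combine_rule=cfg.combine_rule,
    )

    shifts = np.rint(fitted.rows).astype(int) - flat_row
    geometry = PipelineGeometry(
        flat_row=flat_row,
        col_start=image.width // 2 - cfg.crop_size[1] // 2,
        shifts=shifts,
        scale=2**cfg.downscale_steps,
        _crop_cols=cfg.crop_size[1],
    )
    if keep_intermediates:
        inter = {"denoised": denoised, "flattened": flattened, "smoothed": smoothed, "cropped": cropped, "enhanced": enhanced}
    return PipelineResult(
        grade=result,
        up=up,
        down=down,
        geometry=geometry,
        segmented=enhanced,
        raw_gradient=raw,
        timings=timings,
        intermediates=inter,
        source=source,
    )


def boundary_overlay(result: PipelineResult) -> Image.Image:
    """RGB overlay of the segmented image: red = up, green = down boundary."""
    base = result.segmented.to_uint()
    if result.segmented.bit_depth == 16:
        base = (base / 257.0).astype(np.uint8)
    rgb = np.stack([base] * 3, axis=-1)
    cols = np.arange(base.shape[1])
    rgb[result.up.rows, cols] = (255, 0, 0)
    rgb[result.down.rows, cols] = (0, 255, 0)
    return Image.fromarray(rgb)


def write_report(result: PipelineResult, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(result.report(), indent=2, sort_keys=True) + "\n")
    return path


IMAGE_SUFFIXES = (".png", ".tif", ".tiff")


def run_batch(
    directory: str | Path,
    config: PipelineConfig | None = None,
    manifest: str | Path | None = None,
    out_csv: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Grade every image in a directory.

    Unreadable files are logged and skipped (recorded with label
    "error"). If a manifest CSV (filename,label,...) is given or a
    ``manifest.csv`` exists alongside the images, accuracy, sensitivity
    and specificity against it are returned in the metrics dict.
    """
    directory = Path(directory)
    cfg = config or PipelineConfig()
    rows = []
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES)
    if not files:
        logger.warning("no images found in %s", directory)
    for path in files:
        try:
            res = run_pipeline(path, cfg)
            rows.append(
                {
                    "file": path.name,
                    "up_mean": res.grade.up_mean,
                    "down_mean": res.grade.down_mean,
                    "label": res.grade.label,
                }
            )
        except Exception as exc:  # keep batch going past bad files
            logger.error("failed on %s: %s", path.name, exc)
            rows.append({"file": path.name, "up_mean": np.nan, "down_mean": np.nan, "label": "error"})
    df = pd.DataFrame(rows, columns=["file", "up_mean", "down_mean", "label"])

    metrics: dict = {}
    if manifest is None and (directory / "manifest.csv").exists():
        manifest = directory / "manifest.csv"
    if manifest is not None:
        truth = pd.read_csv(manifest).set_index("filename")["label"]
        merged = df[df.label != "error"].set_index("file").join(truth, rsuffix="_true")
        ok = merged.label == merged.label_true
        tp = ((merged.label == "defect") & (merged.label_true == "defect")).sum()
        tn = ((merged.label == "normal") & (merged.label_true == "normal")).sum()
        n_def = (merged.label_true == "defect").sum()
        n_norm = (merged.label_true == "normal").sum()
        metrics = {
            "n": int(len(merged)),
            "accuracy": float(ok.mean()) if len(merged) else float("nan"),
            "sensitivity": float(tp / n_def) if n_def else float("nan"),
            "specificity": float(tn / n_norm) if n_norm else float("nan"),
        }
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df, metrics
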