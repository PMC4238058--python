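"""File I/O, configuration and the end-to-end titration pipeline.

TIFF images (single- or multi-page grayscale) go through tifffile; tables
through pandas. The analysis configuration is a flat YAML mapping with
strict unknown-key rejection, and every pipeline run logs one structured
line per stage with its parameters, so results are reproducible from the
config alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .imgproc import RasterImage
from .phase import clustering_concentration, titration_statistics
from .segment import LabeledClusters

logger = logging.getLogger("slbphase")

__all__ = [
    "AnalysisConfig",
    "read_stack",
    "write_stack",
    "clusters_to_frame",
    "run_pipeline",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Flat analysis configuration; every field is validated on load."""

    threshold_method: str = "triangle"
    histogram_bins: int = 256
    min_area_px: int = 4
    grid_rows: int = 5
    grid_cols: int = 5
    rolling_ball_radius: int = 50
    pixel_size: float = 0.16
    frap_alpha: float = 0.05
    actin_window_min: float = 27.0
    headgroup_area: float = 69.0
    labeled_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.threshold_method not in ("triangle", "max_entropy", "sd_iterative"):
            raise ValueError(f"unknown threshold method {self.threshold_method!r}")
        if self.histogram_bins < 8:
            raise ValueError("histogram_bins must be >= 8")
        if self.min_area_px < 1:
            raise ValueError("min_area_px must be >= 1")
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid must be at least 1x1")
        if self.rolling_ball_radius < 1:
            raise ValueError("rolling_ball_radius must be >= 1")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if not 0 < self.frap_alpha < 1:
            raise ValueError("frap_alpha must lie in (0, 1)")
        if not 0 < self.labeled_fraction <= 1:
            raise ValueError("labeled_fraction must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("config must be a flat key-value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def read_stack(path: str | Path, pixel_size: float | None = None) -> list[RasterImage]:
    """Read a single- or multi-page grayscale TIFF into RasterImages.

    Pixel size comes from the argument or the TIFF XResolution tag
    (pixels per µm convention); RGB pages are rejected — they signal a
    wrong channel export upstream.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        pages = []
        px = pixel_size
        for page in tf.pages:
            arr = page.asarray()
            if arr.ndim != 2:
                raise ValueError(
                    f"{path.name}: page is not single-channel grayscale "
                    f"(shape {arr.shape}); export a single channel"
                )
            if px is None:
                res = page.tags.get("XResolution")
                if res is not None and res.value[0] > 0:
                    px = res.value[1] / res.value[0]  # µm per pixel
            pages.append(arr.astype(float))
    px = px if px is not None else 0.16
    return [RasterImage(values=a, pixel_size=px) for a in pages]


def write_stack(path: str | Path, images: "list[RasterImage] | RasterImage") -> None:
    """Write images as a 16-bit grayscale (multi-page) TIFF, clipped to range."""
    if isinstance(images, RasterImage):
        images = [images]
    data = np.stack([np.clip(im.values, 0, 65535).astype(np.uint16) for im in images])
    px = images[0].pixel_size
    tifffile.imwrite(
        path,
        data if data.shape[0] > 1 else data[0],
        resolution=(1.0 / px, 1.0 / px),
    )


def clusters_to_frame(labeled: LabeledClusters) -> pd.DataFrame:
    """Per-cluster measurement table (one row per cluster)."""
    rows = [
        {
            "id": c.id,
            "area_px": c.area_px,
            "area_um2": c.area_um2,
            "integrated_intensity": c.integrated_intensity,
            "mean_intensity": c.mean_intensity,
            "centroid_y": c.centroid[0],
            "centroid_x": c.centroid[1],
            "touches_edge": c.touches_image_edge,
        }
        for c in labeled.clusters
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "id",
            "area_px",
            "area_um2",
            "integrated_intensity",
            "mean_intensity",
            "centroid_y",
            "centroid_x",
            "touches_edge",
        ],
    )


def run_pipeline(
    config: AnalysisConfig,
    manifest: pd.DataFrame,
    out_dir: str | Path,
) -> dict:
    """Run the titration workflow over a manifest of images.

    ``manifest`` needs columns ``concentration_nM`` and ``image_path``
    (several rows per concentration = replicate tiles). Writes the curve
    CSV and a breakpoint JSON; per-entry failures are logged and skipped.
    Returns a summary dict with the curve, the breakpoint estimates and
    the count of failures.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_hash": config.config_hash(), "n_failed": 0}
    if manifest.empty:
        logger.warning("empty manifest: nothing to analyze")
        summary["curve"] = None
        return summary

    by_conc: dict[float, list[RasterImage]] = {}
    for _, row in manifest.iterrows():
        try:
            imgs = read_stack(row["image_path"], pixel_size=config.pixel_size)
            by_conc.setdefault(float(row["concentration_nM"]), []).extend(imgs)
        except Exception as exc:  # noqa: BLE001 - per-entry failures are skipped
            logger.error("skipping %s: %s", row["image_path"], exc)
            summary["n_failed"] += 1

    series = sorted(by_conc.items())
    curve = titration_statistics(
        [(c, imgs) for c, imgs in series],
        method=config.threshold_method,
        min_area_px=config.min_area_px,
        bins=config.histogram_bins,
    )
    logger.info(
        "titration config=%s n_conc=%d method=%s",
        summary["config_hash"],
        len(series),
        config.threshold_method,
    )

    curve_df = pd.DataFrame(
        {
            "concentration_nM": curve.concentrations,
            "fractional_intensity": curve.statistic("fractional_intensity"),
            "variance_counts2": curve.statistic("variance"),
            "cv2": curve.statistic("cv2"),
            "n_clusters": curve.statistic("n_clusters"),
        }
    )
    curve_df.to_csv(out_dir / "titration_curve.csv", index=False)
    (out_dir / "titration_curve.schema.json").write_text(
        json.dumps(
            {
                "concentration_nM": "solution concentration, nM",
                "fractional_intensity": "fraction of image intensity in clusters, dimensionless",
                "variance_counts2": "population variance of pixel intensities, counts^2",
                "cv2": "variance / mean^2, dimensionless",
                "n_clusters": "mean cluster count per tile",
            },
            indent=2,
        )
    )

    breakpoints = {}
    for statistic in ("fractional_intensity", "variance"):
        est = clustering_concentration(curve, statistic=statistic)
        breakpoints[statistic] = {
            "detected": est.detected,
            "concentration_nM": est.concentration,
            "baseline_level": est.baseline_level,
            "post_slope": est.post_slope,
        }
    (out_dir / "breakpoint.json").write_text(json.dumps(breakpoints, indent=2))
    summary["curve"] = curve
    summary["breakpoints"] = breakpoints
    return summary
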