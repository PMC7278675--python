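"""Batch orchestration: manifests of images in, metric tables out.

Each run is deterministic given its inputs and configuration.  Every
output CSV starts with comment lines recording the package version, a
hash of the effective configuration and the seed, so results can be
traced back to the exact settings that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .crust_fractal import DEFAULT_BOX_SIZES, crust_roughness_pipeline
from .imaging_io import meta_from_row, read_micrograph, read_sample_manifest
from .morphometry import (
    compute_crumb_metrics,
    label_particles,
    particle_features,
    pore_size_histogram,
    summarize_particles,
)
from .segmentation import SegmentationConfig, classify_pixels
from .stats_stage import build_relationship_matrix, load_metrics_table

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_crumb_analysis", "run_crust_analysis", "run_report"]


@dataclass
class RunConfig:
    """Settings for a batch run."""

    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    pixel_size_um: float | None = None  # None: per-file metadata or default
    bin_width_um: float = 25.0
    min_area_px: int = 4
    connectivity: int = 4
    box_sizes: tuple[int, ...] = DEFAULT_BOX_SIZES
    make_plots: bool = False
    seed: int = 0

    def config_hash(self) -> str:
        payload = yaml.safe_dump(
            dataclasses.asdict(self), sort_keys=True, default_flow_style=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        seg = SegmentationConfig(**data.pop("segmentation", {}))
        known = {f.name for f in dataclasses.fields(cls)} - {"segmentation"}
        cfg = cls(segmentation=seg, **{k: v for k, v in data.items() if k in known})
        if isinstance(cfg.box_sizes, list):
            cfg.box_sizes = tuple(cfg.box_sizes)
        return cfg


def _write_csv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    header = (
        f"# crumbscope {__version__}; config_hash={cfg.config_hash()}; "
        f"seed={cfg.seed}\n"
    )
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def _load_manifest(manifest: str | Path | pd.DataFrame) -> pd.DataFrame:
    if isinstance(manifest, pd.DataFrame):
        return manifest
    return read_sample_manifest(manifest)


def run_crumb_analysis(
    manifest: str | Path | pd.DataFrame,
    out_dir: str | Path,
    cfg: RunConfig | None = None,
) -> tuple[pd.DataFrame, int]:
    """Segment and measure every crumb image in the manifest.

    Writes ``metrics.csv`` (one row per image), per-image particle
    tables under ``particles/`` and pore-size histograms under
    ``histograms/``.  Unreadable images are skipped with a logged
    error.

    Returns
    -------
    (metrics, n_failed)
        The metrics table and the number of images that failed.
    """
    cfg = cfg or RunConfig()
    out_dir = Path(out_dir)
    df = _load_manifest(manifest)
    rows = []
    n_failed = 0
    for _, rec in df.iterrows():
        sample_id = str(rec["sample_id"])
        try:
            m = read_micrograph(
                rec["image_path"],
                pixel_size_um=cfg.pixel_size_um,
                meta=meta_from_row(rec),
            )
            masks = classify_pixels(m.matrix_image, m.oil_image, cfg.segmentation)
            metrics = compute_crumb_metrics(masks)
            labels = label_particles(masks.pore, connectivity=cfg.connectivity)
            particles = particle_features(
                labels, m.pixel_size_um, min_area_px=cfg.min_area_px
            )
            summary = summarize_particles(particles)
            hist = pore_size_histogram(particles, bin_width_um=cfg.bin_width_um)
        except Exception:
            logger.exception("failed to analyze %s", sample_id)
            n_failed += 1
            continue
        _write_csv(particles, out_dir / "particles" / f"{sample_id}.csv", cfg)
        _write_csv(hist.to_frame(), out_dir / "histograms" / f"{sample_id}.csv", cfg)
        if cfg.make_plots:
            from .plotting import plot_pore_size_distribution

            (out_dir / "plots").mkdir(parents=True, exist_ok=True)
            plot_pore_size_distribution(
                hist, out_dir / "plots" / f"{sample_id}_pores.png", title=sample_id
            )
        rows.append(
            {
                "sample_id": sample_id,
                "bran_type": rec["bran_type"],
                "bran_concentration_g": rec["bran_concentration_g"],
                "product_type": rec["product_type"],
                "initial_moisture_ml": rec["initial_moisture_ml"],
                "region": rec["region"],
                "porosity_pct": metrics.porosity_pct,
                "poia_pct": metrics.poia_pct,
                "particle_count": summary.count,
                "total_area_um2": summary.total_area_um2,
                "average_size_um2": summary.average_size_um2,
                "mean_perimeter_um": summary.mean_perimeter_um,
                "mean_circularity": summary.mean_circularity,
                "mean_solidity": summary.mean_solidity,
            }
        )
    metrics_df = pd.DataFrame(rows)
    _write_csv(metrics_df, out_dir / "metrics.csv", cfg)
    return metrics_df, n_failed


def run_crust_analysis(
    manifest: str | Path | pd.DataFrame,
    out_dir: str | Path,
    cfg: RunConfig | None = None,
) -> tuple[pd.DataFrame, int]:
    """Measure the roughness index (FD) of every crust image.

    Writes ``fd.csv`` with one row per image plus the per-size box
    counts under ``boxcounts/``.
    """
    cfg = cfg or RunConfig()
    out_dir = Path(out_dir)
    df = _load_manifest(manifest)
    rows = []
    n_failed = 0
    for _, rec in df.iterrows():
        sample_id = str(rec["sample_id"])
        try:
            m = read_micrograph(
                rec["image_path"],
                pixel_size_um=cfg.pixel_size_um,
                meta=meta_from_row(rec),
            )
            result = crust_roughness_pipeline(
                m,
                sizes=cfg.box_sizes,
                n_erode=cfg.segmentation.n_erode,
                n_dilate=cfg.segmentation.n_dilate,
            )
        except Exception:
            logger.exception("failed to analyze %s", sample_id)
            n_failed += 1
            continue
        _write_csv(result.to_frame(), out_dir / "boxcounts" / f"{sample_id}.csv", cfg)
        if cfg.make_plots:
            from .plotting import plot_box_count_fit

            (out_dir / "plots").mkdir(parents=True, exist_ok=True)
            plot_box_count_fit(
                result, out_dir / "plots" / f"{sample_id}_boxcount.png", title=sample_id
            )
        rows.append(
            {
                "sample_id": sample_id,
                "bran_type": rec["bran_type"],
                "bran_concentration_g": rec["bran_concentration_g"],
                "product_type": rec["product_type"],
                "slope_d": result.slope_d,
                "fd": result.fd,
                "fit_r2": result.fit_r2,
            }
        )
    fd_df = pd.DataFrame(rows)
    _write_csv(fd_df, out_dir / "fd.csv", cfg)
    return fd_df, n_failed


def run_report(
    metrics: str | Path | pd.DataFrame,
    out_path: str | Path,
    cfg: RunConfig | None = None,
) -> pd.DataFrame:
    """Pairwise cubic-fit report from a metrics table.

    ``metrics`` may be a CSV path (with the columns of a metrics
    table) or an in-memory frame.  Writes one row per (group,
    predictor, response) with coefficients and R^2.
    """
    cfg = cfg or RunConfig()
    if not isinstance(metrics, pd.DataFrame):
        metrics = load_metrics_table(metrics)
    report = build_relationship_matrix(metrics)
    _write_csv(report, Path(out_path), cfg)
    return report
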