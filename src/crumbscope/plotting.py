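"""Plot exports: pore-size distributions and box-count fits.

Matplotlib is used with the non-interactive Agg backend; every
function writes a file and returns the path.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .crust_fractal import BoxCountResult
from .morphometry import PoreSizeDistribution

__all__ = ["plot_pore_size_distribution", "plot_box_count_fit"]


def plot_pore_size_distribution(
    dist: PoreSizeDistribution, path: str | Path, title: str = ""
) -> Path:
    """Bar chart of pore-size frequencies per diameter bin."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(6, 3.5))
    centers = (dist.bin_edges_um[:-1] + dist.bin_edges_um[1:]) / 2.0
    width = float(np.diff(dist.bin_edges_um).mean()) * 0.9
    ax.bar(centers, dist.frequency_pct, width=width, color="#4878a8")
    ax.set_xlabel("equivalent pore diameter (µm)")
    ax.set_ylabel("frequency (%)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_box_count_fit(
    result: BoxCountResult, path: str | Path, title: str = ""
) -> Path:
    """Log-log box counts with the fitted line and FD annotation."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    logr = np.log(result.box_sizes_px)
    logn = np.log(result.counts)
    ax.plot(logr, logn, "o", color="#33404d", label="counts")
    ax.plot(
        logr,
        -result.slope_d * logr + result.intercept,
        "-",
        color="#c0504d",
        label=f"fit: FD = {result.fd:.2f} (R² = {result.fit_r2:.3f})",
    )
    ax.set_xlabel("log box size (px)")
    ax.set_ylabel("log box count")
    ax.legend(frameon=False)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
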