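"""Phase segmentation of two-channel crumb micrographs.

A fried-dough crumb image contains three phases: the fluorescent solid
matrix (green channel), penetrated oil (red channel) and empty pores
(dark in both channels).  Segmentation proceeds per channel with
automatic histogram thresholding (Otsu for the standard path, Triangle
as the low-noise alternative for pore/matrix separation), followed by a
morphological opening (erosions then dilations) to remove speckle, and a
pixel-wise combination rule that yields mutually exclusive solid / oil /
empty masks covering the whole frame.

Conventions used throughout the package:

* thresholds are integers in [0, 255]; *foreground* means strictly
  greater than the threshold;
* ties in threshold selection are broken towards the lowest qualifying
  value, so outputs are deterministic;
* pixels bright in both channels are assigned to oil (penetrated oil is
  counted wherever the red stain reports it).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage as ndi
from skimage.segmentation import flood

__all__ = [
    "DegenerateHistogramError",
    "SegmentationConfig",
    "ComponentMasks",
    "otsu_threshold",
    "triangle_threshold",
    "morph_clean",
    "wand_select",
    "classify_pixels",
]

_SQUARE3 = np.ones((3, 3), dtype=bool)


class DegenerateHistogramError(ValueError):
    """The intensity histogram has a single occupied bin (constant image)."""


def _histogram256(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if image.min() < 0 or image.max() > 255:
        raise ValueError("expected 8-bit intensities in [0, 255]")
    return np.bincount(image.astype(np.intp).ravel(), minlength=256)


def otsu_threshold(image: np.ndarray) -> int:
    """Otsu's automatic threshold on the 256-bin histogram.

    Returns the integer ``t`` maximizing the between-class variance of
    the split background ``<= t`` / foreground ``> t``; the lowest
    maximizer is returned on ties.

    Raises
    ------
    DegenerateHistogramError
        If the image is constant (no split has two non-empty classes).
    """
    hist = _histogram256(image).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("constant image: Otsu threshold undefined")

    total = hist.sum()
    # cumulative class probability and mean over thresholds t = 0..254
    w0 = np.cumsum(hist)[:-1] / total
    mu_cum = np.cumsum(hist * np.arange(256))[:-1] / total
    mu_total = (hist * np.arange(256)).sum() / total
    w1 = 1.0 - w0
    valid = (w0 > 0) & (w1 > 0)
    variance = np.zeros(255)
    variance[valid] = (mu_total * w0[valid] - mu_cum[valid]) ** 2 / (
        w0[valid] * w1[valid]
    )
    return int(np.argmax(variance))


def triangle_threshold(image: np.ndarray) -> int:
    """Triangle-method threshold on the 256-bin histogram.

    A line is drawn from the histogram peak to the far end of the longer
    tail (the outermost occupied bin).  The threshold is the bin between
    them whose histogram point lies at maximal perpendicular distance
    from that line; the lowest qualifying bin wins ties.  Foreground is
    ``> t``, as everywhere in this package.
    """
    hist = _histogram256(image).astype(np.float64)
    occupied = np.flatnonzero(hist)
    if occupied.size < 2:
        raise DegenerateHistogramError("constant image: Triangle threshold undefined")

    peak = int(np.argmax(hist))  # lowest bin on ties
    lo, hi = int(occupied[0]), int(occupied[-1])
    # the longer tail defines the baseline; prefer the right tail on ties
    tail = hi if (hi - peak) >= (peak - lo) else lo
    if tail == peak:
        raise DegenerateHistogramError("histogram has no tail on either side")

    a, b = (peak, tail) if peak < tail else (tail, peak)
    bins = np.arange(a + 1, b)
    if bins.size == 0:
        return a
    # perpendicular distance from (bin, h[bin]) to the peak-tail line
    dx, dy = tail - peak, hist[tail] - hist[peak]
    dist = np.abs(dy * (bins - peak) - dx * (hist[bins] - hist[peak]))
    return int(bins[np.argmax(dist)])


def morph_clean(
    mask: np.ndarray, n_erode: int = 2, n_dilate: int = 2
) -> np.ndarray:
    """Morphological opening: ``n_erode`` erosions then ``n_dilate``
    dilations with a 3x3 square structuring element.

    The defaults (two of each) implement the standard two-step
    erode/dilate noise removal applied after thresholding.  Pixels
    outside the frame count as background for the erosion.
    """
    if n_erode < 0 or n_dilate < 0:
        raise ValueError("iteration counts must be non-negative")
    out = np.asarray(mask, dtype=bool)
    if n_erode:
        out = ndi.binary_erosion(out, structure=_SQUARE3, iterations=n_erode)
    if n_dilate:
        out = ndi.binary_dilation(out, structure=_SQUARE3, iterations=n_dilate)
    return out


def wand_select(
    image: np.ndarray,
    seed: tuple[int, int],
    tolerance: float = 2.0,
    connectivity: int = 4,
) -> np.ndarray:
    """Wand-style region selection by tolerance flood fill.

    Returns the maximal connected region containing ``seed`` whose
    intensities satisfy ``|I - I(seed)| <= tolerance``, using
    4- or 8-connectivity.  This is the programmatic analogue of the
    wand tool used to pick pore areas (connectedness four, tolerance
    between one and five).
    """
    image = np.asarray(image)
    r, c = seed
    if not (0 <= r < image.shape[0] and 0 <= c < image.shape[1]):
        raise IndexError(f"seed {seed} outside image of shape {image.shape}")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    # signed dtype so the tolerance comparison cannot wrap
    return flood(
        image.astype(np.int16),
        (int(r), int(c)),
        tolerance=float(tolerance),
        connectivity=1 if connectivity == 4 else 2,
    )


@dataclass
class SegmentationConfig:
    """Segmentation settings (YAML-loadable).

    ``matrix_threshold`` / ``oil_threshold`` are either the string
    ``"auto"`` (Otsu) or an explicit integer in [0, 255].
    """

    matrix_threshold: int | str = "auto"
    oil_threshold: int | str = "auto"
    n_erode: int = 2
    n_dilate: int = 2
    wand_tolerance: float = 2.0
    connectivity: int = 4

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SegmentationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in data.items() if k in known})


@dataclass
class ComponentMasks:
    """Mutually exclusive solid / oil / empty-pore pixel classification.

    The three boolean masks are pairwise disjoint and jointly cover
    every pixel of the frame.
    """

    solid: np.ndarray
    oil: np.ndarray
    empty: np.ndarray

    def __post_init__(self) -> None:
        self.solid = np.asarray(self.solid, dtype=bool)
        self.oil = np.asarray(self.oil, dtype=bool)
        self.empty = np.asarray(self.empty, dtype=bool)
        if not (self.solid.shape == self.oil.shape == self.empty.shape):
            raise ValueError("mask shapes differ")
        total = (
            self.solid.astype(np.uint8)
            + self.oil.astype(np.uint8)
            + self.empty.astype(np.uint8)
        )
        if not np.all(total == 1):
            raise ValueError("masks must partition the frame (disjoint and exhaustive)")

    @property
    def pore(self) -> np.ndarray:
        """Union of empty and oil-filled pores (the void phase)."""
        return self.empty | self.oil


def _resolve_threshold(image: np.ndarray, setting: int | str) -> int | None:
    """Resolve an "auto"/integer threshold setting for one channel.

    Returns None for a constant channel under "auto": the caller then
    treats the channel as all-foreground (constant nonzero signal) or
    all-background (constant zero).
    """
    if setting != "auto":
        t = int(setting)
        if not 0 <= t <= 255:
            raise ValueError(f"threshold {t} outside [0, 255]")
        return t
    try:
        return otsu_threshold(image)
    except DegenerateHistogramError:
        return None


def _channel_foreground(image: np.ndarray, setting: int | str) -> np.ndarray:
    t = _resolve_threshold(image, setting)
    if t is None:
        # constant channel: saturated signal is foreground, dark is not
        return np.full(image.shape, bool(image.flat[0] > 0))
    return image > t


def classify_pixels(
    matrix_image: np.ndarray,
    oil_image: np.ndarray,
    cfg: SegmentationConfig | None = None,
) -> ComponentMasks:
    """Classify every pixel as solid matrix, penetrated oil or empty pore.

    The oil channel foreground (thresholded, then opened) defines the
    oil phase; the matrix channel foreground minus oil defines the solid
    phase; everything else is empty pore.  Oil takes priority where both
    channels are bright, since red signal reports penetrated oil
    regardless of matrix co-location.

    A constant channel has no Otsu threshold; it is treated as
    all-foreground when its constant value is non-zero and
    all-background otherwise (saturated versus dark signal).

    Raises
    ------
    DegenerateHistogramError
        If both channels are constant at the same value, so the phases
        are indistinguishable.
    """
    cfg = cfg or SegmentationConfig()
    matrix_image = np.asarray(matrix_image)
    oil_image = np.asarray(oil_image)
    if matrix_image.shape != oil_image.shape:
        raise ValueError("channel shapes differ")
    if cfg.matrix_threshold == "auto" and cfg.oil_threshold == "auto":
        if (
            matrix_image.min() == matrix_image.max()
            and oil_image.min() == oil_image.max()
            and matrix_image.flat[0] == oil_image.flat[0]
        ):
            raise DegenerateHistogramError(
                "both channels constant at the same value: phases "
                "indistinguishable"
            )

    oil_fg = _channel_foreground(oil_image, cfg.oil_threshold)
    matrix_fg = _channel_foreground(matrix_image, cfg.matrix_threshold)

    oil = morph_clean(oil_fg, cfg.n_erode, cfg.n_dilate)
    solid = morph_clean(matrix_fg, cfg.n_erode, cfg.n_dilate) & ~oil
    empty = ~(solid | oil)
    return ComponentMasks(solid=solid, oil=oil, empty=empty)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Export a binary mask as an 8-bit 0/255 single-channel TIFF."""
    import tifffile

    tifffile.imwrite(Path(path), np.asarray(mask, bool).astype(np.uint8) * 255)
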