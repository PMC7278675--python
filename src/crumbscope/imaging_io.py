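"""Reading and writing two-channel confocal micrographs.

Fried-dough cross-sections are imaged on a confocal microscope with two
fluorescence channels: a FITC-stained solid matrix (starch/gluten) and a
Nile-red-stained frying oil.  This module reads such images from
multi-channel TIFF files, attaches the physical pixel calibration and
per-sample metadata, and provides channel split/merge helpers.

Images are stored channel-first (``(2, height, width)``) as unsigned 8-bit
integers.  Acquisition conventions default to 512 x 512 frames at
2.768 um per pixel; both can be overridden per file.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

#: Physical edge length of one pixel, in micrometres, used when the file
#: carries no resolution metadata.
DEFAULT_PIXEL_SIZE_UM = 2.768

#: Channel order used when a file carries no channel names: channel 1 is
#: the stained solid matrix, channel 2 the stained oil.
DEFAULT_CHANNEL_ROLES = {"matrix": 0, "oil": 1}

BRAN_TYPES = frozenset({"OB", "WB", "control"})
PRODUCT_TYPES = frozenset({"dough", "batter"})
REGIONS = frozenset({"crumb", "crust"})
BRAN_CONCENTRATIONS = frozenset({0.0, 5.0, 8.0, 10.0, 15.0, 20.0})


class ChannelAssignmentError(ValueError):
    """Raised when matrix/oil channel roles cannot be resolved."""


@dataclass(frozen=True)
class SampleMeta:
    """Formulation metadata for one imaged sample.

    Parameters
    ----------
    bran_type : {"OB", "WB", "control"}
        Bran used in the formulation (oat or wheat), or the bran-free
        control.
    bran_concentration_g : float
        Grams of bran substituted per 100 g flour; one of
        {0, 5, 8, 10, 15, 20}.  Zero if and only if the sample is the
        control.
    product_type : {"dough", "batter"}
        Low-moisture kneaded dough or high-moisture batter.
    initial_moisture_ml : float
        Water added to the dry mix (65 mL for dough, 100 mL for batter).
    region : {"crumb", "crust"}
        Whether the micrograph shows a cross-section (crumb) or the fried
        outer surface (crust).
    """

    bran_type: str = "control"
    bran_concentration_g: float = 0.0
    product_type: str = "dough"
    initial_moisture_ml: float = 65.0
    region: str = "crumb"

    def __post_init__(self) -> None:
        if self.bran_type not in BRAN_TYPES:
            raise ValueError(f"unknown bran_type {self.bran_type!r}")
        if self.product_type not in PRODUCT_TYPES:
            raise ValueError(f"unknown product_type {self.product_type!r}")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if float(self.bran_concentration_g) not in BRAN_CONCENTRATIONS:
            raise ValueError(
                f"bran_concentration_g must be one of {sorted(BRAN_CONCENTRATIONS)}"
            )
        # the control formulation is exactly the zero-bran one
        if (self.bran_type == "control") != (self.bran_concentration_g == 0):
            raise ValueError(
                "bran_type 'control' requires bran_concentration_g == 0 and vice versa"
            )


@dataclass
class Micrograph:
    """A two-channel 8-bit micrograph with physical calibration.

    ``pixels`` has shape ``(2, height, width)`` and dtype uint8.
    ``channel_roles`` maps ``"matrix"`` and ``"oil"`` to channel indices.
    """

    pixels: np.ndarray
    channel_roles: dict = field(default_factory=lambda: dict(DEFAULT_CHANNEL_ROLES))
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    meta: SampleMeta | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[0] < 2:
            raise ValueError("pixels must be (n_channels>=2, height, width)")
        if self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be uint8; use read_micrograph to rescale")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        roles = set(self.channel_roles)
        if roles != {"matrix", "oil"}:
            raise ChannelAssignmentError(
                "channel_roles must assign exactly 'matrix' and 'oil'"
            )
        idx = [self.channel_roles["matrix"], self.channel_roles["oil"]]
        if len(set(idx)) != 2 or not all(0 <= i < self.pixels.shape[0] for i in idx):
            raise ChannelAssignmentError(f"invalid channel indices {idx}")

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of the frame."""
        return self.pixels.shape[1:]

    @property
    def matrix_image(self) -> np.ndarray:
        return self.pixels[self.channel_roles["matrix"]]

    @property
    def oil_image(self) -> np.ndarray:
        return self.pixels[self.channel_roles["oil"]]

    @property
    def frame_area_um2(self) -> float:
        """Physical area of the full frame in um^2."""
        h, w = self.shape
        return h * w * self.pixel_size_um**2


def _rescale_to_uint8(arr: np.ndarray) -> np.ndarray:
    """Min-max rescale arbitrary integer/float data onto [0, 255]."""
    arr = np.asarray(arr, dtype=np.float64)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    out = (arr - lo) / (hi - lo) * 255.0
    return np.rint(out).astype(np.uint8)


def _coerce_channels_first(arr: np.ndarray) -> np.ndarray:
    """Accept (C,H,W) or (H,W,C) layouts and return channels-first."""
    if arr.ndim == 2:
        return arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected a 2-D or 3-D image, got shape {arr.shape}")
    # heuristics: the channel axis is the short one (<=4)
    if arr.shape[0] <= 4 < arr.shape[-1]:
        return arr
    if arr.shape[-1] <= 4 < arr.shape[0]:
        return np.moveaxis(arr, -1, 0)
    return arr  # ambiguous small images: trust channels-first


def _pixel_size_from_tiff(tif: tifffile.TiffFile) -> float | None:
    """Extract the pixel edge length (um) from TIFF resolution tags."""
    page = tif.pages[0]
    tags = page.tags
    xres = tags.get("XResolution")
    unit = tags.get("ResolutionUnit")
    if xres is None:
        return None
    num, den = xres.value
    if num == 0 or den == 0:
        return None
    pixels_per_unit = num / den
    unit_um = {2: 25400.0, 3: 10000.0}.get(getattr(unit, "value", 2) if unit else 2)
    if unit_um is None or pixels_per_unit <= 0:
        return None
    return unit_um / pixels_per_unit


def read_micrograph(
    path: str | Path,
    pixel_size_um: float | None = None,
    meta: SampleMeta | None = None,
    *,
    partner_path: str | Path | None = None,
    channel_roles: dict | None = None,
) -> Micrograph:
    """Read a two-channel micrograph from TIFF.

    Parameters
    ----------
    path : path
        Multi-channel TIFF, or a single-channel TIFF when ``partner_path``
        supplies the second channel.
    pixel_size_um : float, optional
        Physical pixel size override.  When omitted, the TIFF resolution
        tag is used if present, otherwise the acquisition default of
        2.768 um/px.
    meta : SampleMeta, optional
        Formulation metadata to attach.
    partner_path : path, optional
        Second single-channel file; ``path`` is then the matrix channel
        and ``partner_path`` the oil channel (positional convention).
    channel_roles : dict, optional
        Explicit ``{"matrix": i, "oil": j}`` mapping.  Takes priority over
        the positional default (channel 1 = matrix, channel 2 = oil).

    Notes
    -----
    Non-8-bit data (e.g. 16-bit exports) are min-max rescaled onto
    [0, 255] with a warning; the maximum input value maps to 255.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        tag_pixel_size = _pixel_size_from_tiff(tif)

    arr = _coerce_channels_first(arr)

    if partner_path is not None:
        partner = _coerce_channels_first(tifffile.imread(Path(partner_path)))
        if arr.shape[0] != 1 or partner.shape[0] != 1:
            raise ChannelAssignmentError(
                "partner_path is only valid for single-channel files"
            )
        if arr.shape[1:] != partner.shape[1:]:
            raise ChannelAssignmentError("paired files must have equal frame shapes")
        arr = np.concatenate([arr, partner], axis=0)
    elif arr.shape[0] < 2:
        raise ChannelAssignmentError(
            f"{path} has a single channel and no partner file was given"
        )

    if arr.dtype != np.uint8:
        warnings.warn(
            f"{path.name}: {arr.dtype} data rescaled to 8-bit [0, 255]",
            stacklevel=2,
        )
        arr = np.stack([_rescale_to_uint8(c) for c in arr])

    if pixel_size_um is None:
        pixel_size_um = tag_pixel_size if tag_pixel_size else DEFAULT_PIXEL_SIZE_UM

    roles = dict(channel_roles) if channel_roles else dict(DEFAULT_CHANNEL_ROLES)
    return Micrograph(
        pixels=arr, channel_roles=roles, pixel_size_um=float(pixel_size_um), meta=meta
    )


def write_micrograph(path: str | Path, m: Micrograph) -> None:
    """Write a micrograph to multi-channel TIFF with resolution metadata."""
    path = Path(path)
    ppu = 10000.0 / m.pixel_size_um  # pixels per centimetre
    tifffile.imwrite(
        path,
        m.pixels,
        photometric="minisblack",
        resolution=(ppu, ppu),
        resolutionunit="CENTIMETER",
    )


def split_channels(m: Micrograph) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(matrix_image, oil_image)`` honoring the role mapping."""
    return m.matrix_image.copy(), m.oil_image.copy()


def merge_channels(
    matrix_image: np.ndarray,
    oil_image: np.ndarray,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    meta: SampleMeta | None = None,
) -> Micrograph:
    """Build a Micrograph from two single-channel 8-bit grids."""
    matrix_image = np.asarray(matrix_image, dtype=np.uint8)
    oil_image = np.asarray(oil_image, dtype=np.uint8)
    if matrix_image.shape != oil_image.shape:
        raise ValueError("channel shapes differ")
    return Micrograph(
        pixels=np.stack([matrix_image, oil_image]),
        channel_roles=dict(DEFAULT_CHANNEL_ROLES),
        pixel_size_um=pixel_size_um,
        meta=meta,
    )


MANIFEST_COLUMNS = [
    "sample_id",
    "bran_type",
    "bran_concentration_g",
    "product_type",
    "initial_moisture_ml",
    "region",
    "image_path",
]


def read_sample_manifest(path: str | Path) -> pd.DataFrame:
    """Read a per-sample metadata manifest CSV.

    The manifest must provide the columns
    ``sample_id, bran_type, bran_concentration_g, product_type,
    initial_moisture_ml, region, image_path``.  Image paths are resolved
    relative to the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} is missing columns {missing}")
    base = path.parent
    df = df.copy()
    df["image_path"] = [
        str(p) if Path(p).is_absolute() else str(base / p) for p in df["image_path"]
    ]
    return df


def meta_from_row(row) -> SampleMeta:
    """Build a SampleMeta from one manifest row."""
    return SampleMeta(
        bran_type=str(row["bran_type"]),
        bran_concentration_g=float(row["bran_concentration_g"]),
        product_type=str(row["product_type"]),
        initial_moisture_ml=float(row["initial_moisture_ml"]),
        region=str(row["region"]),
    )
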