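"""Fundus image and cohort-table I/O.

Reads colour fundus photographs (PNG/TIFF/JPEG), splits them into their
8-bit R, G, B component images, and delineates the circular illuminated
imaging region whose pixel count defines IR, the denominator of the
choroidal vasculature appearance index CVAI = CVR / IR.

Conventions used throughout the package:

* pixel coordinates are ``(row, col)``, 0-based, row 0 at the top;
* channel order is R, G, B regardless of on-disk byte order;
* binary masks are boolean arrays; on disk they are 8-bit PNGs with
  foreground 255 and background 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import DataError, EmptyFieldError, FormatError

logger = logging.getLogger(__name__)

#: Header of the cohort CSV, in order.
COHORT_COLUMNS = ("eye_id", "group", "choroidal_thickness_um", "age_years", "sere_dioptre")

#: Valid diagnosis groups.
GROUPS = ("normal", "csc")

#: Default intensity floor separating the illuminated field from the black frame.
DEFAULT_INTENSITY_FLOOR = 10


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class FundusImage:
    """An 8-bit RGB colour fundus photograph.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` uint8 array, channels in R, G, B order.
    eye_id
        Identifier used to join the image with its cohort row.
    source_path
        Where the image was loaded from, if anywhere.
    """

    pixels: np.ndarray
    eye_id: str = ""
    source_path: str | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise FormatError(
                f"FundusImage requires an (H, W, 3) array, got shape {px.shape}"
            )
        if px.shape[0] < 64 or px.shape[1] < 64:
            raise FormatError(
                f"FundusImage requires H >= 64 and W >= 64, got {px.shape[:2]}"
            )
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise FormatError("FundusImage intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class ChannelImage:
    """A single 8-bit plane of a fundus photograph (or a derived plane)."""

    pixels: np.ndarray
    channel_label: str = "derived"

    _LABELS = ("R", "G", "B", "derived")

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise FormatError(f"ChannelImage requires a 2-D array, got shape {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise FormatError("ChannelImage intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        if self.channel_label not in self._LABELS:
            raise FormatError(f"channel_label must be one of {self._LABELS}")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryMask:
    """A boolean pixel grid labelling one region of a fundus photograph."""

    pixels: np.ndarray
    role_label: str = "field_of_view"

    _ROLES = ("retinal_vessel", "choroidal_vessel", "optic_disc", "field_of_view")

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise FormatError(f"BinaryMask requires a 2-D array, got shape {px.shape}")
        if px.dtype != bool:
            vals = np.unique(px)
            if not np.isin(vals, (0, 1, 255)).all():
                raise FormatError("BinaryMask must be strictly two-valued")
            px = px > 0
        if self.role_label not in self._ROLES:
            raise FormatError(f"role_label must be one of {self._ROLES}")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def count(self) -> int:
        return int(self.pixels.sum())


# ---------------------------------------------------------------------------
# Image I/O
# ---------------------------------------------------------------------------

def load_fundus(path: str | Path, eye_id: str | None = None) -> FundusImage:
    """Load a colour fundus photograph from PNG, TIFF or JPEG.

    16-bit inputs are down-scaled to 8-bit by integer division (65535 maps
    to 255) with a logged warning. Inputs that do not carry exactly three
    colour planes raise :class:`FormatError` naming the plane count.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except OSError:
        raise
    except Exception as exc:  # decoder-specific failures
        raise OSError(f"could not decode image file {path}: {exc}") from exc

    n_planes = 1 if arr.ndim == 2 else arr.shape[-1]
    if n_planes != 3:
        raise FormatError(
            f"{path}: expected a 3-plane RGB image, got {n_planes} plane(s)"
        )
    if arr.dtype == np.uint16:
        logger.warning("%s: 16-bit input down-scaled to 8-bit by integer division", path)
        arr = (arr // 257).astype(np.uint8)
    elif arr.dtype != np.uint8:
        raise FormatError(f"{path}: unsupported pixel dtype {arr.dtype}")
    return FundusImage(arr, eye_id=eye_id or path.stem, source_path=str(path))


def save_image(img: FundusImage | ChannelImage, path: str | Path) -> None:
    """Write an image as 8-bit PNG (or whatever the extension implies)."""
    iio.imwrite(Path(path), img.pixels)


def save_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a binary mask as an 8-bit 0/255 PNG."""
    iio.imwrite(Path(path), (mask.pixels.astype(np.uint8)) * 255)


def load_mask(path: str | Path, role_label: str = "field_of_view") -> BinaryMask:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return BinaryMask(arr > 127, role_label=role_label)


# ---------------------------------------------------------------------------
# Channel handling
# ---------------------------------------------------------------------------

def split_channels(img: FundusImage) -> tuple[ChannelImage, ChannelImage, ChannelImage]:
    """Separate a colour photograph into its 8-bit R, G, B component images."""
    r, g, b = (img.pixels[..., i] for i in range(3))
    return (
        ChannelImage(r.copy(), "R"),
        ChannelImage(g.copy(), "G"),
        ChannelImage(b.copy(), "B"),
    )


def recombine_channels(
    r: ChannelImage, g: ChannelImage, b: ChannelImage, eye_id: str = ""
) -> FundusImage:
    """Inverse of :func:`split_channels` (bit-exact)."""
    return FundusImage(np.stack([r.pixels, g.pixels, b.pixels], axis=-1), eye_id=eye_id)


# ---------------------------------------------------------------------------
# Field of view
# ---------------------------------------------------------------------------

def detect_field_of_view(
    img: FundusImage, intensity_floor: int = DEFAULT_INTENSITY_FLOOR
) -> BinaryMask:
    """Delineate the circular illuminated fundus field.

    The maximum over the three channels is thresholded at ``intensity_floor``
    (strictly above), the largest connected component is kept and its holes
    filled. The resulting pixel count is IR, the CVAI denominator. Only the
    dark frame determines the mask; interior content above the floor has no
    influence.
    """
    bright = img.pixels.max(axis=2) > intensity_floor
    if not bright.any():
        raise EmptyFieldError(
            f"no pixel above intensity floor {intensity_floor}: empty field of view"
        )
    labels, n = ndimage.label(bright)
    if n > 1:
        sizes = ndimage.sum_labels(bright, labels, index=np.arange(1, n + 1))
        bright = labels == (int(np.argmax(sizes)) + 1)
    filled = ndimage.binary_fill_holes(bright)
    return BinaryMask(filled, role_label="field_of_view")


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Check the cohort-table schema and invariants; returns the table."""
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"cohort table missing column(s): {missing}")
    if table["eye_id"].duplicated().any():
        dupes = table.loc[table["eye_id"].duplicated(), "eye_id"].tolist()
        raise DataError(f"duplicate eye_id(s): {dupes}")
    bad_groups = set(table["group"]) - set(GROUPS)
    if bad_groups:
        raise DataError(f"unknown group value(s): {sorted(bad_groups)}")
    if (table["choroidal_thickness_um"] <= 0).any():
        raise DataError("choroidal_thickness_um must be positive")
    return table


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV (header exactly ``COHORT_COLUMNS``)."""
    table = pd.read_csv(path)
    return validate_cohort(table)


def write_cohort(table: pd.DataFrame, path: str | Path) -> None:
    """Write a validated cohort table with the canonical column order."""
    validate_cohort(table)
    cols = list(COHORT_COLUMNS) + [c for c in table.columns if c not in COHORT_COLUMNS]
    table[cols].to_csv(path, index=False)
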