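"""MRC image I/O and preprocessing for grid-square survey images.

Images are low-magnification grid-square exposures from counting
cameras, stored as 2-D MRC (MRC2014, modes 0/1/2/6).  The pixel size is
taken from the map header (cell / sampling).  MRC carries no standard
field for exposure time or energy-slit state, so both are written into a
header label and recovered on read; files from other software default to
1 s exposure with a warning.

Coordinate convention used throughout the package: 0-based (row, col),
row 0 at the top.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path

import gemmi
import numpy as np
from scipy import ndimage

from .exceptions import FormatError

logger = logging.getLogger("icemap.image_io")

__all__ = [
    "ImagePlane",
    "ImagePair",
    "read_image",
    "write_image",
    "bin_image",
    "median_filter_image",
    "mean_count_rate",
]

_SUPPORTED_MODES = {0, 1, 2, 6}
_MIN_DIM = 16


@dataclass
class ImagePlane:
    """One 2-D image of per-pixel counts with acquisition metadata."""

    data: np.ndarray
    pixel_size_a: float
    exposure_s: float = 1.0
    slit_inserted: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or min(self.data.shape) < _MIN_DIM:
            raise ValueError(
                f"image must be 2-D and at least {_MIN_DIM}x{_MIN_DIM}, "
                f"got shape {self.data.shape}"
            )
        if self.pixel_size_a <= 0:
            raise ValueError("pixel_size_a must be positive")
        if self.exposure_s <= 0:
            raise ValueError("exposure_s must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class ImagePair:
    """Unfiltered (I) and zero-loss filtered (I_zl) exposure of one square."""

    unfiltered: ImagePlane
    filtered: ImagePlane
    shift_px: tuple[float, float] = (0.0, 0.0)
    aligned: bool = False

    def __post_init__(self) -> None:
        if self.unfiltered.shape != self.filtered.shape:
            raise ValueError(
                f"plane shapes differ: {self.unfiltered.shape} vs "
                f"{self.filtered.shape}"
            )
        if not np.isclose(
            self.unfiltered.pixel_size_a, self.filtered.pixel_size_a, rtol=1e-3
        ):
            raise ValueError("plane pixel sizes differ")


_META_RE = re.compile(r"exposure_s=([0-9.eE+-]+)\s+slit=([01])")


def read_image(path: str | Path) -> ImagePlane:
    """Read a 2-D MRC image; pixel size from the header cell.

    Accepts modes 0/1/2/6.  A 3-D volume (nz > 1) is rejected.  Exposure
    metadata is parsed from a header label when this package wrote the
    file; otherwise the exposure defaults to 1 s with a warning.
    """
    path = Path(path)
    if not path.is_file():
        raise FormatError(f"not a readable file: {path}")
    try:
        m = gemmi.read_ccp4_map(str(path))
    except Exception as exc:  # gemmi raises plain RuntimeError
        raise FormatError(f"cannot read MRC file {path}: {exc}") from exc
    mode = m.header_i32(4)
    if mode not in _SUPPORTED_MODES:
        raise FormatError(f"unsupported MRC mode {mode} in {path}")
    nx, ny, nz = (m.header_i32(i) for i in (1, 2, 3))
    if nz != 1:
        raise FormatError(f"expected a single 2-D image, got nz={nz} in {path}")
    arr = np.array(m.grid, copy=True)
    data = arr[:, :, 0].T.astype(float)  # file x (cols) fastest -> (row, col)
    mx = m.header_i32(8) or nx
    pixel = m.grid.unit_cell.a / mx
    if pixel <= 0:
        raise FormatError(f"non-positive pixel size in header of {path}")
    exposure, slit = 1.0, False
    meta = _META_RE.search(_read_labels(m))
    if meta:
        exposure = float(meta.group(1))
        slit = meta.group(2) == "1"
    else:
        logger.warning(
            "code=NO_EXPOSURE_META: %s carries no exposure metadata; "
            "assuming 1 s",
            path.name,
        )
    return ImagePlane(
        data=data,
        pixel_size_a=float(pixel),
        exposure_s=exposure,
        slit_inserted=slit,
        label=path.stem,
    )


def _read_labels(m: gemmi.Ccp4Map) -> str:
    nlabl = max(0, min(10, m.header_i32(56)))
    return " ".join(m.header_str(57 + 20 * i, 80) for i in range(nlabl))


def write_image(plane: ImagePlane, path: str | Path) -> None:
    """Write a plane as mode-2 (float32) MRC with metadata in a label."""
    data = np.ascontiguousarray(plane.data.T[:, :, None], dtype=np.float32)
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(data)
    ny, nx = plane.shape
    px = plane.pixel_size_a
    m.grid.unit_cell = gemmi.UnitCell(nx * px, ny * px, px, 90, 90, 90)
    m.update_ccp4_header()
    m.set_header_str(
        77, f"exposure_s={plane.exposure_s:g} slit={int(plane.slit_inserted)}"
    )
    m.set_header_i32(56, 2)
    m.write_ccp4_map(str(path))


def bin_image(plane: ImagePlane, factor: int) -> ImagePlane:
    """Block-mean binning by an integer factor.

    Mean pooling (not summation) keeps the image mean — and therefore
    every intensity ratio — invariant, so thickness computation commutes
    with binning.  Trailing rows/columns that do not fill a block are
    cropped with a warning.  The pixel size scales by the factor.
    """
    if factor < 1:
        raise ValueError(f"bin factor must be >= 1, got {factor}")
    if factor == 1:
        return replace(plane, data=plane.data.copy())
    ny, nx = plane.shape
    my, mx = ny // factor, nx // factor
    if my * factor != ny or mx * factor != nx:
        logger.warning(
            "code=BIN_CROP: cropping %dx%d image to %dx%d for factor-%d binning",
            ny,
            nx,
            my * factor,
            mx * factor,
            factor,
        )
    cropped = plane.data[: my * factor, : mx * factor]
    binned = cropped.reshape(my, factor, mx, factor).mean(axis=(1, 3))
    return replace(plane, data=binned, pixel_size_a=plane.pixel_size_a * factor)


def median_filter_image(plane: ImagePlane, kernel: int = 3) -> ImagePlane:
    """Median filter over a kernel x kernel window, reflected edges.

    The default 3x3 window matches the survey-image noise-reduction
    setting this package mirrors.
    """
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"median kernel must be odd and >= 1, got {kernel}")
    if kernel == 1:
        return replace(plane, data=plane.data.copy())
    filtered = ndimage.median_filter(plane.data, size=kernel, mode="reflect")
    return replace(plane, data=filtered)


def mean_count_rate(plane: ImagePlane) -> float:
    """Mean counts per pixel per second over the plane."""
    return float(np.nanmean(plane.data)) / plane.exposure_s
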