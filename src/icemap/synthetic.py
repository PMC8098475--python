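"""Forward simulation of grid-square image pairs with known ground truth.

The generative model mirrors the zero-loss attenuation law.  A periodic
lattice of circular holes sits in a darker support film; the unfiltered
image carries the incident count rate (times a small empty-hole excess
factor inside holes, reproducing the observation that an empty hole
reads brighter than open vacuum), and the filtered image is attenuated
by exp(-(D + C_gen)/lambda) inside holes, where D is the ice-thickness
field and C_gen models the extra apparent attenuation that the
correction term removes.  The support film is attenuated with D = 0
under the same law.  Optionally the filtered image is translated (the
energy-shift-induced image shift) and independent Poisson counting
noise is applied per pixel and plane.

Defaults reproduce the 200 kV survey conditions this package is
calibrated for: 10.7 counts/px/s, 1 s exposure, 144.6 Angstrom pixels,
lambda = 305 nm with C = 4 nm, and R1.2/1.3-style hole geometry (1.2 um
holes on a 2.5 um pitch).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage

from .calibration import CalibrationProfile, CalibrationSample, default_profile
from .exceptions import IcemapError
from .image_io import ImagePair, ImagePlane
from .targeting import HoleLattice

__all__ = [
    "SyntheticScene",
    "make_lattice",
    "make_thickness_field",
    "simulate_pair",
    "simulate_calibration_set",
]

DEFAULT_PIXEL_SIZE_A = 144.6  # survey magnification, 200 kV instrument
DEFAULT_COUNT_RATE = 10.7  # counts / px / s at that magnification
DEFAULT_HOLE_RADIUS_UM = 0.6  # R1.2/1.3 film: 1.2 um holes ...
DEFAULT_SPACING_UM = 2.5  # ... on a 2.5 um pitch


def make_lattice(
    image_shape: tuple[int, int],
    pixel_size_a: float = DEFAULT_PIXEL_SIZE_A,
    spacing_um: float = DEFAULT_SPACING_UM,
    hole_radius_um: float = DEFAULT_HOLE_RADIUS_UM,
    rotation_deg: float = 0.0,
    origin_px: tuple[float, float] | None = None,
) -> HoleLattice:
    """Square hole lattice in pixel coordinates, optionally rotated."""
    spacing_px = spacing_um * 1e4 / pixel_size_a
    radius_px = hole_radius_um * 1e4 / pixel_size_a
    th = np.deg2rad(rotation_deg)
    v1 = (spacing_px * np.cos(th), spacing_px * np.sin(th))
    v2 = (-spacing_px * np.sin(th), spacing_px * np.cos(th))
    if origin_px is None:
        origin_px = (image_shape[0] / 2.0, image_shape[1] / 2.0)
    return HoleLattice(
        origin_px=origin_px,
        v1_px=v1,
        v2_px=v2,
        hole_radius_px=radius_px,
        spacing_um=spacing_um,
    )


@dataclass
class SyntheticScene:
    """Ground-truth description of one simulated grid square."""

    lattice: HoleLattice
    image_shape: tuple[int, int]
    thickness_field: np.ndarray | Callable[[np.ndarray, np.ndarray], np.ndarray]
    profile: CalibrationProfile = field(
        default_factory=lambda: default_profile(200, "M_SA", "FILTER")
    )
    vacuum_offset_nm: float = 4.0
    film_transmission: float = 0.5
    hole_open_vacuum_factor: float = 1.02
    incident_rate: float = DEFAULT_COUNT_RATE
    exposure_s: float = 1.0
    pixel_size_a: float = DEFAULT_PIXEL_SIZE_A
    filtered_shift_px: tuple[float, float] = (0.0, 0.0)
    poisson_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.incident_rate <= 0:
            raise ValueError("incident_rate must be positive")
        if not 0 < self.film_transmission < 1:
            raise ValueError("film_transmission must be in (0, 1)")
        if self.hole_open_vacuum_factor < 1:
            raise ValueError("hole_open_vacuum_factor must be >= 1")
        if self.vacuum_offset_nm < 0:
            raise ValueError("vacuum_offset_nm must be non-negative")


def make_thickness_field(
    kind: str,
    params: dict,
    shape: tuple[int, int],
    seed: int = 0,
) -> np.ndarray:
    """Gridded thickness field D(row, col) in nm.

    ``uniform``: constant ``value``.  ``gradient``: linear ramp from
    ``start`` to ``end`` along ``axis`` (default columns).  ``blobs``:
    Gaussian random field smoothed over ``smooth_px`` with the requested
    ``mean`` and ``sd``, clipped at 0.
    """
    ny, nx = shape
    if kind == "uniform":
        return np.full(shape, float(params["value"]))
    if kind == "gradient":
        axis = int(params.get("axis", 1))
        start, end = float(params["start"]), float(params["end"])
        n = shape[axis]
        ramp = np.linspace(start, end, n)
        field_ = np.broadcast_to(
            ramp if axis == 1 else ramp[:, None], shape
        ).copy()
        return field_
    if kind == "blobs":
        rng = np.random.default_rng(seed)
        smooth = float(params.get("smooth_px", min(shape) / 16))
        raw = ndimage.gaussian_filter(rng.standard_normal(shape), smooth)
        sd_raw = raw.std()
        if sd_raw == 0:
            raw = np.zeros(shape)
        else:
            raw = (raw - raw.mean()) / sd_raw  # exact sample moments
        field_ = float(params["mean"]) + float(params["sd"]) * raw
        return np.clip(field_, 0.0, None)
    raise ValueError(f"unknown thickness field kind {kind!r}")


def _resolve_field(scene: SyntheticScene) -> np.ndarray:
    if callable(scene.thickness_field):
        yy, xx = np.mgrid[: scene.image_shape[0], : scene.image_shape[1]]
        d = np.asarray(scene.thickness_field(yy, xx), dtype=float)
    else:
        d = np.asarray(scene.thickness_field, dtype=float)
    if d.shape != tuple(scene.image_shape):
        raise IcemapError(
            f"thickness field shape {d.shape} != image shape {scene.image_shape}"
        )
    if np.any(d < 0):
        raise IcemapError("thickness field must be non-negative everywhere")
    return d


def _hole_centers(scene: SyntheticScene) -> np.ndarray:
    """Centers (row, col) of all lattice holes with center inside the image."""
    lat = scene.lattice
    ny, nx = scene.image_shape
    basis = lat.basis()
    corners = np.array(
        [[0, 0], [0, nx], [ny, 0], [ny, nx]], dtype=float
    ) - np.asarray(lat.origin_px)
    idx = corners @ np.linalg.inv(basis).T
    lo = np.floor(idx.min(axis=0)).astype(int) - 1
    hi = np.ceil(idx.max(axis=0)).astype(int) + 1
    n1, n2 = np.mgrid[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1]
    nn = np.column_stack([n1.ravel(), n2.ravel()])
    centers = lat.nodes_at(nn)
    inside = (
        (centers[:, 0] >= 0)
        & (centers[:, 0] <= ny - 1)
        & (centers[:, 1] >= 0)
        & (centers[:, 1] <= nx - 1)
    )
    centers = centers[inside]
    order = np.lexsort((np.rint(nn[inside][:, 1]), np.rint(nn[inside][:, 0])))
    return centers[order]


def simulate_pair(scene: SyntheticScene) -> tuple[ImagePair, pd.DataFrame]:
    """Render the unfiltered/filtered pair and the per-hole truth table.

    The truth table has one row per hole whose center lies inside the
    image: id (in lattice order, matching the detector's ordering
    convention), center, the disk-averaged true thickness over the full
    hole, and an ``is_edge`` flag for holes whose disk is not fully
    inside the image.
    """
    ny, nx = scene.image_shape
    d = _resolve_field(scene)
    centers = _hole_centers(scene)
    rad = scene.lattice.hole_radius_px

    hole_mask = np.zeros((ny, nx), dtype=bool)
    rows = []
    for hid, (cy, cx) in enumerate(centers):
        r0, r1 = int(np.floor(cy - rad)), int(np.ceil(cy + rad)) + 1
        c0, c1 = int(np.floor(cx - rad)), int(np.ceil(cx + rad)) + 1
        rr0, rr1 = max(0, r0), min(ny, r1)
        cc0, cc1 = max(0, c0), min(nx, c1)
        yy, xx = np.mgrid[rr0:rr1, cc0:cc1]
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= rad**2
        hole_mask[rr0:rr1, cc0:cc1] |= disk
        is_edge = (
            cy - rad < 2 or cx - rad < 2 or cy + rad > ny - 3 or cx + rad > nx - 3
        )
        mean_d = float(np.mean(d[rr0:rr1, cc0:cc1][disk])) if disk.any() else np.nan
        rows.append((hid, cy, cx, mean_d, is_edge))
    truth = pd.DataFrame(
        rows, columns=["id", "row_px", "col_px", "true_mean_thickness_nm", "is_edge"]
    )

    scale = scene.profile.scale_nm
    rate_unf = np.where(
        hole_mask,
        scene.incident_rate * scene.hole_open_vacuum_factor,
        scene.incident_rate * scene.film_transmission,
    )
    attn = np.where(
        hole_mask,
        np.exp(-(d + scene.vacuum_offset_nm) / scale),
        np.exp(-scene.vacuum_offset_nm / scale),  # film: D = 0, same law
    )
    expected_unf = rate_unf * scene.exposure_s
    expected_fil = expected_unf * attn
    dy, dx = scene.filtered_shift_px
    if dy != 0 or dx != 0:
        expected_fil = ndimage.shift(
            expected_fil, (dy, dx), order=1, mode="nearest"
        )
    rng = np.random.default_rng(scene.seed)
    if scene.poisson_noise:
        data_unf = rng.poisson(expected_unf).astype(float)
        data_fil = rng.poisson(expected_fil).astype(float)
    else:
        data_unf = expected_unf
        data_fil = expected_fil
    unf = ImagePlane(
        data=data_unf,
        pixel_size_a=scene.pixel_size_a,
        exposure_s=scene.exposure_s,
        slit_inserted=False,
        label="synthetic unfiltered",
    )
    fil = ImagePlane(
        data=data_fil,
        pixel_size_a=scene.pixel_size_a,
        exposure_s=scene.exposure_s,
        slit_inserted=True,
        label="synthetic filtered",
    )
    return ImagePair(unfiltered=unf, filtered=fil), truth


def simulate_calibration_set(
    true_lambda_nm: float,
    true_c_nm: float,
    n_holes: int,
    thickness_range: tuple[float, float] = (20.0, 200.0),
    noise_sd_nm: float = 5.0,
    seed: int = 0,
    n_vacuum: int = 3,
) -> list[CalibrationSample]:
    """Synthetic calibration table: exact attenuation, noisy reference.

    Hole thicknesses are uniform over ``thickness_range`` (default 20-200
    nm, spanning the dynamic range a calibration session covers across
    squares); log-attenuation is (D + C)/lambda exactly, and the
    independently measured thickness is D plus Gaussian noise (floored
    at 0).  Three exact vacuum samples (D = 0) are appended.
    """
    if n_holes < 2:
        raise IcemapError(f"need at least 2 calibration holes, got {n_holes}")
    lo, hi = thickness_range
    if not 0 <= lo < hi:
        raise IcemapError(f"invalid thickness range {thickness_range}")
    rng = np.random.default_rng(seed)
    d = rng.uniform(lo, hi, size=n_holes)
    noise = rng.normal(0.0, noise_sd_nm, size=n_holes) if noise_sd_nm > 0 else 0.0
    samples = [
        CalibrationSample(
            log_attenuation=float((di + true_c_nm) / true_lambda_nm),
            true_thickness_nm=float(max(di + ei, 0.0)),
            is_vacuum=False,
        )
        for di, ei in zip(d, np.broadcast_to(noise, d.shape))
    ]
    samples += [
        CalibrationSample(
            log_attenuation=float(true_c_nm / true_lambda_nm),
            true_thickness_nm=0.0,
            is_vacuum=True,
        )
        for _ in range(n_vacuum)
    ]
    return samples
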