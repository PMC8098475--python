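"""Hole detection, per-hole thickness, target selection and grouping.

Holey support films carry a periodic lattice of circular holes, so hole
finding is posed as lattice estimation plus template matching: the two
shortest non-collinear peaks of the image autocorrelation give the
lattice basis, a disk template scores candidate centers, and candidates
snap to the nearest lattice node.  Per-hole thickness is the zero-loss
formula applied to the ratio of the mean intensities inside a disk
(ratio of means — deliberately different from the pixel-map convention,
which averages the ratio image).  Selected holes are grouped into
beam-image-shift patterns (e.g. 3 x 3); unselected holes are skipped,
never acquired as fillers.

Target lists are exported in the SerialEM Navigator autodoc dialect with
the thickness stored in each item's Note.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.feature import match_template, peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label, regionprops

from .calibration import CalibrationProfile, thickness_filter
from .exceptions import IcemapError, InvalidMeasurementError, LatticeError
from .image_io import ImagePair, ImagePlane
from .mapping import SelectionPolicy

logger = logging.getLogger("icemap.targeting")

__all__ = [
    "HoleLattice",
    "Hole",
    "AcquisitionGroup",
    "StageTransform",
    "SelectionSummary",
    "NavigatorItem",
    "QualityCorrelation",
    "estimate_lattice",
    "detect_holes",
    "measure_holes",
    "select_holes",
    "reselect_holes",
    "group_holes",
    "export_navigator",
    "parse_navigator",
    "correlate_quality",
    "holes_to_dataframe",
    "dataframe_to_holes",
]


@dataclass(frozen=True)
class HoleLattice:
    """Periodic hole lattice: origin, basis vectors, hole radius (pixels)."""

    origin_px: tuple[float, float]
    v1_px: tuple[float, float]
    v2_px: tuple[float, float]
    hole_radius_px: float
    spacing_um: float

    def __post_init__(self) -> None:
        if abs(self.cross()) <= 0:
            raise ValueError("degenerate lattice basis")
        if self.hole_radius_px >= 0.5 * min(
            np.hypot(*self.v1_px), np.hypot(*self.v2_px)
        ):
            raise ValueError("hole radius must be below half the lattice spacing")

    def cross(self) -> float:
        return self.v1_px[0] * self.v2_px[1] - self.v1_px[1] * self.v2_px[0]

    def basis(self) -> np.ndarray:
        """Basis matrix with v1, v2 as columns (row/col components as rows)."""
        return np.array(
            [[self.v1_px[0], self.v2_px[0]], [self.v1_px[1], self.v2_px[1]]]
        )

    def indices_of(self, points_px: np.ndarray) -> np.ndarray:
        """Continuous lattice indices (n1, n2) of (row, col) points."""
        rel = np.atleast_2d(points_px) - np.asarray(self.origin_px)
        return rel @ np.linalg.inv(self.basis()).T

    def nodes_at(self, indices: np.ndarray) -> np.ndarray:
        return np.asarray(self.origin_px) + np.atleast_2d(indices) @ self.basis().T


@dataclass
class Hole:
    """One detected hole with per-hole intensities and thickness."""

    id: int
    center_px: tuple[float, float]
    mean_unfiltered: float = float("nan")
    mean_filtered: float = float("nan")
    thickness_nm: float | None = None
    selected: bool = False
    group_id: int | None = None
    flags: frozenset[str] = frozenset()

    def has_flag(self, name: str) -> bool:
        return name in self.flags


@dataclass(frozen=True)
class AcquisitionGroup:
    """One beam-image-shift group of selected holes."""

    id: int
    pattern: tuple[int, int]
    member_ids: tuple[int, ...]
    anchor_id: int

    def __post_init__(self) -> None:
        if not 1 <= len(self.member_ids) <= self.pattern[0] * self.pattern[1]:
            raise ValueError("group size must fit the pattern")


@dataclass(frozen=True)
class SelectionSummary:
    n_below: int
    n_within: int
    n_above: int
    n_flagged: int

    @property
    def n_total(self) -> int:
        return self.n_below + self.n_within + self.n_above + self.n_flagged


# ---------------------------------------------------------------------------
# Lattice estimation
# ---------------------------------------------------------------------------


def _autocorrelation(data: np.ndarray, smooth_sigma: float = 2.0) -> np.ndarray:
    x = np.nan_to_num(data, nan=float(np.nanmean(data)))
    x = ndimage.gaussian_filter(x, smooth_sigma)
    x = x - x.mean()
    f = np.fft.rfft2(x)
    ac = np.fft.irfft2(np.abs(f) ** 2, s=x.shape)
    return np.fft.fftshift(ac)


def _refine_peak(ac: np.ndarray, peak: np.ndarray) -> np.ndarray:
    """Sub-pixel peak position by separable parabolic fit on a 3x3 patch."""
    r, c = int(peak[0]), int(peak[1])
    ny, nx = ac.shape
    if not (1 <= r < ny - 1 and 1 <= c < nx - 1):
        return peak.astype(float)
    out = np.array([r, c], dtype=float)
    for axis, (m, p) in enumerate(
        [(ac[r - 1, c], ac[r + 1, c]), (ac[r, c - 1], ac[r, c + 1])]
    ):
        center = ac[r, c]
        denom = m - 2 * center + p
        if denom < 0:
            out[axis] += 0.5 * (m - p) / denom
    return out


def _canonical(v: np.ndarray) -> np.ndarray:
    if v[0] < 0 or (v[0] == 0 and v[1] < 0):
        return -v
    return v


def estimate_lattice(
    plane: ImagePlane, spacing_hint_um: float | None = None
) -> HoleLattice:
    """Estimate the hole lattice of a grid-square image.

    Basis vectors come from the two shortest non-collinear peaks of the
    image autocorrelation (sub-pixel refined); hole radius and origin
    come from thresholded connected components, and basis and origin are
    then jointly refined by least squares against the component
    centroids.  Raises :class:`LatticeError` when no periodic structure
    is found.
    """
    data = plane.data
    ny, nx = data.shape
    ac = _autocorrelation(data)
    center = np.array([ny // 2, nx // 2])
    min_sep = 10.0
    if spacing_hint_um is not None:
        min_sep = max(min_sep, 0.5 * spacing_hint_um * 1e4 / plane.pixel_size_a)
    peaks = peak_local_max(
        ac, min_distance=5, num_peaks=120, exclude_border=False
    ).astype(float)
    vectors = []
    central = ac[center[0], center[1]]
    for p in peaks:
        v = _refine_peak(ac, p) - center
        norm = np.hypot(*v)
        if norm < min_sep or norm > 0.45 * min(ny, nx):
            continue
        # genuine lattice sidelobes carry a large share of the image
        # variance (~0.7 of the central peak here); extreme values of a
        # structureless autocorrelation stay below ~0.05
        if ac[int(p[0]), int(p[1])] < 0.1 * central:
            continue
        vectors.append(_canonical(v))
    if len(vectors) < 2:
        raise LatticeError("no periodic hole structure found in image")
    vectors.sort(key=lambda v: np.hypot(*v))
    v1 = vectors[0]
    v2 = None
    for v in vectors[1:]:
        sin = abs(v1[0] * v[1] - v1[1] * v[0]) / (np.hypot(*v1) * np.hypot(*v))
        if sin > 0.25:
            v2 = v
            break
    if v2 is None:
        raise LatticeError("only collinear autocorrelation peaks found")

    radius, centroids = _blob_stats(data)
    if centroids.shape[0] < 9:
        raise LatticeError(
            f"found only {centroids.shape[0]} candidate holes; need >= 9"
        )
    origin = centroids[
        np.argmin(np.linalg.norm(centroids - center, axis=1))
    ]
    origin, basis = _refine_lattice(origin, np.column_stack([v1, v2]), centroids)
    v1, v2 = basis[:, 0], basis[:, 1]
    spacing_um = float(np.hypot(*v1)) * plane.pixel_size_a * 1e-4
    return HoleLattice(
        origin_px=(float(origin[0]), float(origin[1])),
        v1_px=(float(v1[0]), float(v1[1])),
        v2_px=(float(v2[0]), float(v2[1])),
        hole_radius_px=float(radius),
        spacing_um=spacing_um,
    )


def _blob_stats(data: np.ndarray) -> tuple[float, np.ndarray]:
    """Hole radius and centroids from Otsu-thresholded components.

    Holes are brighter than the surrounding support film; smoothing
    before thresholding suppresses counting noise.  Components touching
    the border or with outlying area are dropped.
    """
    smooth = ndimage.gaussian_filter(np.nan_to_num(data, nan=0.0), 3.0)
    try:
        thr = threshold_otsu(smooth)
    except ValueError as exc:
        raise LatticeError(f"cannot threshold image: {exc}") from exc
    labels = sk_label(smooth > thr)
    regions = regionprops(labels)
    if not regions:
        raise LatticeError("no connected components above threshold")
    ny, nx = data.shape
    interior = [
        r
        for r in regions
        if r.bbox[0] > 0 and r.bbox[1] > 0 and r.bbox[2] < ny and r.bbox[3] < nx
    ]
    if not interior:
        raise LatticeError("no interior components found")
    areas = np.array([r.area for r in interior])
    med = np.median(areas)
    keep = [r for r, a in zip(interior, areas) if 0.3 * med <= a <= 3 * med]
    radius = float(np.median([np.sqrt(r.area / np.pi) for r in keep]))
    centroids = np.array([r.centroid for r in keep], dtype=float)
    return radius, centroids


def _refine_lattice(
    origin: np.ndarray, basis: np.ndarray, points: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares refinement of origin and basis from snapped points."""
    for _ in range(2):
        rel = points - origin
        n = np.rint(rel @ np.linalg.inv(basis).T)
        # solve points ~= origin + n @ basis.T  (linear in origin and basis)
        a = np.column_stack([np.ones(len(points)), n])
        coef, *_ = np.linalg.lstsq(a, points, rcond=None)
        origin = coef[0]
        basis = coef[1:].T
    return origin, basis


# ---------------------------------------------------------------------------
# Detection and measurement
# ---------------------------------------------------------------------------


def _disk_template(radius: float) -> np.ndarray:
    r = max(2, int(round(radius)))
    size = 2 * r + 5
    yy, xx = np.mgrid[:size, :size] - (size - 1) / 2.0
    return (yy**2 + xx**2 <= radius**2).astype(float)


def detect_holes(
    plane: ImagePlane,
    lattice: HoleLattice,
    edge_margin_px: float | None = None,
    include_edge: bool = False,
    ncc_threshold: float = 0.4,
) -> list[Hole]:
    """Locate holes: disk-template matching snapped to lattice nodes.

    Candidate centers are local maxima of the normalized cross-correlation
    with a disk template; each candidate snaps to the nearest lattice node
    and duplicates per node keep the best score.  Holes whose disk runs
    within ``edge_margin_px`` of the image border (default: hole radius
    + 2 px), or whose surround is darker than support film (grid bar),
    are flagged ``edge`` and excluded unless ``include_edge``.  Ids are
    assigned in lattice-index order and centers are the snapped node
    positions of the refined lattice.
    """
    data = np.nan_to_num(plane.data, nan=0.0)
    ny, nx = data.shape
    if edge_margin_px is None:
        edge_margin_px = lattice.hole_radius_px + 2.0
    template = _disk_template(lattice.hole_radius_px)
    response = np.nan_to_num(match_template(data, template, pad_input=True))
    spacing = min(np.hypot(*lattice.v1_px), np.hypot(*lattice.v2_px))
    peaks = peak_local_max(
        response,
        min_distance=max(3, int(0.45 * spacing)),
        threshold_abs=ncc_threshold,
        exclude_border=False,
    ).astype(float)
    if peaks.size == 0:
        return []
    # snap candidates to lattice nodes, keeping the best score per node
    idx = lattice.indices_of(peaks)
    n_int = np.rint(idx)
    resid = np.linalg.norm((idx - n_int) @ lattice.basis().T, axis=1)
    best: dict[tuple[int, int], tuple[float, np.ndarray]] = {}
    for p, n, r in zip(peaks, n_int, resid):
        if r > 0.35 * spacing:
            continue
        key = (int(n[0]), int(n[1]))
        score = response[int(p[0]), int(p[1])]
        if key not in best or score > best[key][0]:
            best[key] = (score, n)
    if not best:
        return []
    # refine the origin with the surviving candidates, then place centers
    # on the refined nodes (sub-pixel, robust to per-hole noise)
    nodes = np.array([n for _, n in best.values()])
    centers = lattice.nodes_at(nodes)
    order = np.lexsort((nodes[:, 1], nodes[:, 0]))
    holes = [
        Hole(id=hid, center_px=(float(centers[k][0]), float(centers[k][1])))
        for hid, k in enumerate(order)
    ]
    holes = _flag_edges(holes, plane, lattice, edge_margin_px)
    if not include_edge:
        holes = [h for h in holes if not h.has_flag("edge")]
    return holes


def _flag_edges(
    holes: list[Hole],
    plane: ImagePlane,
    lattice: HoleLattice,
    edge_margin_px: float,
) -> list[Hole]:
    data = np.nan_to_num(plane.data, nan=0.0)
    ny, nx = data.shape
    rad = lattice.hole_radius_px
    out = []
    for h in holes:
        cy, cx = h.center_px
        flags = set(h.flags)
        if (
            cy < edge_margin_px
            or cx < edge_margin_px
            or cy > ny - 1 - edge_margin_px
            or cx > nx - 1 - edge_margin_px
        ):
            flags.add("edge")
        else:
            ring = _annulus_mean(data, (cy, cx), 1.2 * rad, 1.5 * rad)
            disk = _disk_mean(data, (cy, cx), 0.7 * rad)
            if np.isfinite(ring) and np.isfinite(disk) and ring < 0.15 * disk:
                flags.add("edge")  # surround darker than film: grid bar
        out.append(replace(h, flags=frozenset(flags)))
    return out


def _disk_indices(
    shape: tuple[int, int], center: tuple[float, float], radius: float
) -> tuple[np.ndarray, np.ndarray]:
    cy, cx = center
    r0 = max(0, int(np.floor(cy - radius)))
    r1 = min(shape[0], int(np.ceil(cy + radius)) + 1)
    c0 = max(0, int(np.floor(cx - radius)))
    c1 = min(shape[1], int(np.ceil(cx + radius)) + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    return yy[mask], xx[mask]


def _disk_mean(data: np.ndarray, center: tuple[float, float], radius: float) -> float:
    yy, xx = _disk_indices(data.shape, center, radius)
    if yy.size == 0:
        return float("nan")
    return float(np.mean(data[yy, xx]))


def _annulus_mean(
    data: np.ndarray, center: tuple[float, float], r_in: float, r_out: float
) -> float:
    yy, xx = _disk_indices(data.shape, center, r_out)
    if yy.size == 0:
        return float("nan")
    cy, cx = center
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    sel = d2 >= r_in**2
    if not sel.any():
        return float("nan")
    return float(np.mean(data[yy[sel], xx[sel]]))


def measure_holes(
    holes: Sequence[Hole],
    pair: ImagePair,
    profile: CalibrationProfile,
    hole_radius_px: float,
    radius_fraction: float = 0.5,
) -> list[Hole]:
    """Per-hole mean intensities and thickness, ratio-of-means convention.

    Both planes are averaged over a disk of ``radius_fraction`` times the
    hole radius and the thickness formula is applied to the two means.
    The fraction should be chosen from the magnification and binning: at
    survey magnification, where counts per hole are scarce, a large disk
    (up to the full hole) minimizes the counting error; the conservative
    default 0.5 avoids the hole edge entirely.  Disks with fewer than 5
    pixels flag ``low_confidence``; non-positive means flag ``invalid``
    with non-finite thickness.
    """
    if not pair.aligned:
        raise IcemapError("pair must be aligned before measuring holes")
    if not 0 < radius_fraction <= 1:
        raise ValueError(f"radius_fraction must be in (0, 1], got {radius_fraction}")
    radius = radius_fraction * hole_radius_px
    unf = pair.unfiltered.data
    fil = pair.filtered.data
    out = []
    for h in holes:
        yy, xx = _disk_indices(unf.shape, h.center_px, radius)
        flags = set(h.flags)
        if yy.size < 5:
            flags.add("low_confidence")
        vals_u = unf[yy, xx]
        vals_f = fil[yy, xx]
        ok = np.isfinite(vals_u) & np.isfinite(vals_f)
        mu = float(np.mean(vals_u[ok])) if ok.any() else float("nan")
        mf = float(np.mean(vals_f[ok])) if ok.any() else float("nan")
        if not (np.isfinite(mu) and np.isfinite(mf)) or mu <= 0 or mf <= 0:
            flags.add("invalid")
            thickness = float("nan")
        else:
            thickness = thickness_filter(mu, mf, profile, clamp=False)
        out.append(
            replace(
                h,
                mean_unfiltered=mu,
                mean_filtered=mf,
                thickness_nm=thickness,
                flags=frozenset(flags),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Selection, re-selection, grouping
# ---------------------------------------------------------------------------


def select_holes(
    holes: Sequence[Hole], policy: SelectionPolicy
) -> tuple[list[Hole], SelectionSummary]:
    """Threshold selection: select holes inside the window, inclusive.

    Negative readings are clamped to 0 for classification.  Holes with
    ``invalid`` or ``edge`` flags are never selected and are counted as
    flagged rather than classified.
    """
    out = []
    n_below = n_within = n_above = n_flagged = 0
    for h in holes:
        t = h.thickness_nm
        blocked = h.has_flag("invalid") or h.has_flag("edge")
        if t is None or not np.isfinite(t):
            blocked = True
        if blocked:
            n_flagged += 1
            out.append(replace(h, selected=False, group_id=None))
            continue
        clamped = max(float(t), 0.0)
        if clamped < policy.t_min_nm:
            n_below += 1
            sel = False
        elif clamped > policy.t_max_nm:
            n_above += 1
            sel = False
        else:
            n_within += 1
            sel = True
        out.append(replace(h, selected=sel, group_id=None))
    return out, SelectionSummary(n_below, n_within, n_above, n_flagged)


def reselect_holes(
    holes: Sequence[Hole], new_policy: SelectionPolicy
) -> tuple[list[Hole], SelectionSummary]:
    """Re-threshold stored thicknesses without re-measuring; idempotent."""
    missing = [h.id for h in holes if h.thickness_nm is None]
    if missing:
        raise IcemapError(f"holes without stored thickness: {missing}")
    return select_holes(holes, new_policy)


def group_holes(
    holes: Sequence[Hole],
    lattice: HoleLattice,
    pattern: tuple[int, int] = (3, 3),
) -> tuple[list[Hole], list[AcquisitionGroup]]:
    """Tile selected holes into beam-image-shift groups.

    The lattice index plane is tiled greedily into ``pattern`` blocks
    anchored at the minimal lattice index among selected holes.  A group
    contains only selected holes (unselected positions are skipped, the
    group stays partial) and every selected hole lands in exactly one
    group.  The anchor is the member nearest the group centroid.
    """
    rows, cols = pattern
    if rows < 1 or cols < 1:
        raise ValueError(f"pattern must be >= (1, 1), got {pattern}")
    selected = [h for h in holes if h.selected]
    if not selected:
        return [replace(h, group_id=None) for h in holes], []
    centers = np.array([h.center_px for h in selected])
    n = np.rint(lattice.indices_of(centers)).astype(int)
    n0 = n.min(axis=0)
    blocks = (n - n0) // np.array([rows, cols])
    order = np.lexsort((blocks[:, 1], blocks[:, 0]))
    group_of: dict[tuple[int, int], list[int]] = {}
    for k in order:
        group_of.setdefault((int(blocks[k, 0]), int(blocks[k, 1])), []).append(k)
    groups: list[AcquisitionGroup] = []
    hole_group: dict[int, int] = {}
    for gid, key in enumerate(sorted(group_of)):
        members = group_of[key]
        mcent = centers[members].mean(axis=0)
        anchor = selected[
            members[int(np.argmin(np.linalg.norm(centers[members] - mcent, axis=1)))]
        ].id
        member_ids = tuple(selected[k].id for k in members)
        groups.append(
            AcquisitionGroup(
                id=gid, pattern=(rows, cols), member_ids=member_ids, anchor_id=anchor
            )
        )
        for hid in member_ids:
            hole_group[hid] = gid
    out = [
        replace(h, group_id=hole_group.get(h.id) if h.selected else None)
        for h in holes
    ]
    return out, groups


# ---------------------------------------------------------------------------
# Navigator export / parse
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StageTransform:
    """Affine map from pixel (row, col) to stage (x, y) in micrometres."""

    matrix: tuple[tuple[float, float], tuple[float, float]]
    offset_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("singular stage transform")

    @classmethod
    def from_pixel_size(cls, pixel_size_a: float) -> "StageTransform":
        s = pixel_size_a * 1e-4  # Angstrom -> micrometre
        return cls(matrix=((0.0, s), (s, 0.0)))  # x = col * s, y = row * s

    def apply(self, point_px: tuple[float, float]) -> tuple[float, float]:
        m = np.asarray(self.matrix)
        xy = m @ np.asarray(point_px, dtype=float) + np.asarray(self.offset_um)
        return float(xy[0]), float(xy[1])


@dataclass(frozen=True)
class NavigatorItem:
    """One parsed Navigator item."""

    id: int
    stage_xy_um: tuple[float, float]
    thickness_nm: float
    acquire: bool
    color: int
    group_id: int | None = None


# Color indices in the export: 0 = within window, 1 = below, 2 = above,
# 3 = flagged/invalid (documented here; acquisition software palettes vary).
_COLOR_WITHIN, _COLOR_BELOW, _COLOR_ABOVE, _COLOR_FLAGGED = 0, 1, 2, 3


def _hole_color(h: Hole, policy: SelectionPolicy) -> int:
    t = h.thickness_nm
    if (
        t is None
        or not np.isfinite(t)
        or h.has_flag("invalid")
        or h.has_flag("edge")
    ):
        return _COLOR_FLAGGED
    clamped = max(float(t), 0.0)
    if clamped < policy.t_min_nm:
        return _COLOR_BELOW
    if clamped > policy.t_max_nm:
        return _COLOR_ABOVE
    return _COLOR_WITHIN


def export_navigator(
    holes: Sequence[Hole],
    groups: Sequence[AcquisitionGroup] = (),
    stage_transform: StageTransform | None = None,
    pixel_size_a: float | None = None,
    policy: SelectionPolicy | None = None,
) -> str:
    """Serialize holes as a SerialEM Navigator autodoc document.

    One item per hole, ordered by id: stage coordinates through the
    transform (default: scaling by the pixel size), the thickness rounded
    to 0.1 nm in the Note, Acquire = 1 for selected holes and a color
    index for the thickness class.  LF line endings, UTF-8.
    """
    if stage_transform is None:
        if pixel_size_a is None:
            raise ValueError("need stage_transform or pixel_size_a")
        stage_transform = StageTransform.from_pixel_size(pixel_size_a)
    if policy is None:
        policy = SelectionPolicy()
    del groups  # group membership is written per item via GroupID
    lines = ["AdocVersion = 2.00", ""]
    for h in sorted(holes, key=lambda h: h.id):
        x, y = stage_transform.apply(h.center_px)
        t = h.thickness_nm
        note = f"{t:.1f} nm" if t is not None and np.isfinite(t) else "nan nm"
        lines += [
            f"[Item = {h.id}]",
            f"StageXYZ = {x:.4f} {y:.4f} 0",
            f"Note = {note}",
            f"Acquire = {int(h.selected)}",
            f"Color = {_hole_color(h, policy)}",
            "Type = 0",
        ]
        if h.group_id is not None:
            lines.append(f"GroupID = {h.group_id}")
        lines.append("")
    return "\n".join(lines)


_ITEM_RE = re.compile(r"^\[Item\s*=\s*(\S+)\]\s*$")
_KEY_RE = re.compile(r"^(\w+)\s*=\s*(.*?)\s*$")


def parse_navigator(text: str) -> list[NavigatorItem]:
    """Parse a Navigator autodoc document (accepts CRLF line endings)."""
    items: list[NavigatorItem] = []
    current: dict[str, str] | None = None

    def finish(d: dict[str, str] | None) -> None:
        if not d:
            return
        xyz = d.get("StageXYZ", "0 0 0").split()
        note = d.get("Note", "nan nm").split()
        try:
            thickness = float(note[0])
        except ValueError:
            thickness = float("nan")
        items.append(
            NavigatorItem(
                id=int(d["__id__"]),
                stage_xy_um=(float(xyz[0]), float(xyz[1])),
                thickness_nm=thickness,
                acquire=d.get("Acquire", "0").strip() == "1",
                color=int(d.get("Color", "0")),
                group_id=int(d["GroupID"]) if "GroupID" in d else None,
            )
        )

    for raw in text.replace("\r\n", "\n").split("\n"):
        line = raw.strip()
        m = _ITEM_RE.match(line)
        if m:
            finish(current)
            current = {"__id__": m.group(1)}
            continue
        if current is not None:
            k = _KEY_RE.match(line)
            if k:
                current[k.group(1)] = k.group(2)
    finish(current)
    return items


def items_to_holes(items: Iterable[NavigatorItem]) -> list[Hole]:
    """Rebuild minimal holes (stage coordinates as centers) for re-selection."""
    return [
        Hole(
            id=it.id,
            center_px=(it.stage_xy_um[1], it.stage_xy_um[0]),
            thickness_nm=it.thickness_nm,
            selected=it.acquire,
            group_id=it.group_id,
            flags=frozenset(() if np.isfinite(it.thickness_nm) else ("invalid",)),
        )
        for it in items
    ]


# ---------------------------------------------------------------------------
# Quality correlation and tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QualityCorrelation:
    table: pd.DataFrame
    binned: pd.DataFrame
    spearman_rho: float
    p_value: float


def correlate_quality(
    holes: Sequence[Hole],
    quality_table: pd.DataFrame,
    bin_width_nm: float = 10.0,
) -> QualityCorrelation:
    """Join per-hole thickness with a quality table and correlate.

    ``quality_table`` must carry columns ``id`` and ``ctf_resolution_a``
    keyed by hole id.  Returns the joined table, mean CTF resolution per
    thickness bin (default 10 nm bins) and the Spearman rank correlation
    — thicker ice degrading the CTF fit shows up as rho > 0.
    """
    for col in ("id", "ctf_resolution_a"):
        if col not in quality_table.columns:
            raise IcemapError(f"quality table is missing column {col!r}")
    hdf = pd.DataFrame(
        {
            "id": [h.id for h in holes],
            "thickness_nm": [
                h.thickness_nm if h.thickness_nm is not None else np.nan
                for h in holes
            ],
        }
    ).dropna()
    joined = hdf.merge(quality_table, on="id", how="inner")
    if joined.empty:
        raise IcemapError("no quality rows match any measured hole id")
    joined = joined.sort_values("id").reset_index(drop=True)
    bins = np.floor(joined["thickness_nm"] / bin_width_nm) * bin_width_nm
    binned = (
        joined.assign(bin_nm=bins)
        .groupby("bin_nm")["ctf_resolution_a"]
        .agg(["mean", "count"])
        .reset_index()
    )
    rho, p = stats.spearmanr(joined["thickness_nm"], joined["ctf_resolution_a"])
    return QualityCorrelation(
        table=joined, binned=binned, spearman_rho=float(rho), p_value=float(p)
    )


_HOLE_COLUMNS = [
    "id",
    "row_px",
    "col_px",
    "mean_I",
    "mean_Izl",
    "thickness_nm",
    "selected",
    "group_id",
    "flags",
]


def holes_to_dataframe(holes: Sequence[Hole]) -> pd.DataFrame:
    rows = [
        (
            h.id,
            h.center_px[0],
            h.center_px[1],
            h.mean_unfiltered,
            h.mean_filtered,
            h.thickness_nm if h.thickness_nm is not None else np.nan,
            int(h.selected),
            h.group_id if h.group_id is not None else -1,
            ";".join(sorted(h.flags)),
        )
        for h in holes
    ]
    return pd.DataFrame(rows, columns=_HOLE_COLUMNS)


def dataframe_to_holes(df: pd.DataFrame) -> list[Hole]:
    out = []
    for r in df.itertuples():
        raw_flags = getattr(r, "flags", "")
        if pd.isna(raw_flags):
            raw_flags = ""
        flags = frozenset(f for f in str(raw_flags).split(";") if f)
        t = float(r.thickness_nm)
        out.append(
            Hole(
                id=int(r.id),
                center_px=(float(r.row_px), float(r.col_px)),
                mean_unfiltered=float(r.mean_I),
                mean_filtered=float(r.mean_Izl),
                thickness_nm=t if np.isfinite(t) else float("nan"),
                selected=bool(r.selected),
                group_id=None if int(r.group_id) < 0 else int(r.group_id),
                flags=flags,
            )
        )
    return out
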