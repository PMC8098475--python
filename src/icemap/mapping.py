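"""Per-pixel thickness mapping of a grid square.

Takes a registered unfiltered/filtered image pair, forms the per-pixel
log-attenuation ln(I / I_zl) and converts it to a thickness map with the
calibrated constants.  Because the energy shift used at low
magnification drags the filtered image sideways, the pair is first
registered by phase correlation (rigid translation only).  Invalid
pixels (non-positive counts, wrapped borders) carry NaN and are excluded
from every statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .calibration import CalibrationProfile, Method, VacuumReference
from .exceptions import AlignmentError, CalibrationError
from .image_io import ImagePair, ImagePlane

logger = logging.getLogger("icemap.mapping")

__all__ = [
    "ThicknessMap",
    "SelectionPolicy",
    "estimate_shift",
    "align_pair",
    "log_attenuation_map",
    "thickness_map",
    "thickness_map_als",
    "local_thickness",
    "classify_thickness",
    "render_heatmap",
    "write_thickness_map",
]


@dataclass
class ThicknessMap:
    """Raw (unclamped) per-pixel thickness in nm with a validity mask."""

    thickness_nm: np.ndarray
    valid: np.ndarray
    profile: CalibrationProfile
    pixel_size_a: float

    def __post_init__(self) -> None:
        if self.thickness_nm.shape != self.valid.shape:
            raise ValueError("thickness and validity mask shapes differ")

    def clamped(self) -> np.ndarray:
        """Thickness with negatives mapped to 0 (display/selection scale)."""
        return np.where(self.valid, np.maximum(self.thickness_nm, 0.0), np.nan)

    def stats(self) -> dict[str, float]:
        vals = self.thickness_nm[self.valid]
        if vals.size == 0:
            return {"n_valid": 0}
        return {
            "n_valid": int(vals.size),
            "mean_nm": float(np.mean(vals)),
            "median_nm": float(np.median(vals)),
            "std_nm": float(np.std(vals)),
        }


@dataclass(frozen=True)
class SelectionPolicy:
    """Acceptable thickness window [t_min_nm, t_max_nm], bounds inclusive.

    The default 20-40 nm window suits small membrane-protein specimens; a
    good starting point for other samples is the particle size +- 5-20 nm.
    """

    t_min_nm: float = 20.0
    t_max_nm: float = 40.0

    def __post_init__(self) -> None:
        if not 0 <= self.t_min_nm < self.t_max_nm:
            raise ValueError(
                f"need 0 <= t_min < t_max, got ({self.t_min_nm}, {self.t_max_nm})"
            )


def estimate_shift(pair: ImagePair) -> tuple[tuple[float, float], float]:
    """Translation of the filtered plane relative to the unfiltered one.

    Phase correlation with sub-pixel refinement.  Returns ((dy, dx),
    confidence); confidence is 1 - registration error, clipped to [0, 1].
    Degenerate (constant) planes yield a zero shift with confidence 0.
    """
    ref = pair.unfiltered.data
    mov = pair.filtered.data
    if np.ptp(ref[np.isfinite(ref)]) == 0 or np.ptp(mov[np.isfinite(mov)]) == 0:
        logger.warning(
            "code=DEGENERATE_SHIFT: constant image, shift undetermined; using (0, 0)"
        )
        return (0.0, 0.0), 0.0
    shift, error, _ = phase_cross_correlation(
        ref, mov, upsample_factor=50, normalization=None
    )
    # phase_cross_correlation returns the shift registering mov onto ref;
    # the offset of mov relative to ref is its negation.
    dy, dx = float(-shift[0]), float(-shift[1])
    confidence = float(np.clip(1.0 - error, 0.0, 1.0))
    return (dy, dx), confidence


def align_pair(pair: ImagePair, shift_px: tuple[float, float]) -> ImagePair:
    """Resample the filtered plane back by ``shift_px`` (bilinear).

    Border pixels that moved in from outside become NaN and stay invalid
    downstream.  Shifts of 25% of the image size or more are rejected.
    """
    ny, nx = pair.filtered.shape
    dy, dx = shift_px
    if abs(dy) >= 0.25 * ny or abs(dx) >= 0.25 * nx:
        raise AlignmentError(
            f"shift ({dy:.1f}, {dx:.1f}) px exceeds 25% of image size ({ny}, {nx})"
        )
    if dy == 0 and dx == 0:
        moved = pair.filtered.data.copy()
    else:
        moved = ndimage.shift(
            pair.filtered.data, (-dy, -dx), order=1, mode="constant", cval=np.nan
        )
    from dataclasses import replace

    return ImagePair(
        unfiltered=pair.unfiltered,
        filtered=replace(pair.filtered, data=moved),
        shift_px=(float(dy), float(dx)),
        aligned=True,
    )


def _require_aligned(pair: ImagePair) -> None:
    if not pair.aligned:
        raise AlignmentError(
            "pair is not aligned; run estimate_shift/align_pair first "
            "(align with shift (0, 0) if the planes are known to coincide)"
        )


def log_attenuation_map(
    pair: ImagePair, median_kernel: int = 3, apply_median: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel ln(I / I_zl) with a validity mask.

    Pixels with non-positive or non-finite counts in either plane are
    invalid (NaN).  A median filter (default 3x3) is applied to the
    ratio image before the log to suppress counting noise; invalid
    pixels are excluded from the filter by temporary in-fill and remain
    invalid afterwards.
    """
    _require_aligned(pair)
    unf = pair.unfiltered.data
    fil = pair.filtered.data
    with np.errstate(invalid="ignore", divide="ignore"):
        valid = (
            np.isfinite(unf) & np.isfinite(fil) & (unf > 0) & (fil > 0)
        )
        ratio = np.where(valid, unf / np.where(valid, fil, 1.0), np.nan)
    if apply_median and median_kernel > 1:
        if not valid.all():
            fill = float(np.nanmedian(ratio)) if valid.any() else 1.0
            filtered = ndimage.median_filter(
                np.where(valid, ratio, fill), size=median_kernel, mode="reflect"
            )
        else:
            filtered = ndimage.median_filter(ratio, size=median_kernel, mode="reflect")
        ratio = np.where(valid, filtered, np.nan)
    with np.errstate(invalid="ignore"):
        lnr = np.log(ratio)
    return lnr, valid


def thickness_map(
    pair: ImagePair,
    profile: CalibrationProfile,
    median_kernel: int = 3,
    apply_median: bool = True,
) -> ThicknessMap:
    """Per-pixel zero-loss thickness map D = scale * ln(I/I_zl) - C."""
    if profile.method != Method.FILTER:
        raise CalibrationError(
            "thickness_map requires a FILTER profile; use thickness_map_als"
        )
    lnr, valid = log_attenuation_map(pair, median_kernel, apply_median)
    d = profile.scale_nm * lnr - profile.correction_nm
    return ThicknessMap(
        thickness_nm=d,
        valid=valid,
        profile=profile,
        pixel_size_a=pair.unfiltered.pixel_size_a,
    )


def thickness_map_als(
    plane: ImagePlane,
    reference: VacuumReference,
    profile: CalibrationProfile,
    median_kernel: int = 3,
    apply_median: bool = True,
) -> ThicknessMap:
    """Aperture-limited thickness map D = scale * ln(I_0 / I) from one image."""
    if profile.method != Method.ALS:
        raise CalibrationError(
            "thickness_map_als requires an ALS profile; use thickness_map"
        )
    data = plane.data
    valid = np.isfinite(data) & (data > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(valid, reference.intensity / np.where(valid, data, 1.0), np.nan)
    if apply_median and median_kernel > 1:
        fill = float(np.nanmedian(ratio)) if valid.any() else 1.0
        ratio = np.where(
            valid,
            ndimage.median_filter(
                np.where(valid, ratio, fill), size=median_kernel, mode="reflect"
            ),
            np.nan,
        )
    with np.errstate(invalid="ignore"):
        d = profile.scale_nm * np.log(ratio)
    return ThicknessMap(
        thickness_nm=d, valid=valid, profile=profile, pixel_size_a=plane.pixel_size_a
    )


def local_thickness(
    pair: ImagePair,
    point: tuple[int, int],
    box_px: int,
    profile: CalibrationProfile,
) -> float:
    """Point measurement: mean ratio over a square box, then the formula.

    Mirrors the cursor tool of the survey script: the ratio image is
    averaged within a box around the point and the thickness formula is
    applied to that averaged ratio (ratio-averaged; the per-hole routine
    in hole targeting instead uses a ratio of mean intensities).  The box
    is clipped at the image borders.
    """
    if box_px < 1 or box_px % 2 == 0:
        raise ValueError(f"box_px must be odd and >= 1, got {box_px}")
    _require_aligned(pair)
    ny, nx = pair.unfiltered.shape
    r, c = point
    if not (0 <= r < ny and 0 <= c < nx):
        raise ValueError(f"point {point} outside image of shape {(ny, nx)}")
    h = box_px // 2
    sl = (slice(max(0, r - h), min(ny, r + h + 1)), slice(max(0, c - h), min(nx, c + h + 1)))
    unf = pair.unfiltered.data[sl]
    fil = pair.filtered.data[sl]
    ok = np.isfinite(unf) & np.isfinite(fil) & (unf > 0) & (fil > 0)
    if not ok.any():
        return float("nan")
    mean_ratio = float(np.mean(unf[ok] / fil[ok]))
    d = profile.scale_nm * np.log(mean_ratio) - profile.correction_nm
    return float(d)


# Classification codes
BELOW, WITHIN, ABOVE, INVALID = 0, 1, 2, -1


def classify_thickness(tmap: ThicknessMap, policy: SelectionPolicy) -> np.ndarray:
    """Partition pixels into below / within / above the window.

    Uses the clamped thickness (negatives count as 0, i.e. below any
    positive lower bound); invalid pixels get code -1.  The partition is
    palette-independent: both heatmap palettes color the same classes.
    """
    d = tmap.clamped()
    out = np.full(d.shape, INVALID, dtype=np.int8)
    ok = tmap.valid
    out[ok & (d < policy.t_min_nm)] = BELOW
    out[ok & (d >= policy.t_min_nm) & (d <= policy.t_max_nm)] = WITHIN
    out[ok & (d > policy.t_max_nm)] = ABOVE
    return out


_DM_COLORS = {BELOW: (255, 0, 0), WITHIN: (0, 255, 0)}  # ABOVE uncolored
_SERIALEM_COLORS = {
    BELOW: (255, 0, 255),  # magenta: too thin
    WITHIN: (0, 255, 0),
    ABOVE: (0, 0, 255),  # blue: too thick
}


def render_heatmap(
    tmap: ThicknessMap,
    policy: SelectionPolicy,
    palette: str = "DM",
    base: np.ndarray | None = None,
    alpha: float = 0.5,
) -> np.ndarray:
    """RGB heatmap of the thickness classes over a grayscale base image.

    ``DM`` palette: too thin red, within window green, too thick left
    uncolored (base image shows through).  ``SERIALEM`` palette: too thin
    magenta, within green, too thick blue.  Invalid pixels are always
    uncolored.  Colored pixels are alpha-blended onto the base.
    """
    palette = palette.upper()
    if palette not in ("DM", "SERIALEM"):
        raise ValueError(f"unknown palette {palette!r}")
    classes = classify_thickness(tmap, policy)
    if base is None:
        gray = np.full(classes.shape, 128.0)
    else:
        lo, hi = np.nanpercentile(base, [1, 99])
        gray = np.clip((base - lo) / max(hi - lo, 1e-12), 0, 1) * 255.0
    rgb = np.repeat(gray[:, :, None], 3, axis=2)
    colors = _DM_COLORS if palette == "DM" else _SERIALEM_COLORS
    for code, color in colors.items():
        mask = classes == code
        rgb[mask] = (1 - alpha) * rgb[mask] + alpha * np.array(color, dtype=float)
    return np.clip(rgb, 0, 255).astype(np.uint8)


def write_thickness_map(
    tmap: ThicknessMap, path: str | Path, policy: SelectionPolicy | None = None
) -> None:
    """Write the map as float MRC plus a text sidecar with the profile used."""
    from .image_io import ImagePlane, write_image

    plane = ImagePlane(
        data=np.where(tmap.valid, tmap.thickness_nm, np.nan),
        pixel_size_a=tmap.pixel_size_a,
        exposure_s=1.0,
        label="thickness_nm",
    )
    write_image(plane, path)
    stats = tmap.stats()
    lines = [
        f"profile = {tmap.profile.voltage_kv}/{tmap.profile.regime.value}/"
        f"{tmap.profile.method.value}",
        f"scale_nm = {tmap.profile.scale_nm}",
        f"correction_nm = {tmap.profile.correction_nm}",
    ]
    if policy is not None:
        lines.append(f"policy_nm = {policy.t_min_nm} {policy.t_max_nm}")
    lines += [f"{k} = {v}" for k, v in stats.items()]
    Path(str(path) + ".txt").write_text("\n".join(lines) + "\n")
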