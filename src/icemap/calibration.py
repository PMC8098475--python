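"""Thickness formulas, calibration-constant registry and fitting.

Ice thickness is estimated from electron attenuation.  With a zero-loss
energy filter the thickness is

    D = lambda_inel * ln(I / I_zl) - C

where ``I`` and ``I_zl`` are the mean intensities without and with the
slit inserted, ``lambda_inel`` is the apparent inelastic mean free path
and ``C`` is an offset that zeroes the reading over vacuum in an empty
hole.  Without a filter, aperture-limited scattering (ALS) against a
vacuum reference intensity ``I_0`` gives

    D = lambda_ALS * ln(I_0 / I).

The scaling constants are apparent, instrument-specific quantities; the
registry below carries the calibrated values for 200 kV and 300 kV
instruments in the low-magnification (LM) and medium/selected-area
(M_SA) regimes, and the fitting routines re-estimate them from tables of
log-attenuation versus independently measured thickness.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    CalibrationError,
    InsufficientDataError,
    InvalidMeasurementError,
    PairingError,
)

logger = logging.getLogger("icemap.calibration")

__all__ = [
    "Regime",
    "Method",
    "CameraModel",
    "CalibrationProfile",
    "VacuumReference",
    "CameraProfile",
    "CalibrationSample",
    "LambdaFit",
    "default_profile",
    "default_camera",
    "thickness_filter",
    "thickness_als",
    "fit_correction_term",
    "fit_lambda_filter",
    "transfer_lambda_cross_regime",
    "fit_lambda_als",
    "counts_from_flux",
    "check_count_rate",
    "read_calibration_csv",
    "write_calibration_csv",
    "save_profiles",
    "load_profiles",
]


class Regime(str, Enum):
    """Magnification regime: low magnification vs medium/selected-area."""

    LM = "LM"
    M_SA = "M_SA"


class Method(str, Enum):
    """Thickness-estimation method: zero-loss filter or aperture-limited."""

    FILTER = "FILTER"
    ALS = "ALS"


class CameraModel(str, Enum):
    K2 = "K2"
    K3 = "K3"
    GENERIC = "GENERIC"


@dataclass(frozen=True)
class CalibrationProfile:
    """Scaling constants for one (voltage, regime, method) combination.

    ``scale_nm`` is lambda_inel for the filter method and lambda_ALS for
    the ALS method; ``correction_nm`` is the vacuum zero-offset C (fixed
    at 0 for ALS, where the reference intensity itself is measured in an
    empty hole).
    """

    voltage_kv: int
    regime: Regime
    method: Method
    scale_nm: float
    correction_nm: float = 0.0
    source: str = ""

    def __post_init__(self) -> None:
        if self.scale_nm <= 0:
            raise ValueError("scale_nm must be positive")
        if self.correction_nm < 0:
            raise ValueError("correction_nm must be non-negative")
        if self.method == Method.ALS and self.correction_nm != 0:
            raise ValueError("ALS profiles have correction_nm = 0")


@dataclass(frozen=True)
class VacuumReference:
    """Mean counts per pixel over vacuum inside an empty hole (I_0)."""

    intensity: float
    settings_tag: str = ""

    def __post_init__(self) -> None:
        if self.intensity <= 0:
            raise ValueError("vacuum reference intensity must be positive")


@dataclass(frozen=True)
class CameraProfile:
    """Counting-camera conversion factor and coincidence-loss ceiling."""

    model: CameraModel
    counts_per_electron: float
    max_count_rate: float

    def __post_init__(self) -> None:
        if self.counts_per_electron <= 0:
            raise ValueError("counts_per_electron must be positive")
        if self.max_count_rate <= 0:
            raise ValueError("max_count_rate must be positive")


@dataclass(frozen=True)
class CalibrationSample:
    """One hole: measured log-attenuation and independently known thickness."""

    log_attenuation: float
    true_thickness_nm: float
    is_vacuum: bool = False

    def __post_init__(self) -> None:
        if self.true_thickness_nm < 0:
            raise ValueError("true_thickness_nm must be non-negative")
        if self.is_vacuum and self.true_thickness_nm != 0:
            raise ValueError("vacuum samples have zero true thickness")


@dataclass(frozen=True)
class LambdaFit:
    """Least-squares estimate of a scaling constant with its standard error."""

    scale_nm: float
    stderr_nm: float
    n_samples: int


# Calibrated constants: (voltage_kv, regime, method) -> (scale_nm, correction_nm).
# Filter constants are apparent inelastic mean free paths; ALS constants are
# the ALS coefficients determined by cross-method comparison at LM.
_DEFAULTS: dict[tuple[int, Regime, Method], tuple[float, float]] = {
    (200, Regime.M_SA, Method.FILTER): (305.0, 4.0),
    (200, Regime.LM, Method.FILTER): (485.0, 35.0),
    (300, Regime.M_SA, Method.FILTER): (435.0, 1.0),
    (300, Regime.LM, Method.FILTER): (805.0, 65.0),
    (200, Regime.LM, Method.ALS): (600.0, 0.0),
    (300, Regime.LM, Method.ALS): (1750.0, 0.0),
}

# K2 reports ~10.7 counts for 12.9 incident electrons per pixel per second
# in counting mode; the guard ceiling of 10 counts/px/s limits coincidence
# loss.  The K3 factor and ceiling are calibration knobs: counting on the K3
# is close to unity gain and its faster frame rate raises the usable rate.
_CAMERAS: dict[CameraModel, tuple[float, float]] = {
    CameraModel.K2: (10.7 / 12.9, 10.0),
    CameraModel.K3: (1.0, 40.0),
    CameraModel.GENERIC: (1.0, 10.0),
}


def default_profile(
    voltage_kv: int, regime: Regime | str, method: Method | str
) -> CalibrationProfile:
    """Return the registry profile for a (voltage, regime, method) key.

    Raises :class:`CalibrationError` naming the key when no calibrated
    default exists for the combination.
    """
    regime = Regime(regime)
    method = Method(method)
    key = (int(voltage_kv), regime, method)
    try:
        scale, corr = _DEFAULTS[key]
    except KeyError:
        raise CalibrationError(
            f"no default calibration for ({voltage_kv} kV, {regime.value}, "
            f"{method.value})"
        ) from None
    return CalibrationProfile(
        voltage_kv=int(voltage_kv),
        regime=regime,
        method=method,
        scale_nm=scale,
        correction_nm=corr,
        source="built-in registry",
    )


def default_camera(model: CameraModel | str) -> CameraProfile:
    """Return the built-in profile for a camera model."""
    model = CameraModel(model)
    cpe, ceiling = _CAMERAS[model]
    return CameraProfile(model=model, counts_per_electron=cpe, max_count_rate=ceiling)


def thickness_filter(
    intensity_unfiltered: float,
    intensity_filtered: float,
    profile: CalibrationProfile,
    clamp: bool = False,
) -> float:
    """Zero-loss thickness: D = scale * ln(I / I_zl) - C, in nm.

    With ``clamp`` the (physically meaningless) negative readings are
    mapped to 0; the raw value is returned otherwise so that calibration
    statistics stay unbiased.
    """
    if profile.method != Method.FILTER:
        raise CalibrationError(
            f"thickness_filter requires a FILTER profile, got {profile.method.value}"
        )
    if intensity_unfiltered <= 0 or intensity_filtered <= 0:
        raise InvalidMeasurementError(
            "intensities must be positive "
            f"(I={intensity_unfiltered}, I_zl={intensity_filtered})"
        )
    d = profile.scale_nm * math.log(intensity_unfiltered / intensity_filtered)
    d -= profile.correction_nm
    if clamp and d < 0:
        return 0.0
    return d


def thickness_als(
    intensity: float, reference: VacuumReference, profile: CalibrationProfile
) -> float:
    """ALS thickness: D = scale * ln(I_0 / I), in nm.

    A reading brighter than the vacuum reference yields a negative raw
    value, returned as-is with a warning.
    """
    if profile.method != Method.ALS:
        raise CalibrationError(
            f"thickness_als requires an ALS profile, got {profile.method.value}"
        )
    if intensity <= 0:
        raise InvalidMeasurementError(f"intensity must be positive, got {intensity}")
    d = profile.scale_nm * math.log(reference.intensity / intensity)
    if d < 0:
        logger.warning(
            "code=ALS_NEGATIVE: intensity %.3g exceeds vacuum reference %.3g "
            "(apparent thickness %.2f nm)",
            intensity,
            reference.intensity,
            d,
        )
    return d


def fit_correction_term(
    vacuum_samples: Iterable[CalibrationSample], scale_nm: float
) -> float:
    """Estimate C from empty-hole measurements: C = scale * mean(lnr).

    Empty holes read a small positive log-attenuation; C is defined so
    that their thickness comes out at zero.  A negative fit (vacuum holes
    brighter filtered than unfiltered) is floored at 0 with a warning.
    """
    lnr = [s.log_attenuation for s in vacuum_samples if s.is_vacuum]
    if not lnr:
        raise InsufficientDataError("no vacuum samples to fit the correction term")
    c = scale_nm * float(np.mean(lnr))
    if c < 0:
        logger.warning(
            "code=NEGATIVE_CORRECTION: fitted correction %.2f nm floored at 0 "
            "(check vacuum measurements)",
            c,
        )
        warnings.warn("fitted correction term was negative; floored at 0")
        c = 0.0
    return c


def _through_origin_fit(x: np.ndarray, y: np.ndarray) -> LambdaFit:
    """Least squares of y = scale * x with OLS standard error."""
    sxx = float(np.sum(x * x))
    if sxx <= 0:
        raise InsufficientDataError("zero variance in log-attenuation values")
    scale = float(np.sum(x * y) / sxx)
    n = x.size
    if n > 1:
        resid = y - scale * x
        s2 = float(np.sum(resid * resid)) / (n - 1)
        stderr = math.sqrt(s2 / sxx)
    else:
        stderr = math.nan
    return LambdaFit(scale_nm=scale, stderr_nm=stderr, n_samples=int(n))


def fit_lambda_filter(
    samples: Iterable[CalibrationSample], correction_nm: float
) -> LambdaFit:
    """Estimate lambda_inel from (log-attenuation, true thickness) pairs.

    Least squares of true_D = lambda * lnr - C with C held fixed, i.e. a
    through-origin regression of D + C on lnr.  C comes first from
    vacuum holes (:func:`fit_correction_term`); holding it fixed keeps
    the vacuum zero exact.  A single usable sample yields the one-point
    solution (D + C) / lnr with undefined standard error.
    """
    usable = [
        s
        for s in samples
        if not s.is_vacuum and math.isfinite(s.log_attenuation)
    ]
    if not usable:
        raise InsufficientDataError("no non-vacuum samples to fit lambda")
    x = np.array([s.log_attenuation for s in usable], dtype=float)
    y = np.array([s.true_thickness_nm for s in usable], dtype=float) + correction_nm
    return _through_origin_fit(x, y)


def _pair_by_id(
    a: Mapping[object, float] | Sequence[float],
    b: Mapping[object, float] | Sequence[float],
) -> tuple[np.ndarray, np.ndarray]:
    """Match two per-hole value collections by id (mappings) or position."""
    if isinstance(a, Mapping) or isinstance(b, Mapping):
        if not (isinstance(a, Mapping) and isinstance(b, Mapping)):
            raise PairingError("both inputs must be keyed by hole id, or neither")
        if set(a) != set(b):
            missing = sorted(map(str, set(a) ^ set(b)))
            raise PairingError(f"hole ids do not match: {missing}")
        keys = sorted(a, key=str)
        return (
            np.array([a[k] for k in keys], dtype=float),
            np.array([b[k] for k in keys], dtype=float),
        )
    if len(a) != len(b):
        raise PairingError(f"length mismatch: {len(a)} vs {len(b)}")
    return np.asarray(a, dtype=float), np.asarray(b, dtype=float)


def transfer_lambda_cross_regime(
    reference_thicknesses: Mapping[object, float] | Sequence[float],
    target_log_attenuations: Mapping[object, float] | Sequence[float],
    target_correction_nm: float,
) -> LambdaFit:
    """Transfer the calibration to another magnification regime.

    Thicknesses measured on the same holes under an already-calibrated
    regime serve as the reference; the target regime's lambda is fitted
    so that lambda * lnr - C_target reproduces them (least squares, C
    fixed).  Requires at least two holes, matched by id.
    """
    ref, lnr = _pair_by_id(reference_thicknesses, target_log_attenuations)
    if ref.size < 2:
        raise InsufficientDataError(
            f"cross-regime transfer needs >= 2 holes, got {ref.size}"
        )
    return _through_origin_fit(lnr, ref + target_correction_nm)


def fit_lambda_als(
    filter_thicknesses: Mapping[object, float] | Sequence[float],
    als_log_attenuations: Mapping[object, float] | Sequence[float],
) -> LambdaFit:
    """Calibrate lambda_ALS against the filter-based method.

    Through-origin regression lambda_ALS = sum(D * lnr) / sum(lnr^2)
    over matched holes, D from the filter method and lnr = ln(I_0 / I)
    from the aperture-limited measurement.
    """
    d, lnr = _pair_by_id(filter_thicknesses, als_log_attenuations)
    if d.size == 0 or not np.any(lnr > 0):
        raise InsufficientDataError(
            "ALS calibration needs at least one positive log-attenuation"
        )
    return _through_origin_fit(lnr, d)


def counts_from_flux(flux: float, camera: CameraProfile) -> float:
    """Convert electrons/px/s to camera counts/px/s."""
    if flux < 0:
        raise ValueError(f"flux must be non-negative, got {flux}")
    return flux * camera.counts_per_electron


def check_count_rate(mean_rate: float, camera: CameraProfile) -> str:
    """Coincidence-loss guard: ``"pass"`` at or below the camera ceiling.

    Returns ``"warn"`` above it and logs; never raises — the guard flags
    questionable statistics but must not block processing.
    """
    if mean_rate < 0:
        raise ValueError(f"mean_rate must be non-negative, got {mean_rate}")
    if mean_rate <= camera.max_count_rate:
        return "pass"
    logger.warning(
        "code=COUNT_RATE: mean rate %.2f counts/px/s exceeds %s ceiling of "
        "%.2f; coincidence loss may bias thickness",
        mean_rate,
        camera.model.value,
        camera.max_count_rate,
    )
    return "warn"


# ---------------------------------------------------------------------------
# Table and registry serialization
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["hole_id", "log_attenuation", "true_thickness_nm", "is_vacuum"]


def read_calibration_csv(path: str | Path) -> list[CalibrationSample]:
    """Read a calibration table (hole_id, log_attenuation, true_thickness_nm, is_vacuum)."""
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS[1:] if c not in df.columns]
    if missing:
        raise InsufficientDataError(
            f"calibration table {path} is missing columns: {missing}"
        )
    return [
        CalibrationSample(
            log_attenuation=float(r.log_attenuation),
            true_thickness_nm=float(r.true_thickness_nm),
            is_vacuum=bool(r.is_vacuum),
        )
        for r in df.itertuples()
    ]


def write_calibration_csv(
    samples: Iterable[CalibrationSample], path: str | Path
) -> None:
    rows = [
        (i, s.log_attenuation, s.true_thickness_nm, s.is_vacuum)
        for i, s in enumerate(samples)
    ]
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def save_profiles(profiles: Iterable[CalibrationProfile], path: str | Path) -> None:
    """Write a profile registry as JSON keyed by voltage/regime/method."""
    obj = {
        f"{p.voltage_kv}/{p.regime.value}/{p.method.value}": {
            "scale_nm": p.scale_nm,
            "correction_nm": p.correction_nm,
            "source": p.source,
        }
        for p in profiles
    }
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")


def load_profiles(path: str | Path) -> list[CalibrationProfile]:
    obj = json.loads(Path(path).read_text())
    out = []
    for key, val in obj.items():
        voltage, regime, method = key.split("/")
        out.append(
            CalibrationProfile(
                voltage_kv=int(voltage),
                regime=Regime(regime),
                method=Method(method),
                scale_nm=float(val["scale_nm"]),
                correction_nm=float(val.get("correction_nm", 0.0)),
                source=str(val.get("source", "")),
            )
        )
    return out
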