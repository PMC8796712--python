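"""Object morphometrics: ellipse fits, individual volumes and the scanner
detection-limit filter.

ZooScan-style processing reduces each scanned organism to the moment-equivalent
ellipse of its binary silhouette.  The prolate-spheroid volume derived from the
fitted axes is the standard size-weighted abundance proxy (biovolume) in
plankton-imaging studies, and the 300 µm equivalent-circular-diameter cutoff is
the conventional lower detection limit of the instrument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import regionprops

#: Lower and upper bounds (mm) of reliably detected organism sizes.
DETECTION_RANGE_MM = (0.3, 59.0)

#: Individual volume (mm^3) separating the "small" and "large" size classes
#: used for taxa with high size variability.
SMALL_LARGE_SPLIT_MM3 = 4.242

#: Upper bound (mm^3) of the calibrated size-class range; larger volumes are
#: accepted but flagged as out-of-calibration by :func:`size_class`.
CALIBRATED_MAX_MM3 = 90.083


@dataclass(frozen=True)
class EllipseFit:
    """Moment-equivalent ellipse of a single object's binary mask.

    Lengths are in mm (full axes, not semi-axes); ``area`` is the foreground
    pixel count scaled by the pixel area, in mm².
    """

    major_axis: float
    minor_axis: float
    area: float
    centroid: tuple[float, float]
    orientation: float

    def __post_init__(self) -> None:
        if not self.major_axis >= self.minor_axis >= 0:
            raise ValueError(
                f"axes must satisfy major >= minor >= 0, got "
                f"({self.major_axis}, {self.minor_axis})"
            )
        if not self.area > 0:
            raise ValueError("ellipse area must be positive")


def fit_ellipse_moments(mask: np.ndarray, pixel_scale: float) -> EllipseFit:
    """Fit the moment-equivalent ellipse to a binary mask.

    Parameters
    ----------
    mask
        2-D array; nonzero pixels are foreground.  Must contain at least one
        foreground pixel and at most the values {0, 1} (or booleans).
    pixel_scale
        Side length of one pixel in mm (mm/px).

    Returns
    -------
    EllipseFit
        Axes from the second-order central moments of the foreground region,
        area as foreground-pixel count × ``pixel_scale``².
    """
    if pixel_scale <= 0:
        raise ValueError("pixel_scale must be positive")
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be a 2-D array")
    uniq = np.unique(mask)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError("mask must be binary (values 0/1 or bool)")
    n_fg = int(mask.sum())
    if n_fg == 0:
        raise ValueError("mask has no foreground pixels")

    props = regionprops(mask.astype(np.uint8))[0]
    major_px = props.axis_major_length
    minor_px = props.axis_minor_length
    # Degenerate regions (single pixel, collinear pixels) have zero-length
    # moment axes; fall back to a one-pixel extent so downstream volume stays
    # finite and positive.
    major_px = max(major_px, 1.0)
    minor_px = max(minor_px, 1.0)
    cy, cx = props.centroid
    return EllipseFit(
        major_axis=major_px * pixel_scale,
        minor_axis=minor_px * pixel_scale,
        area=n_fg * pixel_scale**2,
        centroid=(cy * pixel_scale, cx * pixel_scale),
        orientation=float(props.orientation),
    )


def ellipsoid_volume(major: float, minor: float) -> float:
    """Prolate-spheroid volume (mm³) from full major/minor axes (mm).

    V = 4/3 · π · (major/2) · (minor/2)², i.e. the solid of revolution of the
    fitted ellipse about its major axis.
    """
    major = np.asarray(major, dtype=float)
    minor = np.asarray(minor, dtype=float)
    if np.any(minor <= 0) or np.any(major < minor):
        raise ValueError("require major >= minor > 0")
    out = (4.0 / 3.0) * np.pi * (major / 2.0) * (minor / 2.0) ** 2
    return float(out) if out.ndim == 0 else out


def equivalent_circular_diameter(area: float) -> float:
    """Diameter (mm) of the circle with the given area (mm²): 2·√(area/π)."""
    area = np.asarray(area, dtype=float)
    if np.any(area <= 0):
        raise ValueError("area must be positive")
    out = 2.0 * np.sqrt(area / np.pi)
    return float(out) if out.ndim == 0 else out


def apply_detection_limit(
    objects: pd.DataFrame,
    *,
    measure: str = "ecd",
    size_range_mm: tuple[float, float] = DETECTION_RANGE_MM,
) -> tuple[pd.DataFrame, int]:
    """Drop objects outside the scanner's reliable size range.

    Size is the equivalent circular diameter from ``area_mm2`` by default
    (``measure="ecd"``) or the fitted major axis (``measure="major"``).  Both
    endpoints are inclusive.  Rows whose size field is missing (e.g. members
    of multi-object vignettes, which are counted but not measured) are
    retained: they cannot be assessed and are handled by mean-substitution
    downstream.

    Returns the filtered table and the number of rows removed.
    """
    if measure == "ecd":
        if "area_mm2" not in objects.columns:
            raise KeyError("object table lacks required column 'area_mm2'")
        area = objects["area_mm2"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            size = 2.0 * np.sqrt(np.clip(area, 0.0, None) / np.pi)
    elif measure == "major":
        if "major_mm" not in objects.columns:
            raise KeyError("object table lacks required column 'major_mm'")
        size = objects["major_mm"].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown size measure {measure!r}")

    lo, hi = size_range_mm
    keep = np.isnan(size) | ((size >= lo) & (size <= hi))
    removed = int((~keep).sum())
    return objects.loc[keep].copy(), removed


def size_class(volume: float) -> str:
    """Classify an individual volume (mm³) as ``"small"`` or ``"large"``.

    Small: 0.003–4.242 mm³; large: 4.243–90.083 mm³ (both closed intervals).
    Volumes above the calibrated range are still classified as large.
    """
    if volume <= 0:
        raise ValueError("volume must be positive")
    return "small" if volume <= SMALL_LARGE_SPLIT_MM3 else "large"


def add_measurements(objects: pd.DataFrame) -> pd.DataFrame:
    """Append per-object volume (mm³) and ECD (mm) columns.

    Requires ``major_mm``/``minor_mm`` and ``area_mm2``; rows with missing
    axes get missing volumes (they are handled by mean-substitution later).
    """
    out = objects.copy()
    major = out["major_mm"].to_numpy(dtype=float)
    minor = out["minor_mm"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        vol = (4.0 / 3.0) * np.pi * (major / 2.0) * (minor / 2.0) ** 2
        area = out["area_mm2"].to_numpy(dtype=float)
        ecd = 2.0 * np.sqrt(np.clip(area, 0.0, None) / np.pi)
    out["volume_mm3"] = vol
    out["ecd_mm"] = ecd
    return out
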