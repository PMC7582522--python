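"""Immunofluorescence quantification: ROI mean grey values with
negative-control background subtraction, and nucleus areas.

The mean grey value of a nucleus ROI is the average intensity over pixels
whose centres fall inside the polygon; the mean background level measured
on negative-control material is subtracted.  Negative corrected values are
retained (and flagged by the caller if desired), not clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.path import Path as _MplPath

from .datatypes import FluorescenceImage, RoiPolygon

__all__ = [
    "IntensityMeasurement",
    "polygon_pixel_mask",
    "mean_grey_value",
    "background_correct",
    "roi_area",
    "measure_roi",
]


@dataclass
class IntensityMeasurement:
    raw_mean: float
    background_mean: float
    corrected_mean: float
    roi_area_mm2: float
    below_background: bool


def polygon_pixel_mask(image: FluorescenceImage, roi: RoiPolygon) -> np.ndarray:
    """Boolean mask of pixels whose centres lie inside the polygon."""
    xx, yy = image.pixel_centers_um()
    path = _MplPath(roi.vertices)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    return path.contains_points(pts).reshape(image.shape)


def mean_grey_value(image: FluorescenceImage, roi: RoiPolygon) -> float:
    """Mean intensity over pixel centres inside the ROI polygon.

    Raises if no pixel centre falls inside the polygon (e.g. an ROI
    outside the image).
    """
    mask = polygon_pixel_mask(image, roi)
    if not mask.any():
        raise ValueError(f"ROI {roi.label!r} encloses no pixel centres")
    return float(image.intensities[mask].mean())


def background_correct(raw: float, negative_control_mean: float) -> float:
    """Subtract the negative-control mean; may be negative (reported as-is)."""
    if not (np.isfinite(raw) and np.isfinite(negative_control_mean)):
        raise ValueError("grey values must be finite")
    return float(raw - negative_control_mean)


def roi_area(roi: RoiPolygon, calibration_um_per_px: float | None = None) -> float:
    """Polygon (shoelace) area in mm².

    If vertices are in pixel units, pass the µm/pixel calibration.
    """
    area_um2 = roi.area_um2
    if calibration_um_per_px is not None:
        if calibration_um_per_px <= 0:
            raise ValueError("calibration must be positive")
        area_um2 *= calibration_um_per_px**2
    return area_um2 / 1e6


def measure_roi(
    image: FluorescenceImage, roi: RoiPolygon, negative_control_mean: float
) -> IntensityMeasurement:
    """Raw and background-corrected mean grey value plus ROI area."""
    raw = mean_grey_value(image, roi)
    corrected = background_correct(raw, negative_control_mean)
    return IntensityMeasurement(
        raw_mean=raw,
        background_mean=float(negative_control_mean),
        corrected_mean=corrected,
        roi_area_mm2=roi_area(roi),
        below_background=corrected < 0,
    )
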