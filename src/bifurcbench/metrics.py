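"""Scalar hemodynamic endpoints reduced from the shear-rate field.

Two endpoints mirror the bench study: the area of the flow domain above a
shear-rate threshold (default 1000 1/s, the upper edge of the normal arterial
range of 100-1000 1/s) and the maximum shear rate.  Both are evaluated over a
region of interest; the default ROI is a disc centred on the side-branch
ostium with radius one SB diameter (the integration region of the reference
analysis is unstated, so the whole-domain variant is reported alongside).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Point

from .flow import ShearField
from .geometry import BifurcationGeometry2D

__all__ = ["ShearMetrics", "compute_shear_metrics", "ostium_roi"]


@dataclass(frozen=True)
class ShearMetrics:
    A_high: float  # mm^2 with shear rate > threshold inside the ROI
    shear_max: float  # 1/s over the ROI
    threshold: float  # 1/s
    roi_area: float  # mm^2 of fluid inside the ROI


def ostium_roi(geom: BifurcationGeometry2D, radius: float | None = None):
    """Disc ROI centred on the SB ostium, reaching one SB diameter by default."""
    if geom.ostium_segment is None:
        raise ValueError("geometry has no ostium")
    if radius is None:
        radius = geom.params.D_sb if geom.params is not None else float(
            np.linalg.norm(geom.ostium_segment[1] - geom.ostium_segment[0])
        )
    center = geom.ostium_segment.mean(axis=0)
    return Point(center).buffer(radius)


def compute_shear_metrics(
    shear: ShearField,
    threshold: float = 1000.0,
    roi=None,
) -> ShearMetrics:
    """Threshold the element shear field over a region of interest.

    Elements belong to the ROI by centroid membership; ``roi=None`` uses the
    whole domain.  ``A_high > 0`` implies ``shear_max > threshold`` by
    construction.
    """
    gamma = shear.shear_rate
    areas = shear.element_areas_mm2
    if roi is None:
        mask = np.ones(len(gamma), dtype=bool)
    else:
        c = shear.centroids_mm
        mask = shapely.contains_xy(roi, c[:, 0], c[:, 1])
        if not mask.any():
            raise ValueError("ROI contains no elements")
    g = gamma[mask]
    a = areas[mask]
    return ShearMetrics(
        A_high=float(a[g > threshold].sum()),
        shear_max=float(g.max()),
        threshold=float(threshold),
        roi_area=float(a.sum()),
    )
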