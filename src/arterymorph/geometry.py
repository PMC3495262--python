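"""Radii and wall/layer thicknesses from lumen and wall masks.

Two independent routes are computed and cross-checked:

* **ring route** — the whole arterial ring is reduced to equivalent-circle
  radii: r = √(A/π) from the lumen area and from the lumen+wall area, with
  mean thickness r_out − r_in.  Perimeter-based radii (r = P/2π) and the
  hydraulic diameter D_h = 4A/P are reported alongside so that departures
  from circularity are visible rather than hidden.
* **strip route** — on a transmural strip of width m pixels, the mean
  thickness is t̄ = Σᵢ nᵢ / m where nᵢ is the wall thickness in column i;
  this is identically the wall area divided by the image width.

Layer thicknesses use the strip route for media and adventitia; the intima
follows by subtraction from the total, so the three always sum to the total
exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from skimage.measure import perimeter_crofton

from .errors import DegenerateInputError, InconsistencyError
from .masks import LayerMasks

__all__ = [
    "GeometrySummary",
    "equivalent_radius_from_area",
    "radius_from_perimeter",
    "hydraulic_diameter",
    "ring_geometry",
    "transmural_mean_thickness",
    "layer_thicknesses",
]


@dataclass
class GeometrySummary:
    """Geometry of one arterial ring, in micrometres.

    ``inner_radius_um`` / ``outer_radius_um`` are area-equivalent radii
    (primary route); perimeter-based radii and the luminal hydraulic
    diameter are carried for sensitivity checks.
    """

    inner_radius_um: float
    outer_radius_um: float
    mean_thickness_ring_um: float
    mean_thickness_strip_um: float
    lumen_area_um2: float
    wall_area_um2: float
    luminal_perimeter_um: float
    outer_perimeter_um: float
    hydraulic_diameter_um: float
    inner_radius_perimeter_um: float
    outer_radius_perimeter_um: float
    layer_thickness_um: tuple[float, float, float] | None = None


def equivalent_radius_from_area(area: float) -> float:
    """Radius of the circle with the given area: r = √(A/π)."""
    if area < 0:
        raise ValueError("area must be non-negative")
    return math.sqrt(area / math.pi)


def radius_from_perimeter(perimeter: float) -> float:
    """Radius of the circle with the given circumference: r = P/(2π)."""
    if perimeter < 0:
        raise ValueError("perimeter must be non-negative")
    return perimeter / (2.0 * math.pi)


def hydraulic_diameter(area: float, perimeter: float) -> float:
    """D_h = 4A/P; equals the geometric diameter for a circle."""
    if perimeter <= 0:
        raise ValueError("perimeter must be positive")
    return 4.0 * area / perimeter


def _perimeter_px(mask: np.ndarray) -> float:
    # Crofton estimator with 4 directions: low bias on smooth convex shapes
    return float(perimeter_crofton(mask, directions=4))


def ring_geometry(
    lumen: np.ndarray, wall: np.ndarray, pixel_scale_um_per_px: float
) -> GeometrySummary:
    """Whole-ring geometry from lumen and wall masks.

    The strip-analogue thickness reported here divides the wall area by the
    mid-wall circumference (mean of luminal and outer perimeters); for a
    perfect annulus it equals r_out − r_in analytically.
    """
    if pixel_scale_um_per_px <= 0:
        raise ValueError("pixel scale must be positive")
    if not wall.any():
        raise DegenerateInputError("wall mask is empty")
    s = pixel_scale_um_per_px
    lumen_area = float(lumen.sum()) * s**2
    wall_area = float(wall.sum()) * s**2
    outer_region = lumen | wall
    p_lumen = _perimeter_px(lumen) * s
    p_outer = _perimeter_px(outer_region) * s
    r_in = equivalent_radius_from_area(lumen_area)
    r_out = equivalent_radius_from_area(lumen_area + wall_area)
    mean_perimeter = 0.5 * (p_lumen + p_outer)
    strip_thickness = wall_area / mean_perimeter if mean_perimeter > 0 else float("nan")
    return GeometrySummary(
        inner_radius_um=r_in,
        outer_radius_um=r_out,
        mean_thickness_ring_um=r_out - r_in,
        mean_thickness_strip_um=strip_thickness,
        lumen_area_um2=lumen_area,
        wall_area_um2=wall_area,
        luminal_perimeter_um=p_lumen,
        outer_perimeter_um=p_outer,
        hydraulic_diameter_um=hydraulic_diameter(lumen_area, p_lumen)
        if p_lumen > 0
        else float("nan"),
        inner_radius_perimeter_um=radius_from_perimeter(p_lumen),
        outer_radius_perimeter_um=radius_from_perimeter(p_outer),
    )


def transmural_mean_thickness(
    strip_mask: np.ndarray, pixel_scale_um_per_px: float = 1.0
) -> float:
    """Mean thickness of a transmural strip: t̄ = Σᵢ nᵢ / m = area / width.

    ``nᵢ`` is the number of wall pixels in image column i and m the image
    width in pixels.  The column-sum and area/width formulations are the
    same integer sum, so they agree to machine precision by construction.
    """
    strip_mask = np.asarray(strip_mask, dtype=bool)
    if strip_mask.ndim != 2 or strip_mask.shape[1] == 0:
        raise ValueError("strip mask must be 2-D with positive width")
    if not strip_mask.any():
        raise DegenerateInputError("strip mask is empty")
    m = strip_mask.shape[1]
    column_thickness = strip_mask.sum(axis=0)  # nᵢ
    total = int(column_thickness.sum())
    assert total == int(strip_mask.sum())  # area/width identity
    return total / m * pixel_scale_um_per_px


def layer_thicknesses(
    masks: LayerMasks,
    pixel_scale_um_per_px: float = 1.0,
    tolerance_um: float | None = None,
) -> tuple[float, float, float]:
    """(intima, media, adventitia) thicknesses of a transmural strip.

    Media and adventitia come from :func:`transmural_mean_thickness` on
    their masks; the intima is total − media − adventitia, clipped at zero
    (with a warning) when the independent measurements overshoot slightly.
    An overshoot beyond ``tolerance_um`` (default one pixel) raises.
    """
    s = pixel_scale_um_per_px
    if tolerance_um is None:
        tolerance_um = s
    total = transmural_mean_thickness(masks.wall, s)
    media = (
        transmural_mean_thickness(masks.media, s) if masks.media.any() else 0.0
    )
    adventitia = (
        transmural_mean_thickness(masks.adventitia, s)
        if masks.adventitia.any()
        else 0.0
    )
    intima = total - media - adventitia
    if intima < -tolerance_um:
        raise InconsistencyError(
            f"media + adventitia exceed total thickness by {-intima:.3g} um"
        )
    if intima < 0:
        warnings.warn(
            "intima thickness slightly negative; clipped to 0", stacklevel=2
        )
        intima = 0.0
    return (intima, media, adventitia)
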