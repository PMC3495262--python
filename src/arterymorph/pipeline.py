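"""End-to-end measurement of phantom image sets.

Chains the stages the way a user would on real sections: detect the lumen
on the VVG brightfield by flood fill, recover the wall by excluding the
white perivascular fill, take layer annotations from the supplied masks
(the documented manual hand-off), and reduce everything to ring geometry
plus area-equivalent layer thicknesses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import equivalent_radius_from_area, ring_geometry
from .masks import ArteryImageSet, LayerMasks, detect_lumen
from .synthgen import VVG_OUTSIDE

__all__ = ["measure_phantom_geometry", "measure_cohort_geometry"]

# wall pixels render well below the white perivascular fill; 227 splits the
# two intensity modes (200 vs 255) at >3 noise standard deviations each
WALL_CEILING = 227


def measure_phantom_geometry(
    images: ArteryImageSet,
    annotations: LayerMasks,
    lumen_tolerance: float = 25.0,
) -> dict[str, float]:
    """Measure one phantom from its images, using annotated layer borders.

    The lumen is detected from the VVG channel (seeded at the frame
    centre); the wall is everything darker than the perivascular fill and
    outside the lumen.  Media and adventitia extents come from
    ``annotations`` intersected with the measured wall.  Layer thicknesses
    are differences of area-equivalent radii of the nested regions.
    """
    vvg = images.channels["vvg"]
    seed = (vvg.shape[0] // 2, vvg.shape[1] // 2)
    lumen = detect_lumen(vvg, seed, tolerance=lumen_tolerance)
    wall = (vvg.astype(np.int16) <= WALL_CEILING) & ~lumen
    media = annotations.media & wall
    adventitia = annotations.adventitia & wall
    s = images.pixel_scale_um_per_px

    summary = ring_geometry(lumen, wall, s)
    # nested-region radii: lumen ⊂ +intima ⊂ +media ⊂ +adventitia
    intima = wall & ~media & ~adventitia
    a_lumen = lumen.sum() * s**2
    a_int = a_lumen + intima.sum() * s**2
    a_med = a_int + media.sum() * s**2
    a_adv = a_med + adventitia.sum() * s**2
    r = [equivalent_radius_from_area(a) for a in (a_lumen, a_int, a_med, a_adv)]
    return {
        "inner_radius_um": summary.inner_radius_um,
        "outer_radius_um": summary.outer_radius_um,
        "thickness_um": summary.mean_thickness_ring_um,
        "intima_um": r[1] - r[0],
        "media_um": r[2] - r[1],
        "adventitia_um": r[3] - r[2],
    }


def measure_cohort_geometry(phantoms: dict) -> pd.DataFrame:
    """Run :func:`measure_phantom_geometry` over a generated cohort.

    ``phantoms`` maps (condition, week, animal) to (images, masks, truth)
    as returned by :func:`arterymorph.synthgen.make_cohort`.
    """
    rows = []
    for (condition, week, animal), (images, masks, _truth) in sorted(
        phantoms.items()
    ):
        rec = measure_phantom_geometry(images, masks)
        rec.update(condition=condition, week=week, animal=animal)
        rows.append(rec)
    return pd.DataFrame(rows)
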