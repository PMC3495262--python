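"""Synthetic artery phantoms with exact ground truth.

No imaging data accompany the measurements this pipeline reproduces, so
every stage is validated against phantoms: rasterized annular vessels whose
geometry, stain content and nuclei placement are known exactly at paint
time.  Three wall architectures are emulated — elastic arteries with many
concentric elastic lamellae (aorta-like), muscular arteries with two
lamellae (coronary-like) and muscular arteries with a single lamella
(cerebral-like) — together with negative controls, picrosirius-red
brightfield/polarized pairs, transmural wall strips, pressure-myography
dose–response tables and whole study cohorts.

Rendering model
---------------
Phantoms are 8-bit rasters at a configurable scale (default 1 μm/px).  An
eccentricity parameter ``e`` stretches every layer boundary into an ellipse
with semi-axes ``r(1+e)`` and ``r/(1+e)``.  The stretch preserves area, so
the analytic (area-equivalent) radius of every boundary is independent of
``e`` while perimeters grow — hydraulic and circle-formula diameters then
disagree measurably, which is exactly what the geometry stage must resolve.
Background fluorescence is Gaussian with a nonzero mean, so threshold
calibration against negative controls is nontrivial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd

from .errors import DesignError, OverlapBudgetError, SizingError
from .masks import ArteryImageSet, LayerMasks
from .vasofunction import DoseResponseRecord

__all__ = [
    "ArteryClass",
    "PhantomSpec",
    "GroundTruth",
    "StudyDesign",
    "make_artery_phantom",
    "make_negative_control",
    "make_psr_pair",
    "make_wall_strip",
    "make_dose_response",
    "make_cohort",
    "simulate_measurement_cohort",
    "PRESETS",
]

# Intensity model (8-bit). Background has a nonzero mean so that negative
# control calibration has something real to subtract.
BG_MEAN = 40.0
SIGNAL_MEAN = 180.0
VVG_LUMEN = 10
VVG_WALL = 200
VVG_ELASTIN = 60
VVG_NUCLEUS = 45
VVG_OUTSIDE = 255
NUCLEUS_RADIUS_PX = 2

FLUOR_STAINS = ("sma", "cd34", "mac387")


class ArteryClass(str, Enum):
    ELASTIC_MANY_LAMELLAE = "elastic_many_lamellae"
    MUSCULAR_TWO_LAMELLAE = "muscular_two_lamellae"
    MUSCULAR_ONE_LAMELLA = "muscular_one_lamella"


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one artery phantom.

    ``constituent_fractions`` are target positive-area fractions of the wall
    for (elastin, sma, collagen, cd34, mac387); nuclei are placed at
    ``nuclei_density_cells_per_um2`` (counts per square micrometre of wall).
    """

    artery_class: ArteryClass = ArteryClass.ELASTIC_MANY_LAMELLAE
    inner_radius_um: float = 50.0
    layer_thicknesses_um: tuple[float, float, float] = (5.0, 30.0, 15.0)
    n_lamellae: int = 6
    constituent_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "elastin": 0.479,
            "sma": 0.258,
            "collagen": 0.128,
            "cd34": 0.02,
            "mac387": 0.02,
        }
    )
    nuclei_density_cells_per_um2: float = 0.00378
    pixel_scale_um_per_px: float = 1.0
    noise_sd: float = 8.0
    eccentricity: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.layer_thicknesses_um):
            raise ValueError("all layer thicknesses must be positive")
        if self.inner_radius_um <= 0:
            raise ValueError("inner radius must be positive")
        for name, f in self.constituent_fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction for {name!r} must lie in [0, 1]")
        if self.nuclei_density_cells_per_um2 <= 0:
            raise ValueError("nuclei density must be positive")
        if self.pixel_scale_um_per_px <= 0:
            raise ValueError("pixel scale must be positive")
        if self.eccentricity < 0:
            raise ValueError("eccentricity must be >= 0")
        if self.n_lamellae < 1:
            raise ValueError("at least one elastic lamella is required")

    @property
    def outer_radius_um(self) -> float:
        return self.inner_radius_um + sum(self.layer_thicknesses_um)


@dataclass
class GroundTruth:
    """Exact painted values of one phantom; the oracle for recovery tests."""

    inner_radius_um: float
    outer_radius_um: float
    layer_thicknesses_um: tuple[float, float, float]
    fractions: dict[str, float]
    birefringent_pixels: np.ndarray | None
    nuclei_centroids: np.ndarray
    nuclei_wall_positions: np.ndarray
    nuclei_count: int
    wall_area_um2: float

    @property
    def mean_thickness_um(self) -> float:
        return self.outer_radius_um - self.inner_radius_um


@dataclass(frozen=True)
class StudyDesign:
    """A cohort layout: per-group phantom presets plus sample sizes."""

    groups: tuple[tuple[str, int, int], ...]  # (condition, week, n_animals)
    presets: dict[tuple[str, int], PhantomSpec]
    master_seed: int = 0

    def __post_init__(self) -> None:
        keys = [(c, w) for c, w, _ in self.groups]
        if len(set(keys)) != len(keys):
            raise DesignError("duplicate (condition, week) groups in design")
        for cond, week, n in self.groups:
            if n < 1:
                raise DesignError(f"group {(cond, week)} has n_animals < 1")
            if (cond, week) not in self.presets:
                raise DesignError(f"no preset for group {(cond, week)}")


# Presets loosely parameterized after the three arterial beds the pipeline
# was built for (aorta / coronary / cerebral): wall architecture class,
# lamellae count, nuclei density and constituent fractions.
PRESETS: dict[str, PhantomSpec] = {
    "aorta": PhantomSpec(
        artery_class=ArteryClass.ELASTIC_MANY_LAMELLAE,
        inner_radius_um=60.0,
        layer_thicknesses_um=(5.0, 35.0, 15.0),
        n_lamellae=8,
        constituent_fractions={
            "elastin": 0.479,
            "sma": 0.258,
            "collagen": 0.128,
            "cd34": 0.02,
            "mac387": 0.02,
        },
        nuclei_density_cells_per_um2=0.000127,
    ),
    "coronary": PhantomSpec(
        artery_class=ArteryClass.MUSCULAR_TWO_LAMELLAE,
        inner_radius_um=50.0,
        layer_thicknesses_um=(4.0, 25.0, 12.0),
        n_lamellae=2,
        constituent_fractions={
            "elastin": 0.08,
            "sma": 0.292,
            "collagen": 0.49,
            "cd34": 0.02,
            "mac387": 0.02,
        },
        nuclei_density_cells_per_um2=0.00378,
    ),
    "cerebral": PhantomSpec(
        artery_class=ArteryClass.MUSCULAR_ONE_LAMELLA,
        inner_radius_um=45.0,
        layer_thicknesses_um=(3.0, 20.0, 10.0),
        n_lamellae=1,
        constituent_fractions={
            "elastin": 0.028,
            "sma": 0.318,
            "collagen": 0.306,
            "cd34": 0.02,
            "mac387": 0.02,
        },
        nuclei_density_cells_per_um2=0.005497,
    ),
}


def _elliptical_radius(shape: tuple[int, int], center: tuple[float, float], e: float):
    """Map each pixel centre to the level-set radius of the stretched annulus."""
    yy, xx = np.indices(shape, dtype=float)
    dy = (yy - center[0]) * (1.0 + e)
    dx = (xx - center[1]) / (1.0 + e)
    return np.hypot(dy, dx)


def _frame_geometry(spec: PhantomSpec, margin_px: int = 6):
    scale = spec.pixel_scale_um_per_px
    r_out_px = spec.outer_radius_um / scale
    half_y = r_out_px / (1.0 + spec.eccentricity) + margin_px
    half_x = r_out_px * (1.0 + spec.eccentricity) + margin_px
    shape = (int(np.ceil(2 * half_y)) + 1, int(np.ceil(2 * half_x)) + 1)
    if max(shape) > 4096:
        raise SizingError(
            f"phantom frame {shape} exceeds the 4096 px rendering bound; "
            "reduce radii or increase the pixel scale"
        )
    center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    return shape, center


def _build_masks(spec: PhantomSpec) -> tuple[LayerMasks, np.ndarray]:
    scale = spec.pixel_scale_um_per_px
    shape, center = _frame_geometry(spec)
    rr = _elliptical_radius(shape, center, spec.eccentricity)
    t_int, t_med, t_adv = (t / scale for t in spec.layer_thicknesses_um)
    r_in = spec.inner_radius_um / scale
    b1, b2, b3 = r_in + t_int, r_in + t_int + t_med, r_in + t_int + t_med + t_adv
    lumen = rr < r_in
    wall = (rr >= r_in) & (rr < b3)
    media = (rr >= b1) & (rr < b2)
    adventitia = (rr >= b2) & (rr < b3)
    return LayerMasks(lumen=lumen, wall=wall, media=media, adventitia=adventitia), rr


def _noisy(base: np.ndarray, rng: np.random.Generator, sd: float) -> np.ndarray:
    img = base.astype(float)
    if sd > 0:
        img = img + rng.normal(0.0, sd, size=base.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _exact_subset(
    rng: np.random.Generator, candidates: np.ndarray, k: int
) -> np.ndarray:
    """Flat indices of exactly ``k`` pixels drawn from a boolean mask."""
    flat = np.flatnonzero(candidates)
    if k > flat.size:
        raise SizingError("requested more positive pixels than the mask holds")
    return rng.choice(flat, size=k, replace=False)


def _paint_fraction(
    rng: np.random.Generator,
    wall: np.ndarray,
    fraction: float,
    prefer: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean mask of round(fraction * wall pixels) wall pixels.

    When ``prefer`` is given (e.g. lamellar rings for elastin), those pixels
    are used first and the remainder is sampled from the rest of the wall;
    a surplus in ``prefer`` is subsampled so the painted count is exact.
    """
    n_wall = int(wall.sum())
    k = int(round(fraction * n_wall))
    out = np.zeros(wall.shape, dtype=bool)
    if k == 0:
        return out
    if prefer is not None:
        pref = prefer & wall
        n_pref = int(pref.sum())
        if n_pref >= k:
            out.flat[_exact_subset(rng, pref, k)] = True
            return out
        out |= pref
        k -= n_pref
        remainder = wall & ~pref
    else:
        remainder = wall
    out.flat[_exact_subset(rng, remainder, k)] = True
    return out


def _lamellae_masks(
    spec: PhantomSpec, masks: LayerMasks, rr: np.ndarray
) -> list[np.ndarray]:
    """Thin high-elastin rings spaced evenly through the media."""
    scale = spec.pixel_scale_um_per_px
    t_int, t_med, _ = (t / scale for t in spec.layer_thicknesses_um)
    r0 = spec.inner_radius_um / scale + t_int
    n = spec.n_lamellae
    half_width = 0.6  # px; ~1-px rings
    rings = []
    for k in range(n):
        r_k = r0 + (k + 0.5) * t_med / n
        rings.append((np.abs(rr - r_k) <= half_width) & masks.media)
    return rings


def _angular_prefix(
    candidates: np.ndarray, theta: np.ndarray, k: int, start: float
) -> np.ndarray:
    """First ``k`` candidate pixels in angular order from ``start``."""
    flat = np.flatnonzero(candidates)
    order = np.argsort((theta.ravel()[flat] - start) % (2.0 * np.pi))
    out = np.zeros(candidates.shape, dtype=bool)
    out.flat[flat[order[:k]]] = True
    return out


def _paint_elastin(
    rng: np.random.Generator,
    spec: PhantomSpec,
    masks: LayerMasks,
    rr: np.ndarray,
    fraction: float,
    exclude: np.ndarray | None = None,
) -> np.ndarray:
    """Elastin as lamellar rings plus circumferential fiber arcs.

    Elastic tissue is fibrous, so the painted set is built from contiguous
    arcs rather than scattered pixels — scattered specks would be
    indistinguishable from nuclei during blob removal.  Whole lamellae are
    painted first; the remaining budget is filled with random thin arcs
    anywhere in the wall, the last one truncated in angular order so the
    painted count is exact.
    """
    wall = masks.wall
    target = int(round(fraction * wall.sum()))
    if exclude is not None:
        # keep fibers off the excluded set (nuclei) so blob removal can
        # tell the two apart, as it must on real sections
        from scipy import ndimage

        wall = wall & ~ndimage.binary_dilation(
            exclude, structure=np.ones((3, 3), dtype=bool)
        )
    painted = np.zeros(wall.shape, dtype=bool)
    if target == 0:
        return painted
    center = ((wall.shape[0] - 1) / 2.0, (wall.shape[1] - 1) / 2.0)
    yy, xx = np.indices(wall.shape, dtype=float)
    theta = np.arctan2(yy - center[0], xx - center[1])

    remaining = target
    for ring in _lamellae_masks(spec, masks, rr):
        new = ring & wall & ~painted
        n_new = int(new.sum())
        if n_new == 0:
            continue
        if n_new <= remaining:
            painted |= new
            remaining -= n_new
        else:
            painted |= _angular_prefix(new, theta, remaining, rng.uniform(0, 2 * np.pi))
            remaining = 0
        if remaining == 0:
            return painted

    # fiber arcs: random radius within the wall band, random span
    scale = spec.pixel_scale_um_per_px
    r_in = spec.inner_radius_um / scale
    r_out = spec.outer_radius_um / scale
    for _ in range(10_000):
        if remaining == 0:
            return painted
        r_f = rng.uniform(r_in + 1.0, r_out - 1.0)
        start = rng.uniform(0, 2 * np.pi)
        span = rng.uniform(np.pi / 16, np.pi / 3)
        arc = (
            (np.abs(rr - r_f) <= 0.6)
            & (((theta - start) % (2 * np.pi)) <= span)
            & wall
            & ~painted
        )
        n_new = int(arc.sum())
        if n_new == 0:
            continue
        if n_new <= remaining:
            painted |= arc
            remaining -= n_new
        else:
            painted |= _angular_prefix(arc, theta, remaining, start)
            remaining = 0
    # dense walls can exhaust arc placement; finish with random fill
    painted.flat[_exact_subset(rng, wall & ~painted, remaining)] = True
    return painted


def _place_nuclei(
    rng: np.random.Generator,
    wall: np.ndarray,
    count: int,
    radius: int = NUCLEUS_RADIUS_PX,
) -> np.ndarray:
    """Centres of ``count`` pairwise-disjoint disk blobs inside the wall.

    Random sequential adsorption over the eroded wall: candidate centres
    are visited in random order and accepted unless they fall within the
    minimum separation of an accepted centre (checked on a spatial hash).
    A centre gap of 2r+2 keeps any two blob pixels more than sqrt(2) apart,
    so blobs stay disjoint even under 8-connectivity.
    """
    from scipy import ndimage

    if count == 0:
        return np.empty((0, 2), dtype=float)
    # a blob fits iff its centre survives erosion by the blob footprint
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    footprint = (yy**2 + xx**2) <= radius**2
    eligible = ndimage.binary_erosion(wall, structure=footprint, border_value=0)
    coords = np.argwhere(eligible)
    if coords.shape[0] == 0:
        raise OverlapBudgetError("no wall pixel can host a nucleus blob")
    min_sep = 2 * radius + 2
    min_sep2 = min_sep**2
    cell = min_sep / np.sqrt(2.0)  # at most one accepted centre per cell
    occupied: dict[tuple[int, int], np.ndarray] = {}
    accepted: list[np.ndarray] = []
    for idx in rng.permutation(coords.shape[0]):
        c = coords[idx].astype(float)
        ci, cj = int(c[0] // cell), int(c[1] // cell)
        clash = False
        for di in range(-2, 3):
            for dj in range(-2, 3):
                other = occupied.get((ci + di, cj + dj))
                if other is not None and np.sum((other - c) ** 2) < min_sep2:
                    clash = True
                    break
            if clash:
                break
        if clash:
            continue
        occupied[(ci, cj)] = c
        accepted.append(c)
        if len(accepted) == count:
            return np.array(accepted)
    raise OverlapBudgetError(
        f"placed {len(accepted)}/{count} nuclei without overlap; "
        "density too high for disjoint blobs"
    )


def _paint_disks(
    shape: tuple[int, int], centers: np.ndarray, radius: int = NUCLEUS_RADIUS_PX
) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    offsets = np.argwhere((yy**2 + xx**2) <= radius**2) - radius
    for c in np.rint(centers).astype(int):
        pts = c + offsets
        out[pts[:, 0], pts[:, 1]] = True
    return out


def _wall_positions(masks: LayerMasks, points: np.ndarray) -> np.ndarray:
    # local import: nuclei module provides the canonical definition
    from .nuclei import WallCoordinates

    if points.shape[0] == 0:
        return np.empty(0)
    return WallCoordinates(masks).wall_position(points)


def make_artery_phantom(
    spec: PhantomSpec,
) -> tuple[ArteryImageSet, LayerMasks, GroundTruth]:
    """Render one phantom: VVG brightfield, fluorescence channels, DAPI.

    The returned :class:`GroundTruth` records painted-pixel fractions
    exactly (noise perturbs intensities, never mask membership) and the true
    nuclei centroids with their normalized wall positions.  Output is
    deterministic for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    masks, rr = _build_masks(spec)
    wall = masks.wall
    n_wall = int(wall.sum())
    scale = spec.pixel_scale_um_per_px
    wall_area_um2 = n_wall * scale**2

    fractions: dict[str, float] = {}
    channels: dict[str, np.ndarray] = {}

    # nuclei
    n_nuclei = int(round(spec.nuclei_density_cells_per_um2 * wall_area_um2))
    centers = _place_nuclei(rng, wall, n_nuclei)
    nuclei_px = _paint_disks(wall.shape, centers)
    dapi = np.full(wall.shape, BG_MEAN)
    dapi[nuclei_px] = SIGNAL_MEAN
    channels["dapi"] = _noisy(dapi, rng, spec.noise_sd)

    # VVG brightfield: dark elastin (lamellae first) and dark nuclei on a
    # bright wall, lumen black, perivascular white
    elastin_px = _paint_elastin(
        rng, spec, masks, rr,
        spec.constituent_fractions.get("elastin", 0.0), exclude=nuclei_px,
    )
    fractions["elastin"] = elastin_px.sum() / n_wall
    vvg = np.full(wall.shape, float(VVG_OUTSIDE))
    vvg[wall] = VVG_WALL
    vvg[elastin_px] = VVG_ELASTIN
    vvg[nuclei_px & wall & ~elastin_px] = VVG_NUCLEUS
    vvg[masks.lumen] = VVG_LUMEN
    channels["vvg"] = _noisy(vvg, rng, spec.noise_sd)

    # fluorescence constituents
    for stain in FLUOR_STAINS:
        painted = _paint_fraction(
            rng, wall, spec.constituent_fractions.get(stain, 0.0)
        )
        fractions[stain] = painted.sum() / n_wall
        base = np.full(wall.shape, BG_MEAN)
        base[painted] = SIGNAL_MEAN
        channels[stain] = _noisy(base, rng, spec.noise_sd)

    truth = GroundTruth(
        inner_radius_um=spec.inner_radius_um,
        outer_radius_um=spec.outer_radius_um,
        layer_thicknesses_um=spec.layer_thicknesses_um,
        fractions=fractions,
        birefringent_pixels=None,
        nuclei_centroids=centers,
        nuclei_wall_positions=_wall_positions(masks, centers),
        nuclei_count=n_nuclei,
        wall_area_um2=wall_area_um2,
    )
    images = ArteryImageSet(
        channels=channels,
        pixel_scale_um_per_px=scale,
        batch_key=("40x", spec.artery_class.value),
    )
    return images, masks, truth


def make_negative_control(spec: PhantomSpec) -> ArteryImageSet:
    """Phantom with identical geometry and noise but zero specific signal.

    Emulates primary-antibody substitution: fluorescence channels contain
    only the background intensity distribution.
    """
    rng = np.random.default_rng(spec.seed)
    masks, _ = _build_masks(spec)
    channels = {}
    for stain in FLUOR_STAINS + ("dapi",):
        base = np.full(masks.wall.shape, BG_MEAN)
        channels[stain] = _noisy(base, rng, spec.noise_sd)
    return ArteryImageSet(
        channels=channels,
        pixel_scale_um_per_px=spec.pixel_scale_um_per_px,
        batch_key=("40x", spec.artery_class.value),
    )


def make_psr_pair(
    spec: PhantomSpec,
) -> tuple[np.ndarray, np.ndarray, LayerMasks, GroundTruth]:
    """Picrosirius-red brightfield/polarized pair for collagen quantification.

    The brightfield RGB image is red-dominant exactly on the painted
    collagen pixels; the polarized grayscale image is bright (birefringent)
    on a ground-truth-recorded subset of those pixels (all of them, by
    construction) and near-black elsewhere.
    """
    rng = np.random.default_rng(spec.seed)
    masks, _ = _build_masks(spec)
    wall = masks.wall
    n_wall = int(wall.sum())
    collagen_px = _paint_fraction(
        rng, wall, spec.constituent_fractions.get("collagen", 0.0)
    )
    frac = collagen_px.sum() / n_wall

    base = np.full(wall.shape + (3,), 210.0)  # pale background
    base[masks.lumen] = 10.0
    base[wall] = (200.0, 150.0, 150.0)  # pinkish wall
    base[collagen_px] = (220.0, 60.0, 60.0)  # red collagen
    brightfield = np.stack(
        [_noisy(base[..., c], rng, spec.noise_sd) for c in range(3)], axis=-1
    )

    pol = np.full(wall.shape, 5.0)  # near-black field
    pol[collagen_px] = SIGNAL_MEAN
    polarized = _noisy(pol, rng, spec.noise_sd)

    truth = GroundTruth(
        inner_radius_um=spec.inner_radius_um,
        outer_radius_um=spec.outer_radius_um,
        layer_thicknesses_um=spec.layer_thicknesses_um,
        fractions={"collagen": frac},
        birefringent_pixels=collagen_px,
        nuclei_centroids=np.empty((0, 2)),
        nuclei_wall_positions=np.empty(0),
        nuclei_count=0,
        wall_area_um2=n_wall * spec.pixel_scale_um_per_px**2,
    )
    return brightfield, polarized, masks, truth


def make_wall_strip(
    spec: PhantomSpec, width_px: int = 200
) -> tuple[np.ndarray, LayerMasks, GroundTruth]:
    """Flat transmural strip phantom (higher-magnification view of the wall).

    The wall spans the full image width as horizontal layer bands
    (adventitia on top, intima at the bottom, lumen below), the geometry on
    which the strip thickness formula (wall area ÷ image width) is defined.
    """
    rng = np.random.default_rng(spec.seed)
    scale = spec.pixel_scale_um_per_px
    t_px = [t / scale for t in spec.layer_thicknesses_um]
    total = sum(t_px)
    height = int(np.ceil(total)) + 12
    shape = (height, width_px)
    yy = np.indices(shape, dtype=float)[0]
    # distance measured upward from the luminal border
    lumen_row = height - 6
    depth = lumen_row - yy
    t_int, t_med, t_adv = t_px
    lumen = depth <= 0
    wall = (depth > 0) & (depth <= total)
    media = (depth > t_int) & (depth <= t_int + t_med)
    adventitia = (depth > t_int + t_med) & (depth <= total)
    masks = LayerMasks(lumen=lumen, wall=wall, media=media, adventitia=adventitia)

    img = np.full(shape, float(VVG_OUTSIDE))
    img[wall] = VVG_WALL
    img[lumen] = VVG_LUMEN
    image = _noisy(img, rng, spec.noise_sd)
    truth = GroundTruth(
        inner_radius_um=spec.inner_radius_um,
        outer_radius_um=spec.outer_radius_um,
        layer_thicknesses_um=spec.layer_thicknesses_um,
        fractions={},
        birefringent_pixels=None,
        nuclei_centroids=np.empty((0, 2)),
        nuclei_wall_positions=np.empty(0),
        nuclei_count=0,
        wall_area_um2=wall.sum() * scale**2,
    )
    return image, masks, truth


DEFAULT_DOSES_LOG10M = tuple(np.linspace(-10.0, -5.0, 11))  # 0.1 nM .. 10 μM


def make_dose_response(
    n_vessels: int,
    resting_d: float,
    max_d: float,
    ec50_log10: float = -7.5,
    hill_slope: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    doses_log10_m: tuple[float, ...] = DEFAULT_DOSES_LOG10M,
    condition: str = "NT",
    treatment: str = "none",
) -> list[DoseResponseRecord]:
    """Simulate per-vessel diameter curves with a four-parameter logistic.

    Diameters rise sigmoidally from the resting (toned) diameter toward the
    maximum; the sodium-nitroprusside diameter is the maximum plus noise.
    The logistic is generator-internal ground truth — the analysis stage
    never fits it.
    """
    if not 0 < resting_d < max_d:
        raise ValueError("require 0 < resting_d < max_d")
    rng = np.random.default_rng(seed)
    doses = np.asarray(doses_log10_m, dtype=float)
    records = []
    for v in range(n_vessels):
        resting = resting_d + rng.normal(0.0, noise_sd)
        snp = max_d + rng.normal(0.0, noise_sd)
        span = max_d - resting_d
        d = resting_d + span / (1.0 + 10.0 ** (hill_slope * (ec50_log10 - doses)))
        d = d + rng.normal(0.0, noise_sd, size=doses.shape)
        records.append(
            DoseResponseRecord(
                vessel_id=f"{condition}-{treatment}-{v:02d}",
                condition=condition,
                treatment=treatment,
                resting_diameter_um=float(resting),
                max_diameter_um=float(snp),
                doses_log10_m=tuple(doses),
                diameters_um=tuple(float(x) for x in d),
            )
        )
    return records


def _child_seed(master_seed: int, index: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def make_cohort(
    design: StudyDesign,
) -> tuple[pd.DataFrame, dict[tuple[str, int, int], tuple[ArteryImageSet, LayerMasks, GroundTruth]]]:
    """Render every phantom of a study design with deterministic seeds.

    Returns a cohort table (condition, week, animal, seed and true geometry)
    plus the phantoms keyed by (condition, week, animal).
    """
    rows = []
    phantoms = {}
    index = 0
    for condition, week, n_animals in design.groups:
        preset = design.presets[(condition, week)]
        for animal in range(n_animals):
            seed = _child_seed(design.master_seed, index)
            index += 1
            spec = replace(preset, seed=seed)
            images, masks, truth = make_artery_phantom(spec)
            phantoms[(condition, week, animal)] = (images, masks, truth)
            rows.append(
                {
                    "condition": condition,
                    "week": week,
                    "animal": animal,
                    "seed": seed,
                    "true_inner_radius_um": truth.inner_radius_um,
                    "true_thickness_um": truth.mean_thickness_um,
                    "true_media_um": truth.layer_thicknesses_um[1],
                }
            )
    return pd.DataFrame(rows), phantoms


def simulate_measurement_cohort(
    group_means: dict[tuple[str, int], float],
    n_per_group: int,
    cv: float = 0.10,
    seed: int = 0,
    measure: str = "thickness_um",
) -> pd.DataFrame:
    """Per-animal scalar measurements drawn around group means.

    Lightweight companion to :func:`make_cohort` for statistical power
    studies: each animal's value is Gaussian with the group mean and a
    coefficient of variation ``cv``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for (condition, week), mean in sorted(group_means.items()):
        values = rng.normal(mean, cv * mean, size=n_per_group)
        for animal, v in enumerate(values):
            rows.append(
                {
                    "condition": condition,
                    "week": week,
                    "animal": animal,
                    measure: float(v),
                }
            )
    return pd.DataFrame(rows)
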