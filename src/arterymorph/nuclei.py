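"""Nuclei detection and transmural distribution grids.

Nuclei centroids are detected from the DAPI channel by connected-component
analysis with size, separation and intensity thresholds.  Each centroid is
then assigned a normalized wall position in [0, 1] — 0 on the luminal
border, 1 on the outer adventitial border — defined as d_L/(d_L + d_A)
where d_L and d_A are Euclidean distances to the nearest inner- and
outer-border wall pixels.  Counts are binned into a 25 (transmural) ×
25 (circumferential) grid and normalized by the largest bin count so the
densest transmural location maps to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import DegenerateInputError
from .masks import LayerMasks

__all__ = [
    "NucleiGrid",
    "WallCoordinates",
    "detect_nuclei",
    "radial_grid",
    "cell_density",
]

N_BINS = 25


@dataclass
class NucleiGrid:
    """Detected centroids with their transmural distribution.

    ``grid[n, m]`` counts nuclei in transmural bin n (0 = luminal side) and
    circumferential bin m; ``normalized_grid`` is the grid divided by its
    largest count (global mode) or by each circumferential column's largest
    count (per-column mode).  ``transmural_profile`` is the circumferential
    sum — the nuclei-versus-wall-position curve.
    """

    centroids: np.ndarray  # (n, 2) row/col
    wall_positions: np.ndarray
    circumferential_positions: np.ndarray
    grid: np.ndarray  # (N_BINS, N_BINS) counts
    normalized_grid: np.ndarray
    density_cells_per_um2: float | None = None

    @property
    def count(self) -> int:
        return int(self.grid.sum())

    @property
    def transmural_profile(self) -> np.ndarray:
        return self.grid.sum(axis=1)


class WallCoordinates:
    """Normalized wall coordinates derived from layer masks.

    The inner border is the set of wall pixels 8-adjacent to the lumen; the
    outer border is the set of wall pixels 8-adjacent to neither wall nor
    lumen.  Distances to these sets are exact (KD-tree nearest-neighbour),
    so positions agree with a brute-force search to float precision.
    """

    def __init__(self, masks: LayerMasks) -> None:
        wall = masks.wall
        lumen = masks.lumen
        if not wall.any():
            raise DegenerateInputError("wall mask is empty")
        grown_lumen = ndimage.binary_dilation(
            lumen, structure=np.ones((3, 3), dtype=bool)
        )
        outside = ~wall & ~lumen
        grown_outside = ndimage.binary_dilation(
            outside, structure=np.ones((3, 3), dtype=bool)
        )
        inner_border = wall & grown_lumen
        outer_border = wall & grown_outside
        if not inner_border.any() or not outer_border.any():
            raise DegenerateInputError("wall has no luminal or outer border")
        self._inner_tree = cKDTree(np.argwhere(inner_border))
        self._outer_tree = cKDTree(np.argwhere(outer_border))
        region = wall | lumen
        self.center = np.array(ndimage.center_of_mass(region))
        self.wall = wall

    def wall_position(self, points: np.ndarray) -> np.ndarray:
        """d_L/(d_L + d_A) for each (row, col) point; 0.5 where both are 0."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d_l, _ = self._inner_tree.query(pts)
        d_a, _ = self._outer_tree.query(pts)
        total = d_l + d_a
        out = np.full(pts.shape[0], 0.5)
        nz = total > 0
        out[nz] = d_l[nz] / total[nz]
        return out

    def circumferential_position(self, points: np.ndarray) -> np.ndarray:
        """Angle around the vessel centroid, mapped to [0, 1)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        ang = np.arctan2(pts[:, 0] - self.center[0], pts[:, 1] - self.center[1])
        return (ang + np.pi) / (2.0 * np.pi) % 1.0


def detect_nuclei(
    channel: np.ndarray,
    min_size: int = 8,
    min_separation: float = 4.0,
    min_intensity: int = 100,
) -> np.ndarray:
    """Intensity-weighted nuclei centroids as an (n, 2) row/col array.

    Connected components (8-connectivity) of pixels at or above
    ``min_intensity`` with at least ``min_size`` pixels are nuclei;
    components whose centroids lie closer than ``min_separation`` are
    merged (single link) into one, with the merged centroid the
    intensity-weighted mean over all member pixels.
    """
    if min_size < 0 or min_separation < 0 or min_intensity < 0:
        raise ValueError("thresholds must be non-negative")
    img = np.asarray(channel, dtype=float)
    mask = img >= min_intensity
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        return np.empty((0, 2))
    idx = np.arange(1, n + 1)
    areas = ndimage.sum_labels(np.ones_like(img), labels, idx)
    keep = areas >= min_size
    if not keep.any():
        return np.empty((0, 2))
    idx = idx[keep]
    weight = ndimage.sum_labels(img, labels, idx)
    yy, xx = np.indices(img.shape, dtype=float)
    wy = ndimage.sum_labels(img * yy, labels, idx) / weight
    wx = ndimage.sum_labels(img * xx, labels, idx) / weight
    centroids = np.column_stack([wy, wx])

    if min_separation > 0 and centroids.shape[0] > 1:
        # single-link merge of centroids closer than min_separation
        tree = cKDTree(centroids)
        pairs = tree.query_pairs(min_separation)
        parent = list(range(centroids.shape[0]))

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for a, b in pairs:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
        roots = np.array([find(i) for i in range(centroids.shape[0])])
        merged = []
        for r in np.unique(roots):
            members = roots == r
            w = weight[members]
            merged.append((centroids[members] * w[:, None]).sum(axis=0) / w.sum())
        centroids = np.array(merged)
    order = np.lexsort((centroids[:, 1], centroids[:, 0]))
    return centroids[order]


def radial_grid(
    centroids: np.ndarray,
    coords: WallCoordinates,
    normalize: str = "global",
) -> NucleiGrid:
    """Bin centroids into the 25×25 transmural × circumferential grid.

    Bins are half-open [k/25, (k+1)/25) with the last bin closed, so the
    positions 0 and 1 both land inside the grid.  ``normalize`` is
    ``"global"`` (divide by the largest bin count anywhere — the largest
    number of nuclei found along the transmural direction) or
    ``"per_column"`` (each circumferential column by its own maximum).
    With zero centroids normalization is skipped and the grid is all zero.
    """
    if normalize not in ("global", "per_column"):
        raise ValueError("normalize must be 'global' or 'per_column'")
    centroids = np.asarray(centroids, dtype=float).reshape(-1, 2)
    if centroids.shape[0]:
        wall_pos = coords.wall_position(centroids)
        circ_pos = coords.circumferential_position(centroids)
    else:
        wall_pos = np.empty(0)
        circ_pos = np.empty(0)
    n_idx = np.clip((wall_pos * N_BINS).astype(int), 0, N_BINS - 1)
    m_idx = np.clip((circ_pos * N_BINS).astype(int), 0, N_BINS - 1)
    grid = np.zeros((N_BINS, N_BINS), dtype=int)
    np.add.at(grid, (n_idx, m_idx), 1)

    if grid.sum() == 0:
        normalized = grid.astype(float)
    elif normalize == "global":
        normalized = grid / grid.max()
    else:
        col_max = grid.max(axis=0, keepdims=True)
        normalized = np.divide(
            grid, col_max, out=np.zeros(grid.shape, dtype=float), where=col_max > 0
        )
    return NucleiGrid(
        centroids=centroids,
        wall_positions=wall_pos,
        circumferential_positions=circ_pos,
        grid=grid,
        normalized_grid=normalized,
    )


def cell_density(count: int, wall_area_um2: float) -> float:
    """Cells per square micrometre of wall."""
    if wall_area_um2 <= 0:
        raise ValueError("wall area must be positive")
    return count / wall_area_um2
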