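"""Detect nuclei and compute their transmural distribution.

Centroids come from connected components of the DAPI channel; each is
assigned a wall position in [0, 1] (0 = lumen border, 1 = outer adventitial
border) and binned into a 25x25 transmural-by-circumferential grid
normalized by its largest count.
"""

import numpy as np

from arterymorph import (
    PhantomSpec,
    WallCoordinates,
    cell_density,
    detect_nuclei,
    make_artery_phantom,
    radial_grid,
)

spec = PhantomSpec(nuclei_density_cells_per_um2=0.005497, seed=5)
images, masks, truth = make_artery_phantom(spec)

centroids = detect_nuclei(
    images.channels["dapi"], min_size=8, min_separation=4, min_intensity=100
)
print(f"detected {len(centroids)} nuclei (placed: {truth.nuclei_count})")

grid = radial_grid(centroids, WallCoordinates(masks))
density = cell_density(grid.count, truth.wall_area_um2)
print(f"cell density {density:.6f} cells/um^2 "
      f"(preset {spec.nuclei_density_cells_per_um2})")
print(f"grid mass {grid.grid.sum()} (equals centroid count), "
      f"normalized max {grid.normalized_grid.max():.1f}")

profile = grid.transmural_profile
with np.printoptions(linewidth=120):
    print("nuclei per transmural bin (lumen -> adventitia):")
    print(profile)
# A flat profile reflects the uniform placement of this phantom; on real
# sections the inner bins are denser than the outer ones.
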