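"""Compute a probability-weighted lesion load on a toy grid.

Builds a 12-subject canonical map where a 500-voxel block is present in
every subject (probability 1), overlays a lesion covering exactly that
block, and prints the load: 500 voxels x 1.0 x 0.008 cc = 4.0 cc.
"""

import numpy as np

from lesionload import (
    LesionMask,
    ProbabilisticMap,
    compute_lesion_load,
    default_grid,
)

grid = default_grid((10, 10, 10), voxel_mm=2.0)  # 0.008 cc voxels

counts = np.zeros(grid.shape, dtype=int)
mask = np.zeros(grid.shape, dtype=np.uint8)
block = np.unravel_index(np.arange(500), grid.shape)
counts[block] = 12  # all 12 control subjects agree here
mask[block] = 1  # the lesion destroys exactly that region

pmap = ProbabilisticMap(grid, counts, n_subjects=12, label="AF")
lesion = LesionMask(grid, mask, patient_id="demo")

ll = compute_lesion_load(lesion, pmap)
print(f"lesion volume: {ll.lesion_volume_cc:.3f} cc")
print(f"lesion load against {ll.map_label}: {ll.load_cc:.3f} cc")
# The load equals the lesion volume because every lesioned voxel has
# tract probability 1; partial-probability voxels would contribute
# proportionally less.
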