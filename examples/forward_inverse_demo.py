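"""Localize a known dipole with the spherical head model and sLORETA.

Builds the 19-channel 10-20 montage, an ~1100-voxel source grid and the
three-shell lead field, forward-projects a single dipole, and checks
where the standardized inverse puts its power maximum.
"""

import numpy as np

from vertisource import (
    build_montage,
    build_source_grid,
    compute_inverse_operator,
    compute_leadfield,
    standardized_power,
)

montage = build_montage()
grid = build_source_grid()  # 11-mm spacing within the gray-matter band
leadfield = compute_leadfield(montage, grid)
inverse = compute_inverse_operator(leadfield)
print(f"grid: {grid.n_voxels} voxels at {grid.spacing:g} mm spacing")

rng = np.random.default_rng(0)
voxel = int(rng.integers(grid.n_voxels))
moment = rng.standard_normal(3)
scalp = leadfield.columns(voxel) @ moment  # noiseless forward field

power = standardized_power(inverse, scalp)
found = int(np.argmax(power))
err_mm = np.linalg.norm(grid.coords[voxel] - grid.coords[found])
print(f"true voxel {voxel} at {grid.coords[voxel]} mm")
print(f"power maximum at voxel {found}, localization error {err_mm:.1f} mm")
# 0.0 mm: sLORETA's standardization makes single noiseless sources
# localize exactly, which is why it is trusted for peak coordinates.
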