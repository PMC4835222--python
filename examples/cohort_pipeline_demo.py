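"""Full cohort analysis on a small synthetic study.

Generates a 6 vs 6 cohort with the planted effects (posterior alpha2
increase, patient gamma hypoconnectivity, FEF_L nesting correlated with
VAS intensity), runs the complete pipeline at a reduced grid, and prints
the recovered findings.
"""

import numpy as np

from vertisource import CohortSpec, PipelineConfig, generate_cohort, run_pipeline
from vertisource.synth import POSTERIOR_MIDLINE

cohort = generate_cohort(CohortSpec(n_patients=6, n_controls=6,
                                    duration=120.0, seed=11))
print(cohort.table.groupby("group")[["vas_intensity", "dhi"]].mean().round(1))

config = PipelineConfig(seed=11, grid_spacing=16.0, roi_radius=20.0,
                        min_duration=30.0, n_perm=800)
result = run_pipeline(cohort.recordings, cohort.table, config)

sm = result.group_maps["alpha2"]
near = np.linalg.norm(result.grid.coords - np.array(POSTERIOR_MIDLINE),
                      axis=1) <= 2 * result.grid.spacing
print(f"alpha2 contrast: {int(sm.significant.sum())} significant voxels, "
      f"{int((sm.significant & near).sum())} near the planted source")

pat = (cohort.table.group == "patient").to_numpy()
iu = np.triu_indices(12, 1)
gi = list(result.lps_subjects[0].band_names).index("gamma")
med = np.array([np.nanmedian(m.values[:, :, gi][iu])
                for m in result.lps_subjects])
print(f"median gamma LPS: patients {np.median(med[pat]):.4f} "
      f"vs controls {np.median(med[~pat]):.4f}")
# patients were generated with weaker gamma coupling, so their lagged
# phase synchronization should come out lower.

print(result.nesting_behavior.round(3).to_string(index=False))
# the FEF_L row should show a positive nesting-strength vs VAS-intensity
# correlation (the planted behavioral link); the other ROIs carry none.
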