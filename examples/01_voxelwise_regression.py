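"""Voxel-wise linear regression with a known embedded effect.

Builds a 200-subject synthetic cohort whose images carry a beta = 0.5
association with a scalar score inside a central sphere, fits one OLS model
per voxel, and checks that the effect is recovered where it was planted.
"""

import numpy as np

from voxelwise import EffectSpec, fit_linear, generate_cohort, parse_model

cohort = generate_cohort(
    n=200,
    grid=(24, 24, 24),
    effects=(EffectSpec(("sphere", (11.5, 11.5, 11.5), 5.0), "SCORE", 0.5),),
    seed=7,
)

spec = parse_model(
    "IMG ~ SCORE + AGE",
    roles={"IMG": "voxelwise", "SCORE": "scalar", "AGE": "scalar"},
)
result = fit_linear(spec, cohort.table, cohort.images)

inside = cohort.truth["SCORE"] > 0
beta = result.term_map("SCORE", "beta")
tmap = result.term_map("SCORE", "t")

print(f"voxels in mask: {cohort.geometry.tau}, of which {inside.sum()} in the sphere")
print(f"mean beta inside sphere:  {beta[inside].mean():.3f}   (true effect 0.5)")
print(f"mean beta outside sphere: {beta[~inside].mean():.3f}   (true effect 0)")
print(f"mean |t| inside vs outside: {np.abs(tmap[inside]).mean():.1f} "
      f"vs {np.abs(tmap[~inside]).mean():.1f}")
# The per-voxel slope estimates concentrate around the planted value inside
# the sphere and around zero elsewhere; |t| separates the two regimes.
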