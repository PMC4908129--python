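"""Imaging covariates: one image explained by another, and their interaction.

The defining capability of the toolkit: any variable in the formula may be
an image. Here metabolism-like maps (FDG) are regressed on gray-matter-like
maps (VBM) voxel by voxel, and a second model uses the *interaction* of two
images (amyloid x negated FDG) as a predictor of a scalar clinical score.
"""

import numpy as np

from voxelwise import (
    VariableOp,
    VariableSpec,
    fit_linear,
    generate_table1_cohort,
    parse_model,
)

cohort = generate_table1_cohort(n=80, grid=(24, 24, 24), seed=11)

# --- model: FDG ~ VBM + AGE + GENDER (image response, image covariate) ----
spec = parse_model(
    "FDG ~ VBM + AGE + GENDER",
    roles={"FDG": "voxelwise", "VBM": "voxelwise", "AGE": "scalar",
           "GENDER": "factor"},
)
res = fit_linear(spec, cohort.table, cohort.images)
inside = cohort.truth["VBM->FDG"] > 0
print("FDG ~ VBM: mean VBM slope inside coupled region "
      f"{res.term_map('VBM', 'beta')[inside].mean():.3f} (true 0.6), "
      f"outside {res.term_map('VBM', 'beta')[~inside].mean():.3f} (true 0)")

# --- model: CDRSOB ~ AMY + (-FDG) + AMY*(-FDG) + AGE + GENDER -------------
# the negation is a declared variable operation, applied before fitting
roles = {
    "CDRSOB": "scalar",
    "AMY": "voxelwise",
    "NFDG": VariableSpec("NFDG", "voxelwise", (VariableOp("negate"),)),
    "AGE": "scalar",
    "GENDER": "factor",
}
spec = parse_model("CDRSOB ~ AMY + NFDG + AMY*NFDG + AGE + GENDER", roles)
res = fit_linear(
    spec, cohort.table,
    {"AMY": cohort.images["AMY"], "NFDG": cohort.images["FDG"]},
)
print(f"interaction model terms: {res.term_names}")
t_int = res.term_map("AMY:NFDG", "t")
print(f"interaction |t|: median {np.median(np.abs(t_int)):.2f}, "
      f"max {np.abs(t_int).max():.2f}")
# Six coefficient maps per voxel; the AMY:NFDG map asks where the joint
# amyloid-hypometabolism burden explains the clinical score beyond the
# two main effects.
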