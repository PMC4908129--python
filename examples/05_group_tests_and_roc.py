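"""Voxel-wise group contrasts and ROC classification maps.

An unpaired t-test contrasts two groups whose images differ inside a
sphere; a voxel-wise ROC analysis then asks, voxel by voxel, how well the
image value alone separates the groups (AUC) and at which threshold
(Youden operating point).
"""

import numpy as np

from voxelwise import generate_null_cohort, unpaired_ttest, voxelwise_roc
from voxelwise.synth import sphere_indicator

cohort = generate_null_cohort(n=80, grid=(20, 20, 20), seed=41, smoothing_fwhm=2.0)
geom = cohort.geometry
vm = cohort.images["IMG"]

# plant a group difference of 0.8 inside a sphere for the second group
groups = np.array([0] * 40 + [1] * 40)
sphere = sphere_indicator((20, 20, 20), (9.5, 9.5, 9.5), 4.0)
in_sphere = sphere.ravel(order="F")[geom.voxel_index]
vm.data[40:, in_sphere] += 0.8

tt = unpaired_ttest(vm, groups)
print(f"unpaired t ({tt.term_names[0]}): "
      f"mean t inside sphere {tt.stat[in_sphere, 0].mean():.1f}, "
      f"outside {tt.stat[~in_sphere, 0].mean():.2f}")

roc = voxelwise_roc(vm, groups, positive_label=1)
print(f"mean AUC inside sphere:  {roc.auc[in_sphere].mean():.3f}")
print(f"mean AUC outside sphere: {roc.auc[~in_sphere].mean():.3f}")
j = int(np.argmax(roc.auc))
print(f"best voxel: AUC {roc.auc[j]:.2f}, Youden threshold {roc.threshold_opt[j]:.2f} "
      f"(TPR {roc.tpr_at_opt[j]:.2f}, FPR {roc.fpr_at_opt[j]:.2f})")
# The t map tests mean differences; the AUC map measures single-voxel
# discriminability, and the threshold map gives a per-region operating
# point for classifying new subjects.
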