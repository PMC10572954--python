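"""Recompute the published metrics from the reference confusion matrices.

The study's test split holds 114 Non-Tumor, 55 Necrotic-Tumor and 60
Viable-Tumor tiles. Feeding its printed confusion matrices through the
metric suite reproduces every derived figure: 95.63% accuracy and 93.09%
kappa for the CNN, 96.51% accuracy and perfect viable recall for the
three-member voting ensemble.
"""

import numpy as np

from osteovote import CLASS_NAMES, ConfusionMatrix, report_from_matrix

CNN = np.array([[108, 5, 1], [1, 54, 0], [0, 3, 57]])
ENSEMBLE = np.array([[110, 4, 0], [3, 51, 1], [0, 0, 60]])

for name, counts in (("proposed CNN", CNN), ("voting ensemble", ENSEMBLE)):
    rep = report_from_matrix(ConfusionMatrix(counts, CLASS_NAMES))
    print(f"{name}: accuracy {rep.pct(rep.accuracy)}%  kappa {rep.pct(rep.kappa)}%")
    for i, cls in enumerate(CLASS_NAMES):
        print(f"  {cls:<16} acc {rep.pct(rep.per_class_accuracy[i]):6.2f}  "
              f"precision {rep.pct(rep.per_class_precision[i], 0):>3}  "
              f"recall {rep.pct(rep.per_class_recall[i], 0):>3}  "
              f"f1 {rep.pct(rep.per_class_f1[i], 0):>3}")
    print()
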