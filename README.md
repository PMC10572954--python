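# osteovote

Histopathology image classification for osteosarcoma tissue — Non-Tumor,
Necrotic-Tumor and Viable-Tumor H&E tiles — built around two ideas: a
compact from-scratch CNN, and an **adapted majority-voting ensemble** that
resolves vote ties with class probabilities and selects its members by
exhaustive subset search.

The package is aimed at people who want to study, test or extend the
method itself: every stage is a plain Python function, the external
dataset is replaced by a tunable synthetic generator, and every published
number that is derivable from in-package inputs is recomputed, never
hard-coded into the pipeline.

## What it implements

**Dataset pipeline.** An 80/20 train/test split with the floor rule
(1144 images → 915/229), a 10% validation carve, and class balancing by
horizontal flipping: each minority class is oversampled to the majority
count with bit-exact mirror copies of sources sampled without
replacement (`balance_by_flip`), so 422/208/285 training images become
422 per class. Preprocessing resizes to the network input and divides by
255; training-time augmentation applies vertical flips, small rotations
and brightness jitter on the fly.

**CNN architecture.** `proposed_architecture()` builds the 19-layer
stack — input batch-norm, seven 3×3-conv / 2×2-max-pool pairs with
channels 32, 32, 64, 64, 128, 128, 256, flatten, dense-512 ReLU, dropout,
3-way softmax. Shapes and parameters are accounted in closed form
(conv: (f²·C_in + 1)·C_out; dense: (n_in + 1)·n_out; batch-norm: 4 per
channel): 715,311 parameters at 224×224×3, spatial chain
224 → 112 → 56 → 28 → 14 → 7 → 3 → 1. A numpy backend (`NumpyCNN`,
`train_learner`) instantiates any such spec and trains it with Adam
(lr 0.001, batch 16) on sparse categorical cross-entropy.

**Metrics.** Accuracy, per-class precision/recall/F1/class-accuracy from
the one-vs-rest decomposition, Cohen's kappa
κ = (p_o − p_e)/(1 − p_e) with p_e = Σᵢ rowᵢ·colᵢ/N², multiclass
log-loss −(1/N)Σ log p(true class), and one-vs-rest ROC-AUC via the
Mann–Whitney rank statistic with micro/macro averaging.

**Ensemble.** Each base learner votes for its argmax class; the
plurality wins. Tied vote counts are resolved by the summed predicted
probability of the tied classes across participating learners (residual
ties fall to the lowest class index). `brute_force_search` evaluates all
2^k − k − 1 member subsets of size ≥ 2 on a labeled split and ranks them.
Any probability-emitting model can join via the `BaseLearner` interface —
frozen or fine-tuned pretrained backbones included.

**Synthetic data.** Class-separable RGB images (H&E-like base color +
elliptical blobs + Gaussian noise) at the study's 536/263/345 class
composition or any other, plus fabricated per-learner probability
matrices with controlled accuracy, so the whole pipeline runs and is
tested without the external dataset.

## Worked example

```python
import numpy as np
from osteovote import ConfusionMatrix, report_from_matrix

# published test-set confusion matrix of the proposed CNN
cm = ConfusionMatrix(np.array([[108, 5, 1], [1, 54, 0], [0, 3, 57]]))
rep = report_from_matrix(cm)
print(f"accuracy {rep.pct(rep.accuracy)}%  kappa {rep.pct(rep.kappa)}%")
```

prints

```
accuracy 95.63%  kappa 93.09%
```

— of 229 test tiles, 219 sit on the diagonal (accuracy 219/229 = 95.63%),
and chance-corrected agreement with the true labels is 93.09%. The
`examples/` directory holds one short script per capability (synthetic
data, splitting/balancing, architecture accounting, CNN training, the
voting search, and the published-matrix recomputation above); each prints
its numbers with a line on what they mean. `osteovote --help` exposes the
same stages as a CLI (`synth`, `split`, `architecture`, `vote`, `search`,
`run`, `report`).

Running the ensemble demo (`examples/05_voting_ensemble.py`) with four
synthetic learners of accuracy 92/87/81/56% shows the point of the
search: the best subset (96.3%) excludes the weak learner and beats both
the strongest single model and the full ensemble (94.0%).

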