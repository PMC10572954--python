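# Methods

## Problem and scope

The package implements a three-class tissue classifier for osteosarcoma
H&E histology (Non-Tumor, Necrotic-Tumor, Viable-Tumor — always in that
order, matching the reference confusion matrices) together with the
surrounding pipeline: imbalance-aware dataset preparation, a compact CNN
with exact parameter accounting, a full multiclass metric suite, and a
heterogeneous hard-voting ensemble with probability tie-breaking and
exhaustive member selection. The reference dataset (1144 tiles of
1024×1024 at 10× magnification: 536 non-tumor, 263 necrotic, 345 viable)
is not redistributable, so the package substitutes a synthetic generator
for all testing and demonstration; the real directory-per-class tree can
be dropped in via `read_image_dataset`/`--data-root`. Pretrained
backbones (MobileNet, ResNet, Inception, NasNet, EfficientNet families)
are deliberately out of scope: anything that emits class probabilities
can join the ensemble through the `BaseLearner` interface, in `frozen` or
`fine_tuned` mode, but no backbone is reimplemented here.

## Dataset pipeline

**Splitting.** The split is a single global shuffle with
|train| = floor(frac·n); at 80/20 this reproduces 915/229 on 1144
images. The reference training counts (422/208/285 out of 536/263/345)
deviate from exact per-class 80% (429/210/276), which is only consistent
with a global, non-stratified split — so global is the default and
stratified splitting is an explicit option. Validation (default 10%,
same floor rule) is carved from the training share before balancing;
balanced counts of 422 per class account for the full 80% share, so the
carve-first ordering is the only self-consistent reading of the
reference counts.

**Balancing.** Minority classes are oversampled to the majority count by
horizontal mirroring. Flip sources are drawn uniformly without
replacement, each copy records its source id, and mirrors are bit-exact
(`pixels[:, ::-1, :]`). When a deficit exceeds the class size — which
happens in the reference composition itself: the necrotic class needs
214 copies from 208 sources — strict mode raises, and
`allow_duplicates=True` switches to minimal duplication: full
without-replacement passes over the pool, so only the unavoidable excess
(6 images there) is mirrored twice. Note that a twice-used source yields
two identical mirrors; this is inherent to flip-only oversampling past
2× and is surfaced rather than hidden.

**Preprocessing and augmentation.** Images are bilinearly resized to the
network input and divided by 255 into [0, 1]. Training-time augmentation
applies, in order: vertical flip (default probability 0.5), rotation
uniform in ±20° with reflect padding, multiplicative brightness uniform
in [0.8, 1.2] with clipping. The magnitudes are package defaults — the
reference procedure names the transforms but not their strengths — and
all three are configurable. Augmentation happens per batch inside the
training loop and is never materialized, so every epoch sees fresh
variants.

## CNN architecture and training backend

`proposed_architecture()` is the 19-layer stack: input batch-norm, seven
3×3 same-padding conv layers (channels 32, 32, 64, 64, 128, 128, 256)
each followed by 2×2 max pooling with floor division, then flatten,
dense-512 ReLU, dropout, dense-3 softmax. Parameter accounting is closed
form — conv (f²·C_in + 1)·C_out, dense (n_in + 1)·n_out, batch-norm 4·C
— giving 715,311 total at 224×224×3. Two conventions matter and are the
only ones that reproduce the published per-layer table: batch-norm
counts its two non-trainable moving statistics (4 per channel, hence 12
for RGB input), and pooling uses stride = pool size with floor division
(hence 7 → 3 → 1 at the tail). The dropout rate is not specified by the
reference architecture; it defaults to 0.5 and never affects the counts.

Because no deep-learning framework is a dependency, training is a small
NHWC numpy backend: shift-and-matmul convolutions, reshape-based max
pooling with argmax routing, standard batch-norm with momentum-0.9
moving statistics, inverted dropout, He-normal initialization from a
recorded seed, and Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-7) on sparse
categorical cross-entropy at learning rate 0.001 and batch size 16 — the
reference training settings. The backward pass is verified against
central-difference gradients in the test suite, and the backend doubles
as the brute-force oracle for parameter accounting: closed-form counts
must equal the summed sizes of actually-instantiated weight tensors.

Desk-scale training uses `small_architecture()` (same design, channels
8/16, dense 32, 32×32 input — about 34k parameters): the full 715k-
parameter stack at 224×224 is constructed and accounted exactly but
training it in numpy on one CPU is not a sensible use of anyone's time.
Tests and the acceptance script train the reduced stack on 100 synthetic
images per class at 32×32 for ~15 epochs, which converges to ≥ 0.85
validation accuracy in a few seconds.

## Metrics

All metrics derive from the K×K confusion matrix (rows = true class) or
probability rows:

- accuracy = trace/N; per-class precision, recall, F1 and one-vs-rest
  class accuracy from the (TP, TN, FP, FN) decomposition;
- Cohen's kappa (p_o − p_e)/(1 − p_e) with the marginal-product chance
  agreement p_e = Σᵢ rowᵢ·colᵢ/N². The reference text leaves "random
  accuracy" undefined; the marginal-product form is fixed here because
  it exactly reproduces the published 93.09% from the published matrix;
- multiclass log-loss, the binary cross-entropy form generalized to K
  classes (the only form compatible with single-number three-class
  log-loss values), probabilities clipped to [1e-15, 1 − 1e-15], rows
  required to sum to 1 within 1e-6;
- one-vs-rest ROC-AUC via the rank/Mann–Whitney statistic with average
  ranks (ties count 0.5); macro = unweighted mean over classes with both
  labels present, micro = AUC over the flattened one-hot/score pairs.

Zero-denominator cases return 0 with a `RuntimeWarning` instead of
raising, so a degenerate class cannot abort a batch report. Reports
carry both macro and support-weighted aggregates because published
model-comparison tables do not state which aggregation they use; both
are emitted and the ambiguity is documented rather than resolved. Two
presentation roundings (integer percent and two-decimal percent) mirror
the two table styles in circulation.

The ensemble's reference confusion matrix is not printed anywhere in
recoverable form; the matrix used in tests ([[110,4,0],[3,51,1],[0,0,60]])
is *reconstructed* from the published per-class correct counts (110/114,
51/55, 60/60) and is the unique matrix consistent with the published
class-wise precision (97/93/98) and recall (96/93/100) — all eight
derived figures check out. Its Cohen's kappa computes to 94.43%, not the
96.5% printed alongside (which equals the accuracy and is treated as a
transcription error, not a target).

## Ensemble

Voting is hard: each participating learner contributes one vote to its
argmax class (lowest index on within-learner probability ties). A strict
plurality wins outright — probabilities can never override a strict
majority. When two or more classes tie on votes, the winner is the tied
class with the greatest summed predicted probability across the
participating learners; the "sum over learners among tied classes" rule
is the most direct reading of tie resolution "by class probability", and
mean/sum are equivalent here since the learner count is fixed within a
comparison. A residual exact tie falls to the lowest class index so the
classifier is a deterministic function of its inputs.

Member selection enumerates all 2^k − k − 1 subsets of size ≥ 2 in
sorted order and scores each with the adapted vote on a labeled
evaluation split; ranking is by the chosen criterion (accuracy by
default; kappa and macro-F1 selectable) descending, ties broken by fewer
members, then higher kappa, then lexicographic ids. The evaluation split
is the caller's choice: ranking on a held-out validation split avoids
selection leakage, while passing the test split reproduces a
test-ranked search. Per-combination reports also carry probabilistic
metrics computed on the members' mean probability rows.

## Synthetic data

The generator emulates only what the pipeline needs: three classes
separable in color. Each image is a base color (eosin-pink 225/180/205,
dull purple 160/120/160, basophilic purple 110/60/140), darker
elliptical blobs at a class-specific density (2/4/8 per 10⁴ pixels,
axes up to min(H,W)/12) standing in for nuclei, and Gaussian pixel noise
(sd 18) clipped to [0, 255]. Class means sit > 3 pooled noise sd apart,
so a nearest-mean-color classifier already exceeds 90% accuracy — by
design, since the generator's job is to make learnability cheap to
verify, not to imitate histology. It deliberately does not model H&E
texture, stain variation, necrosis morphology, intra-class
heterogeneity or inter-class similarity; passing tests therefore
demonstrate the pipeline's correctness and trainability, not expected
performance on real tiles. Default test size is 96×96 (224×224
supported); generation is bit-deterministic given the seed.

Fabricated probability matrices drive the ensemble tests: per sample
the predicted class is the true label with the learner's nominal
accuracy (otherwise uniform over the rest), and the row is a Dirichlet
draw with concentration 20 on the predicted class (sharply peaked, as
trained softmax outputs are), with the maximum swapped onto the
predicted class so the argmax is exact. Rows sum to 1 within 1e-9.

## Numerical and design choices

- Rounding: floor for all split sizes; floor(x + 0.5) (half-up) for the
  scaled class-composition fixture, so scale 0.1 of (536, 263, 345)
  gives (54, 26, 35).
- Probability-row validation tolerance 1e-6; log-loss clip 1e-15;
  batch-norm ε 1e-3.
- Whether the flip sources of the reference balancing were drawn
  randomly or deterministically is not recoverable; they are drawn
  uniformly at random under a recorded seed.
- Training for 200 epochs (the reference schedule) is supported but not
  exercised; desk-scale runs use ≤ 15 epochs, which the separable
  generator makes sufficient. Whether the reference schedule used early
  stopping is unknown; none is implemented.
- The CLI is a thin wrapper over the library (`run` chains the stages;
  single-stage subcommands exist for piecemeal use); artifacts are plain
  CSV/JSON and every writer has a matching reader used by `report`,
  which re-derives its tables from stored artifacts rather than
  recomputing the pipeline.

## Known limitations

Training the full 224×224 stack is impractical in the numpy backend (no
vectorized GPU path); the synthetic generator's separability makes
near-perfect scores normal and says nothing about real-data accuracy;
ensemble selection on the evaluation split it is scored on is
optimistically biased (offered because it mirrors the reference
procedure, with a validation split recommended instead); and the
reconstructed ensemble confusion matrix, while uniquely consistent with
all published per-class figures, remains a reconstruction.
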