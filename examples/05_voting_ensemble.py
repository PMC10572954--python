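"""Adapted majority voting and the exhaustive combination search.

Fabricates four base learners of different accuracies, votes them, and
searches every combination of two or more members. The printed table
shows why the search matters: the best subset usually excludes the weak
learners, and vote ties are resolved by accumulated class probability.
"""

import numpy as np

from osteovote import adapted_majority_vote, brute_force_search, generate_prediction_matrices

rng = np.random.default_rng(0)
y = rng.integers(0, 3, 300)
matrices = generate_prediction_matrices(
    n_learners=4, true_labels=y, n_classes=3,
    per_learner_accuracy=[0.92, 0.85, 0.80, 0.55], seed=1)

for pm in matrices:
    acc = (pm.argmax_labels() == y).mean()
    print(f"{pm.learner_id}: single accuracy {100 * acc:.2f}%")

labels, ties = adapted_majority_vote(matrices)
print(f"\nall four voting together: accuracy {100 * (labels == y).mean():.2f}% "
      f"({int(ties.sum())} samples resolved by probability tie-break)")

result = brute_force_search(matrices, y, criterion="accuracy")
print(f"\nall {len(result.ranked)} combinations (2^4 - 4 - 1 = 11), ranked:")
for combo, rep in result.ranked:
    print(f"  {'+'.join(combo.learner_ids):<30} accuracy {100 * rep.accuracy:6.2f}%  "
          f"kappa {100 * rep.kappa:6.2f}%")
print(f"\nselected: {'+'.join(result.selected.learner_ids)}")
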