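"""Split a dataset 80/20, carve validation, and balance the training set.

Reproduces the bookkeeping of the study dataset: 1144 images split with
the floor rule into 915 train / 229 test, 10% validation carved from the
training share, and minority classes oversampled to the majority count by
horizontal flipping.
"""

from osteovote import balance_by_flip, carve_validation, make_paper_count_fixture, split_dataset
from osteovote.records import class_counts

# the full 536/263/345 composition at a small image size
records = make_paper_count_fixture(1.0, image_size=(16, 16), seed=0)
print(f"dataset: {len(records)} images, per class {class_counts(records)}")

train, test = split_dataset(records, train_frac=0.8, seed=0)
print(f"80/20 split: {len(train)} train / {len(test)} test (floor rule)")

train, validation = carve_validation(train, val_frac=0.1, seed=1)
print(f"validation carve: {len(train)} train / {len(validation)} validation")

before = class_counts(train)
balanced = balance_by_flip(train, seed=2, allow_duplicates=True)
after = class_counts(balanced)
flips = sum(1 for r in balanced if r.provenance == "flipped_copy")
print(f"balancing: {before} -> {after} (+{flips} horizontal mirrors)")
# every class now matches the majority count; each mirror is the bit-exact
# horizontal flip of a recorded source image
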