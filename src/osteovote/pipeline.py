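"""Dataset splitting, class balancing and image preprocessing.

The workflow mirrors a standard histology-classification recipe: split the
labeled tiles 80/20 into training and test sets, carve 10% of the training
share off as validation, oversample every minority class in the training
set up to the majority class by adding horizontal mirror copies, resize to
the network input size and scale intensities to [0, 1]. Training-time
augmentation (vertical flip, small rotations, brightness jitter) is
applied on the fly, never materialized, so each epoch sees fresh variants.

All operations are deterministic given their seeds; split sizes follow a
floor rule (|train| = floor(frac * n)), which reproduces a 915/229 split
of 1144 images at an 80/20 ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import defaultdict

import numpy as np

from .records import ImageRecord, class_counts


@dataclass(frozen=True)
class AugmentConfig:
    """Training-time augmentation magnitudes.

    vertical_flip_prob : probability of flipping top-to-bottom.
    rotation_range_deg : rotations drawn uniformly in +-range, with
        reflect padding at the borders.
    brightness_delta : multiplicative brightness factor drawn uniformly in
        [1 - delta, 1 + delta], clipped back to the valid intensity range.
    """

    vertical_flip_prob: float = 0.5
    rotation_range_deg: float = 20.0
    brightness_delta: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.vertical_flip_prob <= 1.0:
            raise ValueError("vertical_flip_prob must be a probability")
        if self.rotation_range_deg < 0:
            raise ValueError("rotation_range_deg must be non-negative")
        if not 0.0 <= self.brightness_delta <= 1.0:
            raise ValueError("brightness_delta must lie in [0, 1]")


def split_dataset(
    records: list[ImageRecord],
    train_frac: float = 0.8,
    seed: int = 0,
    stratified: bool = False,
) -> tuple[list[ImageRecord], list[ImageRecord]]:
    """Shuffle and split into (train, test) with |train| = floor(frac * n).

    The default split is a single global shuffle, so per-class training
    counts fluctuate around frac * class size; ``stratified=True`` applies
    the floor rule per class instead.
    """
    if not records:
        raise ValueError("cannot split an empty dataset")
    if not 0.0 < train_frac <= 1.0:
        raise ValueError(f"train_frac must be in (0, 1], got {train_frac}")
    rng = np.random.default_rng(seed)
    if stratified:
        by_class: dict[int, list[ImageRecord]] = defaultdict(list)
        for r in records:
            by_class[r.label].append(r)
        train: list[ImageRecord] = []
        test: list[ImageRecord] = []
        for label in sorted(by_class):
            group = by_class[label]
            order = rng.permutation(len(group))
            cut = int(np.floor(train_frac * len(group)))
            train.extend(group[i] for i in order[:cut])
            test.extend(group[i] for i in order[cut:])
        return train, test
    order = rng.permutation(len(records))
    cut = int(np.floor(train_frac * len(records)))
    train = [records[i] for i in order[:cut]]
    test = [records[i] for i in order[cut:]]
    return train, test


def carve_validation(
    train: list[ImageRecord], val_frac: float = 0.1, seed: int = 0
) -> tuple[list[ImageRecord], list[ImageRecord]]:
    """Remove floor(val_frac * |train|) records as a validation set."""
    if not 0.0 <= val_frac < 1.0:
        raise ValueError(f"val_frac must be in [0, 1), got {val_frac}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(train))
    n_val = int(np.floor(val_frac * len(train)))
    validation = [train[i] for i in order[:n_val]]
    remaining = [train[i] for i in order[n_val:]]
    return remaining, validation


def flip_horizontal(pixels: np.ndarray) -> np.ndarray:
    """Mirror left-to-right (second axis)."""
    return pixels[:, ::-1, :].copy()


def balance_by_flip(
    train: list[ImageRecord], seed: int = 0, allow_duplicates: bool = False
) -> list[ImageRecord]:
    """Oversample every minority class to the majority count with mirrors.

    For each class short of the maximum count, a without-replacement
    random subset of that class's records, sized to the deficit, is
    horizontally flipped and appended (provenance ``flipped_copy``,
    ``source_id`` recording the mirrored original). A deficit larger than
    the class itself cannot be met with distinct mirrors and raises by
    default; with ``allow_duplicates`` the pool is cycled in full
    without-replacement passes, so only the unavoidable excess repeats a
    source (e.g. 208 images oversampled to 422 flip every original once
    and reuse just 6 sources a second time).
    """
    counts = class_counts(train)
    if not counts or any(c == 0 for c in counts.values()):
        raise ValueError(f"every class must be present in the training set, got counts {counts}")
    target = max(counts.values())
    rng = np.random.default_rng(seed)
    by_class: dict[int, list[ImageRecord]] = defaultdict(list)
    for r in train:
        by_class[r.label].append(r)
    out = list(train)
    for label in sorted(by_class):
        pool = by_class[label]
        deficit = target - len(pool)
        if deficit == 0:
            continue
        if deficit > len(pool) and not allow_duplicates:
            raise ValueError(
                f"class {label}: deficit {deficit} exceeds the {len(pool)} available "
                "source images; pass allow_duplicates=True to reuse sources"
            )
        chosen: list[int] = []
        remaining = deficit
        n_pass = 0
        while remaining > 0:  # full passes, then a sampled partial pass
            if remaining >= len(pool):
                chosen.extend(range(len(pool)))
                remaining -= len(pool)
            else:
                chosen.extend(int(i) for i in rng.choice(len(pool), size=remaining,
                                                         replace=False))
                remaining = 0
            n_pass += 1
        suffix = n_pass > 1
        for j, idx in enumerate(chosen):
            src = pool[idx]
            out.append(
                ImageRecord(
                    id=f"{src.id}__flip{j if suffix else ''}",
                    pixels=flip_horizontal(src.pixels),
                    label=src.label,
                    provenance="flipped_copy",
                    source_id=src.id,
                )
            )
    return out


def preprocess(record: ImageRecord, target_size: tuple[int, int] = (224, 224)) -> np.ndarray:
    """Bilinear-resize to ``target_size`` and scale intensities to [0, 1]."""
    from skimage.transform import resize

    h, w = target_size
    if h <= 0 or w <= 0:
        raise ValueError(f"target size must be positive, got {target_size}")
    if record.pixels.shape[:2] == (h, w):
        resized = record.pixels.astype(np.float64)
    else:
        resized = resize(
            record.pixels.astype(np.float64), (h, w),
            order=1, mode="edge", anti_aliasing=False, preserve_range=True,
        )
    return resized / 255.0


def preprocess_batch(records: list[ImageRecord],
                     target_size: tuple[int, int] = (224, 224)) -> tuple[np.ndarray, np.ndarray]:
    """Stack preprocessed images into (X, y) arrays."""
    X = np.stack([preprocess(r, target_size) for r in records])
    y = np.array([r.label for r in records], dtype=np.int64)
    return X, y


def augment_pixels(pixels: np.ndarray, config: AugmentConfig,
                   rng: np.random.Generator, max_value: float = 255.0) -> np.ndarray:
    """Apply flip/rotation/brightness to one image array (any intensity scale)."""
    from skimage.transform import rotate

    out = pixels.astype(np.float64)
    if rng.random() < config.vertical_flip_prob:
        out = out[::-1, :, :]
    if config.rotation_range_deg > 0:
        angle = rng.uniform(-config.rotation_range_deg, config.rotation_range_deg)
        out = rotate(out, angle, mode="reflect", preserve_range=True)
    if config.brightness_delta > 0:
        factor = rng.uniform(1.0 - config.brightness_delta, 1.0 + config.brightness_delta)
        out = out * factor
    return np.clip(out, 0.0, max_value)


def augment(record: ImageRecord, config: AugmentConfig,
            rng: np.random.Generator) -> ImageRecord:
    """Randomly transformed copy of a record, provenance ``augmented``."""
    pixels = augment_pixels(record.pixels, config, rng).astype(np.uint8)
    return ImageRecord(
        id=f"{record.id}__aug",
        pixels=pixels,
        label=record.label,
        provenance="augmented",
        source_id=record.id,
    )


def write_split_manifest(path, splits: dict[str, list[ImageRecord]]) -> None:
    """CSV manifest of a split: id, class_index, subset, provenance, source_id."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "class_index", "subset", "provenance", "source_id"])
        for subset, records in splits.items():
            for r in records:
                writer.writerow([r.id, r.label, subset, r.provenance, r.source_id or ""])
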