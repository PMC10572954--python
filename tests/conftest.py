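import numpy as np
import pytest

from osteovote import ConfusionMatrix, GeneratorConfig, ImageRecord, generate_image_dataset

#: Test-set confusion matrix of the reference CNN on the three-class
#: osteosarcoma problem (rows: Non-Tumor, Necrotic-Tumor, Viable-Tumor).
CNN_CONFUSION = [[108, 5, 1], [1, 54, 0], [0, 3, 57]]

#: Confusion matrix of the three-member voting ensemble on the same test
#: set, reconstructed from its published per-class correct counts
#: (110/114, 51/55, 60/60) and class-wise precision/recall.
ENL_CNE_CONFUSION = [[110, 4, 0], [3, 51, 1], [0, 0, 60]]


@pytest.fixture
def cnn_cm() -> ConfusionMatrix:
    return ConfusionMatrix(np.array(CNN_CONFUSION))


@pytest.fixture
def enl_cne_cm() -> ConfusionMatrix:
    return ConfusionMatrix(np.array(ENL_CNE_CONFUSION))


@pytest.fixture(scope="session")
def small_dataset():
    """30 synthetic 64x64 images per class, fixed seed."""
    config = GeneratorConfig(per_class_counts={0: 30, 1: 30, 2: 30},
                             image_size=(64, 64), seed=7)
    return generate_image_dataset(config)


def make_dummy_records(class_counts: dict[int, int], side: int = 4,
                       seed: int = 0) -> list[ImageRecord]:
    """Tiny random images for split/balance bookkeeping tests."""
    rng = np.random.default_rng(seed)
    records = []
    for label, count in class_counts.items():
        for i in range(count):
            pixels = rng.integers(0, 256, size=(side, side, 3), dtype=np.uint8)
            records.append(ImageRecord(id=f"c{label}_{i}", pixels=pixels, label=label))
    return records
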