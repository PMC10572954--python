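"""Core record types shared across the pipeline.

An :class:`ImageRecord` is one labeled RGB image together with its
provenance: ``original`` images come straight from the source dataset (or
the synthetic generator), ``flipped_copy`` marks horizontal mirrors added
by oversampling, and ``augmented`` marks on-the-fly training-time
transforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PROVENANCES = ("original", "flipped_copy", "augmented")

#: Fixed class order used throughout: it matches the row order of every
#: confusion matrix the pipeline reports.
CLASS_NAMES = ("Non-Tumor", "Necrotic-Tumor", "Viable-Tumor")


@dataclass
class ImageRecord:
    """One labeled RGB image.

    Parameters
    ----------
    id : str
        Unique identifier within a dataset.
    pixels : numpy.ndarray
        ``H x W x 3`` uint8 array, values in [0, 255].
    label : int
        Class index in ``[0, K)``.
    provenance : str
        One of ``original``, ``flipped_copy``, ``augmented``.
    source_id : str or None
        For derived records (flipped/augmented), the id of the record they
        were produced from.
    """

    id: str
    pixels: np.ndarray
    label: int
    provenance: str = "original"
    source_id: str | None = field(default=None)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3 or self.pixels.size == 0:
            raise ValueError(f"pixels must be a non-empty HxWx3 array, got shape {self.pixels.shape}")
        if self.label < 0:
            raise ValueError(f"label must be non-negative, got {self.label}")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape  # type: ignore[return-value]


def class_counts(records: list[ImageRecord], n_classes: int | None = None) -> dict[int, int]:
    """Per-class record counts, including zero entries up to ``n_classes``."""
    labels = [r.label for r in records]
    k = n_classes if n_classes is not None else (max(labels) + 1 if labels else 0)
    counts = {c: 0 for c in range(k)}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    return counts
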