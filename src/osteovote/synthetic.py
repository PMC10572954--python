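"""Synthetic stand-ins for the osteosarcoma histology dataset.

The real study data — 1144 H&E-stained 1024x1024 tiles labeled Non-Tumor
(536), Necrotic-Tumor (263) and Viable-Tumor (345) — cannot be shipped, so
this module generates class-separable RGB images from a simple generative
model: a class base color, darker elliptical "nuclei" blobs at a
class-specific density, and Gaussian pixel noise. The default palette
mimics H&E staining (eosin-pink stroma through densely basophilic purple)
and keeps class mean colors more than three pooled noise standard
deviations apart, so a nearest-mean-color classifier — and any CNN — can
learn the classes.

The module also fabricates per-learner class-probability matrices with a
controllable per-learner accuracy, used to exercise the voting ensemble
without training six backbone networks.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .records import CLASS_NAMES, ImageRecord
from .ensemble import ProbabilityMatrix

#: Per-class image counts of the emulated osteosarcoma dataset.
PAPER_CLASS_COUNTS = (536, 263, 345)


class ConfigurationError(ValueError):
    """Raised for invalid generator configurations."""


@dataclass(frozen=True)
class ClassSpec:
    """Generative description of one synthetic tissue class."""

    label_index: int
    label_name: str
    base_color: tuple[int, int, int]
    blob_density: float = 4.0  # blobs per 10^4 pixels
    noise_sd: float = 18.0

    def __post_init__(self) -> None:
        if not all(0 <= c <= 255 for c in self.base_color):
            raise ConfigurationError(f"base_color components must be in [0,255]: {self.base_color}")
        if self.blob_density < 0 or self.noise_sd < 0:
            raise ConfigurationError("blob_density and noise_sd must be non-negative")


#: Default three-class palette, ordered Non-Tumor, Necrotic-Tumor, Viable-Tumor.
DEFAULT_CLASS_SPECS = (
    ClassSpec(0, CLASS_NAMES[0], (225, 180, 205), blob_density=2.0),
    ClassSpec(1, CLASS_NAMES[1], (160, 120, 160), blob_density=4.0),
    ClassSpec(2, CLASS_NAMES[2], (110, 60, 140), blob_density=8.0),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Counts, image size and seed for one deterministic generation run."""

    per_class_counts: dict[int, int]
    image_size: tuple[int, int] = (96, 96)
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h <= 0 or w <= 0:
            raise ConfigurationError(f"image size must be positive, got {self.image_size}")
        if any(c < 0 for c in self.per_class_counts.values()):
            raise ConfigurationError("per-class counts must be non-negative")


def _render_image(spec: ClassSpec, size: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    from skimage.draw import ellipse

    h, w = size
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = spec.base_color
    n_blobs = int(round(spec.blob_density * h * w / 1e4))
    blob_color = np.clip(np.asarray(spec.base_color, dtype=np.float64) - 60.0, 0, 255)
    max_axis = max(3, min(h, w) // 12)
    for _ in range(n_blobs):
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        ry = rng.uniform(2, max_axis)
        rx = rng.uniform(2, max_axis)
        rot = rng.uniform(0, np.pi)
        rr, cc = ellipse(cy, cx, ry, rx, shape=(h, w), rotation=rot)
        img[rr, cc] = blob_color
    img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_image_dataset(
    config: GeneratorConfig,
    class_specs: list[ClassSpec] | tuple[ClassSpec, ...] = DEFAULT_CLASS_SPECS,
) -> list[ImageRecord]:
    """Generate a labeled image dataset from the class-conditional model.

    Deterministic given ``config.seed``: two runs with identical arguments
    produce bit-identical pixels.
    """
    known = {s.label_index for s in class_specs}
    unknown = set(config.per_class_counts) - known
    if unknown:
        raise ConfigurationError(f"counts refer to unknown class indices {sorted(unknown)}")
    rng = np.random.default_rng(config.seed)
    by_index = {s.label_index: s for s in class_specs}
    records: list[ImageRecord] = []
    for label in sorted(config.per_class_counts):
        spec = by_index[label]
        for i in range(config.per_class_counts[label]):
            pixels = _render_image(spec, config.image_size, rng)
            records.append(
                ImageRecord(id=f"{spec.label_name}_{i:05d}", pixels=pixels, label=label)
            )
    return records


def make_paper_count_fixture(
    scale: float = 1.0,
    image_size: tuple[int, int] = (96, 96),
    seed: int = 0,
    class_specs: tuple[ClassSpec, ...] = DEFAULT_CLASS_SPECS,
) -> list[ImageRecord]:
    """Dataset with the study's class composition 536/263/345, scaled.

    Counts are ``floor(scale * count + 0.5)`` (round half up) so that, e.g.,
    scale 0.1 gives (54, 26, 35). ``scale`` must keep every class non-empty.
    """
    if scale <= 0:
        raise ConfigurationError(f"scale must be positive, got {scale}")
    counts = {i: int(np.floor(scale * c + 0.5)) for i, c in enumerate(PAPER_CLASS_COUNTS)}
    if any(c < 1 for c in counts.values()):
        raise ConfigurationError(f"scale {scale} rounds a class to zero images: {counts}")
    config = GeneratorConfig(per_class_counts=counts, image_size=image_size, seed=seed)
    return generate_image_dataset(config, class_specs)


def generate_prediction_matrices(
    n_learners: int,
    true_labels: np.ndarray | list[int],
    n_classes: int,
    per_learner_accuracy: list[float],
    concentration: float = 20.0,
    seed: int = 0,
) -> list[ProbabilityMatrix]:
    """Fabricate per-learner class-probability matrices.

    For each learner and sample, the predicted class equals the true label
    with probability equal to the learner's accuracy (independent Bernoulli
    draws); otherwise it is uniform over the remaining classes. The row is
    a Dirichlet draw sharply peaked (``concentration``) on the predicted
    class, with the maximum guaranteed to sit on it, so the row's argmax is
    exactly the Bernoulli outcome and every row sums to one.
    """
    if n_learners < 1:
        raise ConfigurationError("need at least one learner")
    if len(per_learner_accuracy) != n_learners:
        raise ConfigurationError("per_learner_accuracy must have one entry per learner")
    if any(not 0.0 <= a <= 1.0 for a in per_learner_accuracy):
        raise ConfigurationError("accuracies must lie in [0, 1]")
    if concentration <= 0:
        raise ConfigurationError("concentration must be positive")
    y = np.asarray(true_labels, dtype=int)
    n = y.shape[0]
    rng = np.random.default_rng(seed)
    out: list[ProbabilityMatrix] = []
    for li, acc in enumerate(per_learner_accuracy):
        correct = rng.random(n) < acc
        chosen = y.copy()
        wrong = ~correct
        if wrong.any():
            # uniform over the K-1 classes other than the true label
            offset = rng.integers(1, n_classes, size=int(wrong.sum()))
            chosen[wrong] = (y[wrong] + offset) % n_classes
        alpha = np.ones((n, n_classes))
        alpha[np.arange(n), chosen] = concentration
        rows = rng.gamma(alpha)
        rows /= rows.sum(axis=1, keepdims=True)
        # guarantee the argmax lands on the chosen class by swapping it in
        amax = rows.argmax(axis=1)
        idx = np.arange(n)
        rows[idx, amax], rows[idx, chosen] = rows[idx, chosen], rows[idx, amax]
        out.append(ProbabilityMatrix(learner_id=f"learner_{li}", values=rows))
    return out


# ---------------------------------------------------------------------------
# On-disk formats: directory-per-class PNG trees with a manifest CSV, and a
# flat CSV dialect for probability matrices.

def write_image_dataset(records: list[ImageRecord], root: str | Path,
                        class_names: tuple[str, ...] = CLASS_NAMES) -> Path:
    """Write PNGs as ``<root>/<class_name>/<id>.png`` plus manifest.csv."""
    root = Path(root)
    manifest = root / "manifest.csv"
    root.mkdir(parents=True, exist_ok=True)
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "class_name", "class_index", "provenance"])
        for rec in records:
            cname = class_names[rec.label]
            cdir = root / cname
            cdir.mkdir(exist_ok=True)
            Image.fromarray(rec.pixels).save(cdir / f"{rec.id}.png")
            writer.writerow([rec.id, cname, rec.label, rec.provenance])
    return manifest


def read_image_dataset(root: str | Path,
                       class_names: tuple[str, ...] = CLASS_NAMES) -> list[ImageRecord]:
    """Read a directory-per-class PNG/JPEG tree back into records."""
    root = Path(root)
    if not root.is_dir():
        raise ConfigurationError(f"data root {root} does not exist")
    name_to_index = {n: i for i, n in enumerate(class_names)}
    records: list[ImageRecord] = []
    for cname in class_names:
        cdir = root / cname
        if not cdir.is_dir():
            continue
        for path in sorted(cdir.iterdir()):
            if path.suffix.lower() not in {".png", ".jpg", ".jpeg"}:
                continue
            pixels = np.asarray(Image.open(path).convert("RGB"))
            records.append(ImageRecord(id=path.stem, pixels=pixels, label=name_to_index[cname]))
    if not records:
        raise ConfigurationError(f"no class folders with images found under {root}")
    return records


def write_probability_matrices(matrices: list[ProbabilityMatrix], path: str | Path) -> Path:
    """CSV with columns learner_id, sample_id, p_0 .. p_{K-1}."""
    path = Path(path)
    k = matrices[0].values.shape[1]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["learner_id", "sample_id"] + [f"p_{j}" for j in range(k)])
        for pm in matrices:
            for i, row in enumerate(pm.values):
                writer.writerow([pm.learner_id, i] + [f"{p:.17g}" for p in row])
    return path


def read_probability_matrices(path: str | Path) -> list[ProbabilityMatrix]:
    import pandas as pd

    df = pd.read_csv(path)
    pcols = [c for c in df.columns if c.startswith("p_")]
    out = []
    for lid, grp in df.groupby("learner_id", sort=False):
        grp = grp.sort_values("sample_id")
        out.append(ProbabilityMatrix(learner_id=str(lid), values=grp[pcols].to_numpy()))
    return out
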