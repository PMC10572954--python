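"""End-to-end pipeline: ingest/synthesize -> split -> balance -> train ->
predict -> evaluate -> ensemble search.

Each stage writes its artifacts into a run directory so a finished run can
be re-reported without recomputation:

* ``manifest_split.csv``   — id, class, subset, provenance per record
* ``architecture.json``    — the trained stack with shapes and counts
* ``history.csv``          — per-epoch training/validation curves
* ``predictions.csv``      — per-learner probability rows (CSV dialect)
* ``confusion_matrix.csv`` — test-set confusion matrix with class names
* ``metrics.json``         — full-precision metric report
* ``search.json`` / ``search.csv`` — ranked ensemble combinations
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import synthetic
from .architecture import proposed_architecture, small_architecture
from .ensemble import brute_force_search
from .metrics import metric_report
from .nn import TrainingConfig, train_learner
from .pipeline import (AugmentConfig, balance_by_flip, carve_validation,
                       preprocess_batch, split_dataset, write_split_manifest)
from .records import CLASS_NAMES

logger = logging.getLogger("osteovote")


@dataclass
class RunConfig:
    """Everything one reproducible pipeline run needs."""

    out_dir: str = "runs/run"
    data_root: str | None = None  # None -> synthesize
    per_class_counts: tuple[int, ...] = (50, 50, 50)
    image_size: tuple[int, int] = (96, 96)
    input_size: tuple[int, int] = (32, 32)
    seed: int = 0
    train_frac: float = 0.8
    val_frac: float = 0.1
    balance: bool = True
    stratified: bool = False
    epochs: int = 8
    batch_size: int = 16
    learning_rate: float = 0.001
    dropout_rate: float = 0.25
    augment: AugmentConfig | None = field(
        default_factory=lambda: AugmentConfig(rotation_range_deg=10.0, brightness_delta=0.1))
    n_extra_learners: int = 2
    extra_learner_accuracy: float = 0.9
    criterion: str = "accuracy"
    class_names: tuple[str, ...] = CLASS_NAMES


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    Deterministic given ``config`` for every stage (training included:
    the backend is seeded numpy). Raises with the failing stage named; no
    stage writes artifacts before its inputs validated.
    """
    out = Path(config.out_dir)
    stage = "configure"
    try:
        if config.data_root is not None and not Path(config.data_root).is_dir():
            raise FileNotFoundError(f"data root {config.data_root} does not exist")
        out.mkdir(parents=True, exist_ok=True)
        _setup_logging(out)
        t0 = time.time()

        stage = "ingest"
        if config.data_root is None:
            gen = synthetic.GeneratorConfig(
                per_class_counts={i: c for i, c in enumerate(config.per_class_counts)},
                image_size=config.image_size, seed=config.seed)
            records = synthetic.generate_image_dataset(gen)
            logger.info("synthesized %d images", len(records))
        else:
            records = synthetic.read_image_dataset(config.data_root, config.class_names)
            logger.info("read %d images from %s", len(records), config.data_root)

        stage = "split"
        train, test = split_dataset(records, config.train_frac, seed=config.seed,
                                    stratified=config.stratified)
        train, validation = carve_validation(train, config.val_frac, seed=config.seed + 1)

        stage = "balance"
        if config.balance:
            train = balance_by_flip(train, seed=config.seed + 2)
        write_split_manifest(out / "manifest_split.csv",
                             {"train": train, "validation": validation, "test": test})

        stage = "preprocess"
        Xtr, ytr = preprocess_batch(train, config.input_size)
        Xva, yva = (preprocess_batch(validation, config.input_size)
                    if validation else (np.empty((0,)), np.empty((0,), dtype=int)))
        Xte, yte = preprocess_batch(test, config.input_size)

        stage = "train"
        spec = small_architecture(input_shape=(*config.input_size, 3),
                                  dropout_rate=config.dropout_rate,
                                  n_classes=len(config.class_names))
        spec.to_json(out / "architecture.json")
        proposed_architecture().to_json(out / "architecture_full.json")
        tconf = TrainingConfig(learning_rate=config.learning_rate,
                               batch_size=config.batch_size, epochs=config.epochs)
        learner = train_learner(spec, tconf, (Xtr, ytr),
                                validation=(Xva, yva) if len(yva) else None,
                                augment=config.augment, seed=config.seed + 3)
        learner.write_history(out / "history.csv")
        logger.info("trained %d epochs; final %s", config.epochs,
                    learner.history[-1] if learner.history else "(none)")

        stage = "predict"
        cnn_probs = learner.predict_proba(Xte)
        extras = synthetic.generate_prediction_matrices(
            n_learners=config.n_extra_learners, true_labels=yte,
            n_classes=len(config.class_names),
            per_learner_accuracy=[config.extra_learner_accuracy] * config.n_extra_learners,
            seed=config.seed + 4)
        matrices = [cnn_probs] + extras
        synthetic.write_probability_matrices(matrices, out / "predictions.csv")

        stage = "evaluate"
        rep = metric_report(yte, probs=cnn_probs.values, class_names=config.class_names)
        _write_confusion_csv(out / "confusion_matrix.csv", rep.cm.counts, config.class_names)
        (out / "metrics.json").write_text(json.dumps(rep.to_dict(), indent=2))
        logger.info("cnn test accuracy %.4f kappa %.4f", rep.accuracy, rep.kappa)

        stage = "search"
        result = brute_force_search(matrices, yte, criterion=config.criterion)
        _write_search(out, result)
        logger.info("best combination %s (%s=%.4f)", result.selected.learner_ids,
                    config.criterion, result.best_report.accuracy)

        (out / "run_config.json").write_text(json.dumps(
            {k: v if not isinstance(v, AugmentConfig) else asdict(v)
             for k, v in asdict(config).items()}, indent=2, default=str))
        logger.info("pipeline finished in %.1fs", time.time() - t0)
        return out
    except Exception as exc:
        logger.error("stage %r failed: %s", stage, exc)
        raise


def _setup_logging(out: Path) -> None:
    if not any(isinstance(h, logging.FileHandler) and
               Path(getattr(h, "baseFilename", "")) == (out / "run.log").resolve()
               for h in logger.handlers):
        fh = logging.FileHandler(out / "run.log")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(fh)
    logger.setLevel(logging.INFO)


def _write_confusion_csv(path: Path, counts: np.ndarray,
                         class_names: tuple[str, ...]) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["true\\pred"] + list(class_names))
        for name, row in zip(class_names, counts):
            writer.writerow([name] + [int(v) for v in row])


def read_confusion_csv(path) -> tuple[np.ndarray, tuple[str, ...]]:
    import csv

    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    names = tuple(rows[0][1:])
    counts = np.array([[int(v) for v in r[1:]] for r in rows[1:]], dtype=np.int64)
    return counts, names


def _write_search(out: Path, result) -> None:
    import csv

    payload = [{"members": list(c.learner_ids),
                "accuracy": r.accuracy, "kappa": r.kappa,
                "macro_precision": r.macro_precision, "macro_recall": r.macro_recall,
                "macro_f1": r.macro_f1,
                "weighted_precision": r.weighted_precision,
                "weighted_recall": r.weighted_recall, "weighted_f1": r.weighted_f1}
               for c, r in result.ranked]
    (out / "search.json").write_text(json.dumps(
        {"criterion": result.criterion, "ranked": payload}, indent=2))
    with open(out / "search.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["members", "accuracy", "precision", "recall", "f1", "kappa"])
        for row in payload:
            writer.writerow(["+".join(row["members"]),
                             f"{100 * row['accuracy']:.2f}",
                             f"{row['weighted_precision']:.4f}",
                             f"{row['weighted_recall']:.4f}",
                             f"{row['weighted_f1']:.4f}",
                             f"{100 * row['kappa']:.2f}"])


def report(run_dir) -> dict[str, str]:
    """Render class-wise and combination tables from a finished run's artifacts.

    Re-derives every number from the stored confusion matrix and search
    results, so reporting never drifts from what the run computed.
    Idempotent; raises if required artifacts are missing.
    """
    run_dir = Path(run_dir)
    missing = [n for n in ("confusion_matrix.csv", "search.json")
               if not (run_dir / n).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run {run_dir}: missing {missing}")
    counts, names = read_confusion_csv(run_dir / "confusion_matrix.csv")
    from .metrics import ConfusionMatrix, report_from_matrix
    rep = report_from_matrix(ConfusionMatrix(counts, names))

    lines = [f"{'Class':<16}{'Accuracy':>9}{'Precision':>10}{'Recall':>8}{'F1':>5}"]
    for i, name in enumerate(names):
        lines.append(f"{name:<16}"
                     f"{100 * rep.per_class_accuracy[i]:>9.2f}"
                     f"{round(100 * rep.per_class_precision[i]):>10d}"
                     f"{round(100 * rep.per_class_recall[i]):>8d}"
                     f"{round(100 * rep.per_class_f1[i]):>5d}")
    lines.append(f"Overall accuracy {100 * rep.accuracy:.2f}%  kappa {100 * rep.kappa:.2f}%")
    classwise = "\n".join(lines)

    search = json.loads((run_dir / "search.json").read_text())
    lines = [f"{'Members':<40}{'Accuracy':>9}{'Kappa':>8}"]
    for row in search["ranked"]:
        lines.append(f"{'+'.join(row['members']):<40}"
                     f"{100 * row['accuracy']:>9.2f}{100 * row['kappa']:>8.2f}")
    combos = "\n".join(lines)
    return {"classwise": classwise, "combinations": combos}
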