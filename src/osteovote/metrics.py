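"""Evaluation metrics for multiclass classifiers.

Everything is computed from first principles on a K x K confusion matrix
(rows = true class, columns = predicted class) and, for the probabilistic
metrics, on per-sample class-probability rows:

* accuracy = trace / N
* per-class precision, recall, F1 and one-vs-rest class accuracy from the
  binary decomposition (TP, TN, FP, FN) of each class
* Cohen's kappa = (p_o - p_e) / (1 - p_e), with chance agreement p_e taken
  as the marginal-product expectation sum_i row_i * col_i / N^2
* multiclass log-loss = mean negative log predicted probability of the
  true class (the binary cross-entropy form generalized to K classes),
  with probabilities clipped to [eps, 1 - eps]
* one-vs-rest ROC AUC via the Mann-Whitney rank statistic (ties count
  half), with unweighted macro and flattened micro averages

Zero-denominator metrics are defined as 0 with a warning rather than
raising, so a degenerate class never aborts a full report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .records import CLASS_NAMES


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K count matrix; rows index the true class, columns the predicted."""

    counts: np.ndarray
    class_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError(f"confusion matrix must be square, got shape {counts.shape}")
        if (counts < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")
        if counts.sum() == 0:
            raise ValueError("confusion matrix must contain at least one observation")
        object.__setattr__(self, "counts", counts)

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class BinaryCounts:
    """One-vs-rest decomposition of a confusion matrix for one class."""

    tpos: int
    tng: int
    fpos: int
    fng: int

    @property
    def total(self) -> int:
        return self.tpos + self.tng + self.fpos + self.fng


def confusion_matrix(y_true, y_pred, n_classes: int,
                     class_names: tuple[str, ...] | None = None) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.size == 0:
        raise ValueError("empty label sequences")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if arr.min() < 0 or arr.max() >= n_classes:
            raise ValueError(f"{name} contains labels outside [0, {n_classes})")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts, class_names)


def one_vs_rest_counts(cm: ConfusionMatrix, class_index: int) -> BinaryCounts:
    k = class_index
    if not 0 <= k < cm.n_classes:
        raise ValueError(f"class index {k} out of range [0, {cm.n_classes})")
    tpos = int(cm.counts[k, k])
    fng = int(cm.counts[k, :].sum()) - tpos
    fpos = int(cm.counts[:, k].sum()) - tpos
    tng = cm.total - tpos - fng - fpos
    return BinaryCounts(tpos=tpos, tng=tng, fpos=fpos, fng=fng)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: zero denominator, defining the value as 0", RuntimeWarning,
                      stacklevel=3)
        return 0.0
    return num / den


def accuracy(cm: ConfusionMatrix) -> float:
    return float(np.trace(cm.counts)) / cm.total


def precision(bc: BinaryCounts) -> float:
    return _safe_div(bc.tpos, bc.tpos + bc.fpos, "precision")


def recall(bc: BinaryCounts) -> float:
    return _safe_div(bc.tpos, bc.tpos + bc.fng, "recall")


def f1_score(bc: BinaryCounts) -> float:
    pn, rl = precision(bc), recall(bc)
    return _safe_div(2.0 * pn * rl, pn + rl, "f1")


def class_accuracy(bc: BinaryCounts) -> float:
    return _safe_div(bc.tpos + bc.tng, bc.total, "class accuracy")


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa: chance-corrected agreement from the marginals."""
    n = cm.total
    p_o = float(np.trace(cm.counts)) / n
    rows = cm.counts.sum(axis=1).astype(np.float64)
    cols = cm.counts.sum(axis=0).astype(np.float64)
    p_e = float(rows @ cols) / (n * n)
    if p_e == 1.0:
        warnings.warn("kappa: chance agreement is 1, defining kappa as 0", RuntimeWarning)
        return 0.0
    return (p_o - p_e) / (1.0 - p_e)


def multiclass_log_loss(y_true, probs: np.ndarray, clip_eps: float = 1e-15) -> float:
    y_true = np.asarray(y_true, dtype=int)
    probs = np.asarray(probs, dtype=np.float64)
    if probs.ndim != 2 or probs.shape[0] != y_true.shape[0]:
        raise ValueError("probability matrix rows must align with labels")
    sums = probs.sum(axis=1)
    if np.abs(sums - 1.0).max() > 1e-6:
        raise ValueError("probability rows must sum to 1 within 1e-6")
    p = np.clip(probs[np.arange(len(y_true)), y_true], clip_eps, 1.0 - clip_eps)
    return float(-np.mean(np.log(p)))


def _binary_auc(scores: np.ndarray, positives: np.ndarray) -> float:
    """AUC via the rank / Mann-Whitney statistic; ties contribute 0.5."""
    from scipy.stats import rankdata

    n_pos = int(positives.sum())
    n_neg = len(positives) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined without both positives and negatives")
    ranks = rankdata(scores)  # average ranks handle ties
    rank_sum = ranks[positives].sum()
    u = rank_sum - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def ovr_auc(y_true, probs: np.ndarray) -> dict:
    """One-vs-rest ROC AUC per class plus micro and macro averages.

    A class with no positives or no negatives gets ``None`` and is
    excluded from the macro average.
    """
    y_true = np.asarray(y_true, dtype=int)
    probs = np.asarray(probs, dtype=np.float64)
    k = probs.shape[1]
    per_class: list[float | None] = []
    for c in range(k):
        pos = y_true == c
        if pos.all() or not pos.any():
            warnings.warn(f"AUC for class {c} undefined (one-sided labels)", RuntimeWarning)
            per_class.append(None)
            continue
        per_class.append(_binary_auc(probs[:, c], pos))
    defined = [a for a in per_class if a is not None]
    macro = float(np.mean(defined)) if defined else 0.0
    onehot = np.zeros_like(probs, dtype=bool)
    onehot[np.arange(len(y_true)), y_true] = True
    micro = _binary_auc(probs.ravel(), onehot.ravel())
    return {"per_class": per_class, "macro": macro, "micro": micro}


@dataclass
class MetricReport:
    """Complete metric suite for one classifier on one evaluation split.

    All fields are fractions (AUC/kappa on their natural scales);
    :meth:`as_percent` applies the two presentation roundings used in
    published tables (integer percents for class-wise tables, two-decimal
    percents for model-comparison tables).
    """

    cm: ConfusionMatrix
    accuracy: float
    per_class_precision: list[float]
    per_class_recall: list[float]
    per_class_f1: list[float]
    per_class_accuracy: list[float]
    per_class_auc: list[float | None] = field(default_factory=list)
    macro_precision: float = 0.0
    macro_recall: float = 0.0
    macro_f1: float = 0.0
    weighted_precision: float = 0.0
    weighted_recall: float = 0.0
    weighted_f1: float = 0.0
    kappa: float = 0.0
    log_loss: float | None = None
    macro_auc: float | None = None
    micro_auc: float | None = None

    @staticmethod
    def pct(value: float, decimals: int = 2) -> float:
        """Presentation rounding: value as a percent with given decimals."""
        return round(100.0 * value, decimals) if decimals else int(round(100.0 * value))

    def as_percent(self, decimals: int = 2) -> dict:
        p = lambda v: self.pct(v, decimals)
        return {
            "accuracy": p(self.accuracy),
            "precision": [p(v) for v in self.per_class_precision],
            "recall": [p(v) for v in self.per_class_recall],
            "f1": [p(v) for v in self.per_class_f1],
            "class_accuracy": [p(v) for v in self.per_class_accuracy],
            "kappa": p(self.kappa),
        }

    def to_dict(self) -> dict:
        return {
            "confusion_matrix": self.cm.counts.tolist(),
            "accuracy": self.accuracy,
            "per_class_precision": self.per_class_precision,
            "per_class_recall": self.per_class_recall,
            "per_class_f1": self.per_class_f1,
            "per_class_accuracy": self.per_class_accuracy,
            "per_class_auc": self.per_class_auc,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "weighted_precision": self.weighted_precision,
            "weighted_recall": self.weighted_recall,
            "weighted_f1": self.weighted_f1,
            "kappa": self.kappa,
            "log_loss": self.log_loss,
            "macro_auc": self.macro_auc,
            "micro_auc": self.micro_auc,
        }


def report_from_matrix(cm: ConfusionMatrix) -> MetricReport:
    """Assemble the label-based metric suite from a confusion matrix alone."""
    k = cm.n_classes
    bcs = [one_vs_rest_counts(cm, c) for c in range(k)]
    prec = [precision(b) for b in bcs]
    rec = [recall(b) for b in bcs]
    f1 = [f1_score(b) for b in bcs]
    cacc = [class_accuracy(b) for b in bcs]
    support = cm.counts.sum(axis=1).astype(np.float64)
    w = support / support.sum()
    return MetricReport(
        cm=cm,
        accuracy=accuracy(cm),
        per_class_precision=prec,
        per_class_recall=rec,
        per_class_f1=f1,
        per_class_accuracy=cacc,
        macro_precision=float(np.mean(prec)),
        macro_recall=float(np.mean(rec)),
        macro_f1=float(np.mean(f1)),
        weighted_precision=float(w @ prec),
        weighted_recall=float(w @ rec),
        weighted_f1=float(w @ f1),
        kappa=kappa(cm),
    )


def metric_report(y_true, y_pred=None, probs: np.ndarray | None = None,
                  n_classes: int | None = None,
                  class_names: tuple[str, ...] | None = CLASS_NAMES) -> MetricReport:
    """Full metric report from labels and (optionally) probability rows.

    If ``y_pred`` is omitted it is taken as the row-argmax of ``probs``;
    probabilistic metrics (log-loss, AUC) are filled in whenever ``probs``
    is given.
    """
    y_true = np.asarray(y_true, dtype=int)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_pred is None:
        if probs is None:
            raise ValueError("need y_pred or probs")
        y_pred = np.asarray(probs).argmax(axis=1)
    if n_classes is None:
        n_classes = probs.shape[1] if probs is not None else int(max(y_true.max(), np.max(y_pred))) + 1
    cm = confusion_matrix(y_true, y_pred, n_classes, class_names)
    rep = report_from_matrix(cm)
    if probs is not None:
        rep.log_loss = multiclass_log_loss(y_true, probs)
        auc = ovr_auc(y_true, probs)
        rep.per_class_auc = auc["per_class"]
        rep.macro_auc = auc["macro"]
        rep.micro_auc = auc["micro"]
    return rep
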