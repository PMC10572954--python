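"""Adapted majority-voting ensemble with probability tie-breaking.

Each base learner casts one hard vote per sample for its most probable
class. The plurality class wins; when two or more classes tie on vote
count, the tie is resolved by comparing the predicted probabilities the
participating learners assigned to the tied classes, summed across
learners — the tied class with the greatest accumulated probability wins.
A residual exact tie falls back to the lowest class index so the rule is
deterministic.

Base-learner selection is exhaustive: every subset of two or more
registered learners (2^k - k - 1 combinations for k learners) is scored
on a labeled evaluation split and ranked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .metrics import MetricReport, metric_report


@dataclass(frozen=True)
class ProbabilityMatrix:
    """Class-probability predictions of one base learner: n_samples x K."""

    learner_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2 or values.shape[1] < 2:
            raise ValueError(f"expected an n x K matrix with K >= 2, got shape {values.shape}")
        if (values < -1e-12).any() or (values > 1 + 1e-12).any():
            raise ValueError("probabilities must lie in [0, 1]")
        if np.abs(values.sum(axis=1) - 1.0).max() > 1e-6:
            raise ValueError("every probability row must sum to 1 within 1e-6")
        object.__setattr__(self, "values", values)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_classes(self) -> int:
        return self.values.shape[1]

    def argmax_labels(self) -> np.ndarray:
        return self.values.argmax(axis=1)


@dataclass(frozen=True)
class VoteTally:
    """Per-sample, per-class hard-vote counts; rows sum to the learner count."""

    counts: np.ndarray

    @property
    def n_learners(self) -> int:
        return int(self.counts[0].sum()) if len(self.counts) else 0


@dataclass(frozen=True)
class EnsembleCombination:
    """A candidate ensemble: a set of at least two distinct learner ids."""

    learner_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        ids = tuple(sorted(self.learner_ids))
        if len(ids) < 2 or len(set(ids)) != len(ids):
            raise ValueError("a combination needs at least two distinct learner ids")
        object.__setattr__(self, "learner_ids", ids)

    def __len__(self) -> int:
        return len(self.learner_ids)


@dataclass
class CombinationSearchResult:
    """Ranked outcome of the exhaustive combination search."""

    ranked: list[tuple[EnsembleCombination, MetricReport]]
    criterion: str

    @property
    def selected(self) -> EnsembleCombination:
        return self.ranked[0][0]

    @property
    def best_report(self) -> MetricReport:
        return self.ranked[0][1]


def _check_alignment(predictions: list[ProbabilityMatrix]) -> tuple[int, int]:
    if len(predictions) < 2:
        raise ValueError("voting needs at least two base learners")
    shapes = {(p.n_samples, p.n_classes) for p in predictions}
    if len(shapes) != 1:
        raise ValueError(f"prediction matrices disagree on shape: {sorted(shapes)}")
    return shapes.pop()


def tally_votes(predictions: list[ProbabilityMatrix]) -> VoteTally:
    """Count one argmax vote per learner per sample (CF of the vote counter)."""
    n, k = _check_alignment(predictions)
    counts = np.zeros((n, k), dtype=np.int64)
    rows = np.arange(n)
    for pm in predictions:
        counts[rows, pm.argmax_labels()] += 1
    return VoteTally(counts)


def adapted_majority_vote(
    predictions: list[ProbabilityMatrix],
) -> tuple[np.ndarray, np.ndarray]:
    """Plurality vote with probability tie-breaking.

    Returns ``(labels, tie_flags)``: ``tie_flags[i]`` is True where the
    winning class was decided by the accumulated-probability rule rather
    than a strict vote majority.
    """
    tally = tally_votes(predictions)
    counts = tally.counts
    n, k = counts.shape
    prob_sum = np.add.reduce([pm.values for pm in predictions])
    labels = np.empty(n, dtype=np.int64)
    tie_flags = np.zeros(n, dtype=bool)
    top = counts.max(axis=1)
    tied = counts == top[:, None]
    n_tied = tied.sum(axis=1)
    clear = n_tied == 1
    labels[clear] = counts[clear].argmax(axis=1)
    for i in np.flatnonzero(~clear):
        candidates = np.flatnonzero(tied[i])
        sums = prob_sum[i, candidates]
        labels[i] = candidates[int(np.argmax(sums))]  # argmax: lowest index on exact tie
        tie_flags[i] = True
    return labels, tie_flags


def enumerate_combinations(learner_ids) -> list[EnsembleCombination]:
    """All subsets of size >= 2 in deterministic sorted order: 2^k - k - 1."""
    ids = sorted(set(learner_ids))
    if len(ids) < 2:
        raise ValueError("need at least two learner ids to form combinations")
    out = []
    for size in range(2, len(ids) + 1):
        for combo in combinations(ids, size):
            out.append(EnsembleCombination(combo))
    return out


def brute_force_search(
    predictions: list[ProbabilityMatrix],
    y_eval,
    criterion: str = "accuracy",
) -> CombinationSearchResult:
    """Score every learner combination with the adapted vote and rank them.

    Ranking is by the chosen criterion descending; ties prefer fewer
    learners, then higher kappa, then lexicographic ids. The evaluation
    labels can come from any labeled split; a held-out validation split
    avoids selection leakage, while passing the test split reproduces a
    test-set-ranked search.
    """
    criteria = {
        "accuracy": lambda r: r.accuracy,
        "kappa": lambda r: r.kappa,
        "f1": lambda r: r.macro_f1,
    }
    if criterion not in criteria:
        raise ValueError(f"unknown criterion {criterion!r}; choose from {sorted(criteria)}")
    y_eval = np.asarray(y_eval, dtype=int)
    n, k = _check_alignment(predictions)
    if y_eval.shape[0] != n:
        raise ValueError("evaluation labels must align with the prediction matrices")
    by_id = {pm.learner_id: pm for pm in predictions}
    if len(by_id) != len(predictions):
        raise ValueError("duplicate learner ids")
    key = criteria[criterion]
    scored: list[tuple[EnsembleCombination, MetricReport]] = []
    for combo in enumerate_combinations(by_id):
        members = [by_id[lid] for lid in combo.learner_ids]
        labels, _ = adapted_majority_vote(members)
        mean_probs = np.mean([pm.values for pm in members], axis=0)
        rep = metric_report(y_eval, y_pred=labels, probs=mean_probs, n_classes=k)
        scored.append((combo, rep))
    scored.sort(key=lambda cr: (-key(cr[1]), len(cr[0]), -cr[1].kappa, cr[0].learner_ids))
    return CombinationSearchResult(ranked=scored, criterion=criterion)
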