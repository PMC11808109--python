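"""Size gating, confusion counts, and group majority voting.

Cell frames carry a hardware-computed equivalent circular diameter; a
single size threshold (e.g. 15 µm for squamous metaplastic vs squamous
epithelial cervical cells, or 10 µm for microspheres vs hematocytes)
turns that into a two-way classification whose quality is scored against
manual labels by per-class precision.

For sample-level decisions, images are shuffled into fixed-size groups
(64 by default) and a pluggable per-group scorer labels each group; the
sample takes the majority label.  The scorer is any callable — a trained
CNN can be plugged in; a group-aggregate logistic scorer is provided as
the default baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Hashable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GateRule", "ConfusionCounts", "GroupVote",
    "gate_by_size", "confusion", "precision_from_counts", "group_vote",
    "make_logistic_group_scorer",
]


@dataclass(frozen=True)
class GateRule:
    """Single size threshold; ``tie`` picks the label at exact equality."""

    threshold_um: float
    above_label: str = "above"
    below_label: str = "below"
    tie: str = "above"

    def __post_init__(self) -> None:
        if self.threshold_um <= 0:
            raise ValueError("threshold_um must be positive")
        if self.tie not in ("above", "below"):
            raise ValueError("tie must be 'above' or 'below'")


@dataclass
class ConfusionCounts:
    """Counts per (true_label, predicted_label) pair."""

    counts: dict[tuple[Hashable, Hashable], int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def correct(self, label: Hashable) -> int:
        return self.counts.get((label, label), 0)

    def class_total(self, label: Hashable) -> int:
        return sum(c for (t, _), c in self.counts.items() if t == label)

    def class_precision(self, label: Hashable) -> float:
        """Percent of class ``label`` items predicted correctly."""
        return precision_from_counts(self.correct(label), self.class_total(label))

    def to_frame(self) -> pd.DataFrame:
        rows = [{"true": t, "predicted": p, "count": c}
                for (t, p), c in sorted(self.counts.items(), key=str)]
        return pd.DataFrame(rows)


@dataclass
class GroupVote:
    group_size: int
    group_labels: list[Hashable]
    sample_label: Hashable
    vote_fractions: dict[Hashable, float]
    n_dropped: int
    tie_broken: bool = False


def gate_by_size(sizes_um: Sequence[float], rule: GateRule) -> list[str]:
    """Label each size by the threshold rule (ties go to ``rule.tie``)."""
    labels = []
    for s in sizes_um:
        if s < 0:
            raise ValueError("sizes must be non-negative")
        if s > rule.threshold_um:
            labels.append(rule.above_label)
        elif s < rule.threshold_um:
            labels.append(rule.below_label)
        else:
            labels.append(rule.above_label if rule.tie == "above" else rule.below_label)
    return labels


def confusion(pred: Sequence[Hashable], truth: Sequence[Hashable]) -> ConfusionCounts:
    """Order-independent (true, predicted) pair counts."""
    if len(pred) != len(truth):
        raise ValueError("pred and truth lengths differ")
    counts: dict[tuple[Hashable, Hashable], int] = {}
    for t, p in zip(truth, pred):
        counts[(t, p)] = counts.get((t, p), 0) + 1
    return ConfusionCounts(counts)


def precision_from_counts(correct: int, total: int) -> float:
    """``100 * correct / total`` as percent, round-half-even at 2 decimals."""
    if total <= 0:
        raise ZeroDivisionError("total must be positive")
    if not (0 <= correct <= total):
        raise ValueError("correct must lie in [0, total]")
    return float(np.round(100.0 * correct / total, 2))


def group_vote(items: Sequence, group_size: int,
               scorer: Callable[[Sequence], Hashable], seed: int = 0,
               tie_priority: Hashable | None = None) -> GroupVote:
    """Majority vote over fixed-size shuffled groups of one sample's images.

    Items are shuffled by ``seed``, split into groups of ``group_size``
    (the remainder is dropped and recorded), each group is labelled by
    ``scorer``, and the sample label is the modal group label.  A tie is
    broken by ``tie_priority`` when given, else by sorted label order;
    tie breaks are recorded.
    """
    n_groups = len(items) // group_size
    if n_groups < 1:
        raise ValueError("need at least one full group")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(items))
    labels = []
    for g in range(n_groups):
        members = [items[i] for i in order[g * group_size:(g + 1) * group_size]]
        labels.append(scorer(members))
    tally: dict[Hashable, int] = {}
    for lab in labels:
        tally[lab] = tally.get(lab, 0) + 1
    best = max(tally.values())
    winners = sorted((str(k), k) for k, v in tally.items() if v == best)
    tie_broken = len(winners) > 1
    if tie_broken and tie_priority is not None and tie_priority in tally \
            and tally[tie_priority] == best:
        sample_label = tie_priority
    else:
        sample_label = winners[0][1]
    fractions = {k: v / n_groups for k, v in tally.items()}
    return GroupVote(group_size, labels, sample_label, fractions,
                     n_dropped=len(items) - n_groups * group_size,
                     tie_broken=tie_broken)


def make_logistic_group_scorer(weights: Sequence[float], bias: float,
                               labels: tuple[Hashable, Hashable] = ("positive", "negative"),
                               feature_fn: Callable[[Sequence], Sequence[float]] | None = None
                               ) -> Callable[[Sequence], Hashable]:
    """Baseline per-group scorer: logistic score on group-aggregate features.

    ``feature_fn`` maps a group of items to a feature vector (default:
    column means of an (n, d) array of per-image features such as size,
    opacity and granularity); the first label is returned when the
    logistic score exceeds 1/2.
    """
    w = np.asarray(weights, dtype=float)

    def scorer(group: Sequence) -> Hashable:
        if feature_fn is not None:
            feats = np.asarray(feature_fn(group), dtype=float)
        else:
            feats = np.asarray(group, dtype=float).mean(axis=0)
        z = float(w @ feats + bias)
        p = 1.0 / (1.0 + np.exp(-z))
        return labels[0] if p > 0.5 else labels[1]

    return scorer
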