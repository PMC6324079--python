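"""Orthology benchmarking metrics.

Both group-level predictions (OGs) and fine-grained pairwise predictions are
scored with the same pair-based machinery: a grouping induces the set of
unordered protein pairs that co-occur in at least one group, and precision /
recall / F-measure are computed on those pair sets.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

__all__ = ["GroupSet", "copair_set", "fmeasure", "pairwise_pr"]


@dataclass(frozen=True)
class GroupSet:
    """A collection of protein groups over a universe.

    Reference group sets may overlap; predictions from this toolkit are
    disjoint, but nothing here requires that.
    """

    groups: tuple[frozenset[str], ...]
    universe: frozenset[str]

    @classmethod
    def from_iterable(cls, groups: Iterable[Iterable[str]]) -> "GroupSet":
        gs = tuple(frozenset(g) for g in groups)
        uni = frozenset().union(*gs) if gs else frozenset()
        return cls(gs, uni)

    def restricted_to(self, universe: frozenset[str]) -> "GroupSet":
        gs = tuple(g & universe for g in self.groups)
        return GroupSet(tuple(g for g in gs if g), universe)


def copair_set(g: GroupSet) -> set[frozenset[str]]:
    """All unordered pairs co-occurring in at least one group."""
    pairs: set[frozenset[str]] = set()
    for group in g.groups:
        for a, b in combinations(sorted(group), 2):
            pairs.add(frozenset((a, b)))
    return pairs


def _prf(n_common: int, n_pred: int, n_true: int) -> tuple[float, float, float]:
    precision = n_common / n_pred if n_pred else 1.0
    recall = n_common / n_true
    f = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return precision, recall, f


def fmeasure(
    predicted: GroupSet, reference: GroupSet
) -> tuple[float, float, float]:
    """Pair-based (precision, recall, F) of a predicted grouping.

    Predicted proteins outside the reference universe are dropped before
    scoring. An empty prediction has precision 1.0 by convention; a
    reference with no co-pairs is an error.
    """
    ref_pairs = copair_set(reference)
    if not ref_pairs:
        raise ValueError("reference has no co-membership pairs")
    pred_pairs = copair_set(predicted.restricted_to(reference.universe))
    return _prf(len(pred_pairs & ref_pairs), len(pred_pairs), len(ref_pairs))


def pairwise_pr(
    predicted_pairs: set[frozenset[str]], true_pairs: set[frozenset[str]]
) -> tuple[float, float, float]:
    """Set precision / recall / F on unordered pairs; same conventions as
    :func:`fmeasure`."""
    if not true_pairs:
        raise ValueError("empty truth pair set")
    return _prf(
        len(predicted_pairs & true_pairs), len(predicted_pairs), len(true_pairs)
    )
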