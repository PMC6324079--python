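"""Genome / proteome quality control.

Cellular genomes are screened on three assembly-quality rules before entering
orthology inference: completeness against a universe of 40 universal
single-copy marker genes (at most 4 may be missing), contig count (must be
fewer than 300), and assembly N50 (must be at least 10 kb). Viral proteomes
are screened only on proteome size: at least 3 proteins after polyprotein
cleaving. Marker detection and polyprotein cleaving are upstream inputs, not
computed here.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MARKER_UNIVERSE_SIZE",
    "GenomeRecord",
    "QCResult",
    "compute_n50",
    "assess_genome",
    "assess_viral_proteome",
    "assess_many",
]

MARKER_UNIVERSE_SIZE = 40


@dataclass(frozen=True)
class GenomeRecord:
    """Metadata for one genome or viral proteome.

    ``marker_hits`` is the subset of the 40-marker universe detected in the
    proteome; ``n_proteins`` counts proteins after any in-silico polyprotein
    cleaving (relevant to viral records only).
    """

    genome_id: str
    contig_lengths: tuple[int, ...] = ()
    marker_hits: frozenset[str] = frozenset()
    n_proteins: int = 0
    is_viral: bool = False

    def __post_init__(self):
        if any(c <= 0 for c in self.contig_lengths):
            raise ValueError(f"{self.genome_id}: contig lengths must be positive")
        if self.n_proteins < 0:
            raise ValueError(f"{self.genome_id}: n_proteins must be >= 0")
        if not self.is_viral and not self.contig_lengths:
            raise ValueError(f"{self.genome_id}: non-viral genome needs contigs")


@dataclass(frozen=True)
class QCResult:
    genome_id: str
    passed: bool
    failure_reasons: tuple[str, ...] = ()

    def __post_init__(self):
        if self.passed != (len(self.failure_reasons) == 0):
            raise ValueError("passed must be true iff failure_reasons is empty")


def compute_n50(contig_lengths: Sequence[int]) -> int:
    """Assembly N50: the contig length at which the cumulative sum of
    lengths, taken in non-increasing order, first reaches half the total.

    Raises ``ValueError`` on an empty assembly or non-positive lengths.
    """
    lengths = np.asarray(contig_lengths)
    if lengths.size == 0:
        raise ValueError("empty assembly: no contigs")
    if np.any(lengths <= 0):
        raise ValueError("contig lengths must be positive")
    desc = np.sort(lengths)[::-1]
    csum = np.cumsum(desc)
    idx = int(np.searchsorted(csum, csum[-1] / 2.0))
    return int(desc[idx])


def assess_genome(
    g: GenomeRecord,
    marker_universe_size: int = MARKER_UNIVERSE_SIZE,
    max_missing: int = 4,
    max_contigs_exclusive: int = 300,
    min_n50: int = 10_000,
) -> QCResult:
    """Apply the cellular-genome quality filters.

    A genome fails on ``markers`` iff it is missing more than ``max_missing``
    of the marker universe; on ``contigs`` iff it has
    ``max_contigs_exclusive`` contigs or more ("fewer than 300" passes); on
    ``n50`` iff its N50 is below ``min_n50``. Boundaries are inclusive on the
    passing side in each case.
    """
    if g.is_viral:
        raise ValueError(
            f"{g.genome_id} is viral; use assess_viral_proteome instead"
        )
    reasons: list[str] = []
    if (marker_universe_size - len(g.marker_hits)) > max_missing:
        reasons.append("markers")
    if len(g.contig_lengths) >= max_contigs_exclusive:
        reasons.append("contigs")
    if compute_n50(g.contig_lengths) < min_n50:
        reasons.append("n50")
    return QCResult(g.genome_id, passed=not reasons, failure_reasons=tuple(reasons))


def assess_viral_proteome(g: GenomeRecord, min_proteins: int = 3) -> QCResult:
    """Viral proteomes pass iff they retain at least ``min_proteins``
    proteins after polyprotein cleaving."""
    reasons = () if g.n_proteins >= min_proteins else ("viral_size",)
    return QCResult(g.genome_id, passed=not reasons, failure_reasons=reasons)


def assess_many(records: Iterable[GenomeRecord], **kwargs) -> list[QCResult]:
    """Dispatch each record to the appropriate assessor."""
    out = []
    for g in records:
        if g.is_viral:
            out.append(assess_viral_proteome(g))
        else:
            out.append(assess_genome(g, **kwargs))
    return out
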