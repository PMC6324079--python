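"""Similarity-graph structures: best hits, reciprocal best hits, in-paralogs.

The all-vs-all similarity search itself (a Smith–Waterman or BLAST-like
search) is upstream; this module consumes its score table. Scores are
bit-score-like: larger is more similar, zero means absent. All operations are
species-aware and restricted to an explicit species subset so they can be run
independently per taxonomic level.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "ScoreTable",
    "InParalogCluster",
    "normalize_scores",
    "best_hits",
    "reciprocal_best_hits",
    "in_paralog_clusters",
]


class ScoreTable:
    """Symmetric sparse protein-pair similarity table with a species map.

    Build via :func:`normalize_scores`; the constructor assumes entries are
    already canonical (no self pairs, keys sorted, positive scores).
    """

    def __init__(
        self,
        entries: Mapping[tuple[str, str], float],
        species_of: Mapping[str, str],
    ):
        self.entries: dict[tuple[str, str], float] = dict(entries)
        self.species_of: dict[str, str] = dict(species_of)
        for (a, b), s in self.entries.items():
            if a >= b:
                raise ValueError(f"entry key ({a},{b}) not canonical")
            if s <= 0:
                raise ValueError(f"non-positive score for ({a},{b})")
        missing = {p for ab in self.entries for p in ab} - set(self.species_of)
        if missing:
            raise KeyError(f"proteins without species mapping: {sorted(missing)[:5]}")
        self._adj: dict[str, list[tuple[str, float]]] | None = None

    def score(self, a: str, b: str) -> float:
        """Score of the unordered pair, 0.0 if absent."""
        if a == b:
            return 0.0
        key = (a, b) if a < b else (b, a)
        return self.entries.get(key, 0.0)

    def proteins(self) -> set[str]:
        return set(self.species_of)

    def species(self) -> set[str]:
        return set(self.species_of.values())

    @property
    def adjacency(self) -> dict[str, list[tuple[str, float]]]:
        """Protein -> sorted list of (partner, score)."""
        if self._adj is None:
            adj: dict[str, list[tuple[str, float]]] = {p: [] for p in self.species_of}
            for (a, b), s in self.entries.items():
                adj[a].append((b, s))
                adj[b].append((a, s))
            for lst in adj.values():
                lst.sort()
            self._adj = adj
        return self._adj

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ScoreTable)
            and self.entries == other.entries
            and self.species_of == other.species_of
        )


@dataclass(frozen=True)
class InParalogCluster:
    """Maximal set of same-species proteins closer to each other than to any
    protein of another species (within the current species subset)."""

    species: str
    members: frozenset[str]
    anchor: str

    def __post_init__(self):
        if self.anchor not in self.members:
            raise ValueError("anchor must be a member")


def normalize_scores(
    raw_hits: Mapping[tuple[str, str], float],
    species_of: Mapping[str, str],
) -> ScoreTable:
    """Canonicalize a directed hit table.

    Self hits are dropped; for each unordered pair the maximum score over
    both directions (and duplicates) is retained; zero/negative scores are
    treated as absent. Every protein mentioned must have a species mapping.
    """
    entries: dict[tuple[str, str], float] = {}
    for (q, s), score in raw_hits.items():
        if q == s or score <= 0:
            continue
        key = (q, s) if q < s else (s, q)
        prev = entries.get(key)
        if prev is None or score > prev:
            entries[key] = float(score)
    return ScoreTable(entries, species_of)


def _subset_or_all(t: ScoreTable, species_subset: Iterable[str] | None) -> set[str]:
    if species_subset is None:
        return t.species()
    subset = set(species_subset)
    unknown = subset - t.species()
    if unknown:
        raise KeyError(f"species not in table: {sorted(unknown)}")
    return subset


def best_hits(
    t: ScoreTable, species_subset: Iterable[str] | None = None
) -> dict[tuple[str, str], frozenset[str]]:
    """Per-(protein, target-species) best hits, ties retained.

    Returns ``{(protein, target_species): {best-scoring proteins of that
    species}}`` for every protein whose species is in the subset and every
    *other* subset species it has hits against.
    """
    subset = _subset_or_all(t, species_subset)
    out: dict[tuple[str, str], frozenset[str]] = {}
    best: dict[tuple[str, str], tuple[float, set[str]]] = {}
    for (a, b), s in t.entries.items():
        for p, q in ((a, b), (b, a)):
            sp_p, sp_q = t.species_of[p], t.species_of[q]
            if sp_p not in subset or sp_q not in subset or sp_p == sp_q:
                continue
            key = (p, sp_q)
            cur = best.get(key)
            if cur is None or s > cur[0]:
                best[key] = (s, {q})
            elif s == cur[0]:
                cur[1].add(q)
    for key, (_, hits) in best.items():
        out[key] = frozenset(hits)
    return out


def reciprocal_best_hits(
    t: ScoreTable, species_subset: Iterable[str] | None = None
) -> nx.Graph:
    """Undirected best-reciprocal-hit graph.

    Edge (a, b) present iff b is among a's best hits in b's species and vice
    versa; edge attribute ``score`` carries the pair score, node attribute
    ``species`` the species. All subset proteins appear as nodes, including
    isolated ones.
    """
    subset = _subset_or_all(t, species_subset)
    bh = best_hits(t, subset)
    g = nx.Graph()
    for p, sp in t.species_of.items():
        if sp in subset:
            g.add_node(p, species=sp)
    for (p, sp_q), hits in bh.items():
        for q in hits:
            if p < q and p in bh.get((q, t.species_of[p]), frozenset()):
                g.add_edge(p, q, score=t.score(p, q))
    return g


def in_paralog_clusters(
    t: ScoreTable, species_subset: Iterable[str] | None = None
) -> list[InParalogCluster]:
    """Partition each subset species' proteins into in-paralog clusters.

    Two same-species proteins join (transitively) iff their mutual score is
    at least each one's best cross-species score within the subset. Every
    protein gets exactly one cluster; singletons included. The anchor is the
    member with the highest cross-species score (ties: lexicographically
    smallest member).
    """
    subset = _subset_or_all(t, species_subset)
    prots = sorted(p for p, sp in t.species_of.items() if sp in subset)
    max_cross: dict[str, float] = {p: 0.0 for p in prots}
    for (a, b), s in t.entries.items():
        sa, sb = t.species_of[a], t.species_of[b]
        if sa not in subset or sb not in subset or sa == sb:
            continue
        max_cross[a] = max(max_cross[a], s)
        max_cross[b] = max(max_cross[b], s)

    parent = {p: p for p in prots}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (a, b), s in t.entries.items():
        if t.species_of.get(a) != t.species_of.get(b):
            continue
        if t.species_of[a] not in subset:
            continue
        if s >= max_cross[a] and s >= max_cross[b]:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

    groups: dict[str, set[str]] = {}
    for p in prots:
        groups.setdefault(find(p), set()).add(p)
    clusters = []
    for root in sorted(groups):
        members = frozenset(groups[root])
        anchor = min(members, key=lambda m: (-max_cross[m], m))
        clusters.append(
            InParalogCluster(t.species_of[root], members, anchor)
        )
    clusters.sort(key=lambda c: (c.species, min(c.members)))
    return clusters
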