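"""Species-aware triangulation clustering of BRH graphs into orthologous
groups (OGs), independently per taxonomic level.

An OG at a level is a set of three or more homologous proteins that diverge
from the same speciation event. Seeds are found by 3-clique percolation on
the best-reciprocal-hit graph (triangles merged whenever they share an
edge); in-paralog clusters then attach as atomic units to the seed they are
best connected to. Clusters below three members, or spanning fewer than two
species, are left unassigned rather than emitted as OGs.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import networkx as nx

from .simgraph import (
    InParalogCluster,
    ScoreTable,
    in_paralog_clusters,
    reciprocal_best_hits,
)
from .taxonomy import Taxonomy, TaxonomyLevel

__all__ = [
    "OrthologousGroup",
    "find_triangles",
    "cluster_level",
    "build_all_levels",
    "unassigned_proteins",
]


@dataclass(frozen=True)
class OrthologousGroup:
    """A set of >=3 proteins from >=2 species attached to one level."""

    og_id: str
    level: str
    members: frozenset[str]
    n_species: int

    def __post_init__(self):
        if len(self.members) < 3:
            raise ValueError("an OG needs at least 3 members")
        if self.n_species < 2:
            raise ValueError("an OG needs members from at least 2 species")


def find_triangles(g: nx.Graph) -> set[frozenset[str]]:
    """All 3-cliques of the graph.

    On a BRH graph every triangle spans exactly three species, since BRH
    edges only join proteins of different species.
    """
    triangles: set[frozenset[str]] = set()
    for u, v in g.edges():
        common = set(g[u]) & set(g[v])
        for w in common:
            triangles.add(frozenset((u, v, w)))
    return triangles


def _percolate_triangles(
    triangles: Iterable[frozenset[str]],
) -> list[set[str]]:
    """Connected components of the triangle graph where two triangles are
    adjacent iff they share an edge (3-clique percolation); returns the node
    sets of the components."""
    tris = sorted(triangles, key=sorted)
    parent = list(range(len(tris)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    edge_to_tri: dict[frozenset[str], int] = {}
    for i, tri in enumerate(tris):
        for pair in combinations(sorted(tri), 2):
            key = frozenset(pair)
            j = edge_to_tri.setdefault(key, i)
            if j != i:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    comps: dict[int, set[str]] = {}
    for i, tri in enumerate(tris):
        comps.setdefault(find(i), set()).update(tri)
    return [comps[r] for r in sorted(comps, key=lambda r: min(comps[r]))]


def cluster_level(
    g: nx.Graph,
    level: TaxonomyLevel,
    inpar: list[InParalogCluster],
) -> list[OrthologousGroup]:
    """Cluster one level's BRH graph into orthologous groups.

    Seeds are the 3-clique-percolation components of ``g``. Each in-paralog
    cluster (singletons included) then attaches, as a unit, to the seed
    reached by its highest-scoring supporting BRH edge (tie: smallest seed
    id); clusters with no BRH edge into any seed stay unattached. Final
    clusters with fewer than three members or fewer than two species are
    not emitted.
    """
    seeds = _percolate_triangles(find_triangles(g))
    seed_id = {i: min(members) for i, members in enumerate(seeds)}
    assign: dict[str, int] = {}
    for i, members in enumerate(seeds):
        for p in members:
            assign[p] = i

    final = dict(assign)
    for clu in sorted(inpar, key=lambda c: (c.species, min(c.members))):
        best: tuple[float, str, int] | None = None  # (score, seed_id, seed_idx)
        for m in sorted(clu.members):
            if m not in g:
                continue
            for v, attrs in sorted(g[m].items()):
                if v in clu.members or v not in assign:
                    continue
                i = assign[v]
                cand = (attrs["score"], seed_id[i], i)
                if best is None or cand[0] > best[0] or (
                    cand[0] == best[0] and cand[1] < best[1]
                ):
                    best = cand
        if best is not None:
            for m in clu.members:
                final[m] = best[2]

    groups: dict[int, set[str]] = {}
    for p, i in final.items():
        groups.setdefault(i, set()).add(p)

    species_of = nx.get_node_attributes(g, "species")
    for clu in inpar:
        for m in clu.members:
            species_of.setdefault(m, clu.species)

    ogs = []
    for members in groups.values():
        if len(members) < 3:
            continue
        n_sp = len({species_of[m] for m in members})
        if n_sp < 2:
            continue
        og_id = f"{level.level_id}.{min(members)}"
        ogs.append(OrthologousGroup(og_id, level.level_id, frozenset(members), n_sp))
    ogs.sort(key=lambda o: o.og_id)
    return ogs


def unassigned_proteins(
    t: ScoreTable, level: TaxonomyLevel, ogs: list[OrthologousGroup]
) -> set[str]:
    """Level proteins (present in the score table) not in any emitted OG."""
    in_ogs = set().union(*(o.members for o in ogs)) if ogs else set()
    return {
        p for p, sp in t.species_of.items() if sp in level.species
    } - in_ogs


def build_all_levels(
    t: ScoreTable, taxonomy: Taxonomy
) -> dict[str, list[OrthologousGroup]]:
    """Run BRH + in-paralog + triangulation clustering at every level.

    Levels with fewer than two species are skipped with a warning (no
    speciation event is definable there). OG identifiers embed the level id
    and the lexicographically smallest member, so they are unique across
    levels and stable under input reordering.
    """
    out: dict[str, list[OrthologousGroup]] = {}
    for level in taxonomy.iter_top_down():
        if len(level.species) < 2:
            warnings.warn(
                f"level {level.level_id} has <2 species; skipped", stacklevel=2
            )
            continue
        subset = level.species & t.species()
        if len(subset) < 2:
            out[level.level_id] = []
            continue
        g = reciprocal_best_hits(t, subset)
        inpar = in_paralog_clusters(t, subset)
        out[level.level_id] = cluster_level(g, level, inpar)
    return out
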