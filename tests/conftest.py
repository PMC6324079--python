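"""Shared fixtures and independent brute-force oracles.

The oracles reimplement each graph/clustering operation in the most naive
way possible (explicit loops, repeated passes) so that the package's
optimized implementations can be checked against them on random instances.
They deliberately share no code with the package beyond basic containers.
"""
from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from ogforge.simgraph import InParalogCluster, ScoreTable


# ---------------------------------------------------------------------------
# random instance generators
# ---------------------------------------------------------------------------

def random_score_table(
    rng: np.random.Generator,
    n_species: int = 4,
    max_per_species: int = 6,
    density: float = 0.4,
    integer_scores: bool = True,
) -> ScoreTable:
    """Random sparse symmetric score table; integer scores force ties."""
    species_of: dict[str, str] = {}
    for s in range(n_species):
        for i in range(int(rng.integers(1, max_per_species + 1))):
            species_of[f"p{s}x{i}"] = f"sp{s}"
    prots = sorted(species_of)
    entries: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(prots, 2):
        if rng.random() < density:
            score = float(rng.integers(1, 20)) if integer_scores else float(
                rng.uniform(0.5, 20)
            )
            entries[(a, b)] = score
    return ScoreTable(entries, species_of)


# ---------------------------------------------------------------------------
# simgraph oracles
# ---------------------------------------------------------------------------

def brute_normalize(raw: dict, species_of: dict) -> dict:
    out: dict[tuple[str, str], float] = {}
    for (q, s), score in raw.items():
        if q == s or score <= 0:
            continue
        key = tuple(sorted((q, s)))
        out[key] = max(out.get(key, 0.0), float(score))
    return out


def brute_best_hits(t: ScoreTable, subset: set[str]) -> dict:
    prots = [p for p, sp in t.species_of.items() if sp in subset]
    out = {}
    for p in prots:
        for target in subset:
            if target == t.species_of[p]:
                continue
            cands = [
                (q, t.score(p, q))
                for q in prots
                if t.species_of[q] == target and t.score(p, q) > 0
            ]
            if not cands:
                continue
            m = max(s for _, s in cands)
            out[(p, target)] = frozenset(q for q, s in cands if s == m)
    return out


def brute_rbh_edges(t: ScoreTable, subset: set[str]) -> set[frozenset[str]]:
    bh = brute_best_hits(t, subset)
    edges = set()
    for (p, target), hits in bh.items():
        for q in hits:
            back = bh.get((q, t.species_of[p]), frozenset())
            if p in back:
                edges.add(frozenset((p, q)))
    return edges


def brute_inparalog_sets(t: ScoreTable, subset: set[str]) -> set[frozenset[str]]:
    prots = sorted(p for p, sp in t.species_of.items() if sp in subset)
    maxcross = {}
    for p in prots:
        cross = [
            t.score(p, q)
            for q in prots
            if t.species_of[q] != t.species_of[p] and t.score(p, q) > 0
        ]
        maxcross[p] = max(cross, default=0.0)
    clusters = [{p} for p in prots]
    changed = True
    while changed:
        changed = False
        for i, j in itertools.combinations(range(len(clusters)), 2):
            if not clusters[i] or not clusters[j]:
                continue
            joined = False
            for a in clusters[i]:
                for b in clusters[j]:
                    if (
                        t.species_of[a] == t.species_of[b]
                        and t.score(a, b) > 0
                        and t.score(a, b) >= maxcross[a]
                        and t.score(a, b) >= maxcross[b]
                    ):
                        joined = True
            if joined:
                clusters[i] |= clusters[j]
                clusters[j] = set()
                changed = True
    return {frozenset(c) for c in clusters if c}


# ---------------------------------------------------------------------------
# clustering oracle
# ---------------------------------------------------------------------------

def brute_triangles(g: nx.Graph) -> set[frozenset[str]]:
    return {
        frozenset(tri)
        for tri in itertools.combinations(sorted(g.nodes), 3)
        if g.has_edge(tri[0], tri[1])
        and g.has_edge(tri[0], tri[2])
        and g.has_edge(tri[1], tri[2])
    }


def brute_cluster_sets(
    g: nx.Graph, inpar: list[InParalogCluster]
) -> set[frozenset[str]]:
    """3-clique percolation + atomic in-paralog attachment, via an explicit
    triangle-adjacency graph and exhaustive candidate scans."""
    tris = sorted(brute_triangles(g), key=sorted)
    tg = nx.Graph()
    tg.add_nodes_from(range(len(tris)))
    for i, j in itertools.combinations(range(len(tris)), 2):
        if len(tris[i] & tris[j]) == 2:
            tg.add_edge(i, j)
    seeds = []
    for comp in nx.connected_components(tg):
        members = set()
        for i in comp:
            members |= tris[i]
        seeds.append(members)
    seeds.sort(key=min)
    assign = {}
    for k, members in enumerate(seeds):
        for p in members:
            assign[p] = k

    final = dict(assign)
    for clu in sorted(inpar, key=lambda c: (c.species, min(c.members))):
        cands = []
        for m in sorted(clu.members):
            if m not in g:
                continue
            for v in sorted(g[m]):
                if v in clu.members or v not in assign:
                    continue
                cands.append((-g[m][v]["score"], min(seeds[assign[v]]), assign[v]))
        if cands:
            _, _, k = min(cands)
            for m in clu.members:
                final[m] = k

    out: dict[int, set[str]] = {}
    for p, k in final.items():
        out.setdefault(k, set()).add(p)
    species = nx.get_node_attributes(g, "species")
    for clu in inpar:
        for m in clu.members:
            species.setdefault(m, clu.species)
    return {
        frozenset(c)
        for c in out.values()
        if len(c) >= 3 and len({species[p] for p in c}) >= 2
    }


# ---------------------------------------------------------------------------
# reconciliation oracle (LCA mapping)
# ---------------------------------------------------------------------------

def lca_reconciliation_events(gene_tree, species_tree) -> dict[int, str]:
    """Duplication/speciation labels by classic LCA-mapping reconciliation:
    a node is a duplication iff it maps to the same species-tree node as at
    least one of its children. Returns labels keyed by id(node)."""

    def mapping(node):
        species = sorted({next(iter(t.species_set)) for t in ([node] if node.is_tip() else node.tips())})
        if len(species) == 1:
            return species_tree.find(species[0])
        return species_tree.lca(species)

    labels = {}
    for node in gene_tree.non_tips(include_self=True):
        m = mapping(node)
        dup = any(mapping(c) is m for c in node.children)
        labels[id(node)] = "duplication" if dup else "speciation"
    return labels


# ---------------------------------------------------------------------------
# bench oracle
# ---------------------------------------------------------------------------

def brute_copairs(groups) -> set[frozenset[str]]:
    pairs = set()
    for g in groups:
        for a in g:
            for b in g:
                if a != b:
                    pairs.add(frozenset((a, b)))
    return pairs


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def clean_dataset():
    """Clean-regime dataset: no duplication, no loss, noise-free scores."""
    from ogforge.simulate import SimulationConfig, simulate_dataset

    return simulate_dataset(SimulationConfig(seed=11, n_species=6, n_families=10))


@pytest.fixture(scope="session")
def noisy_dataset():
    from ogforge.simulate import SimulationConfig, simulate_dataset

    return simulate_dataset(
        SimulationConfig(
            seed=12, n_species=6, n_families=10, dup_rate=0.3, loss_rate=0.1,
            score_noise_sd=5.0,
        )
    )
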