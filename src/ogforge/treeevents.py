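"""Gene-tree analysis: alignment trimming, fallback tree building, rooting,
speciation/duplication labeling by species overlap, and typed pairwise
orthology extraction.

The species-overlap rule labels an internal node of a rooted gene tree a
*duplication* iff the species sets of at least two of its children
intersect, and a *speciation* otherwise. Ortholog pairs are leaf pairs from
different species whose most recent common ancestor is a speciation node;
their relation type (one-to-one / one-to-many / many-to-many) counts the
in-paralogs of each partner's species on each side of that ancestor.

Production-grade alignment and maximum-likelihood tree inference are
upstream inputs; the only built-in estimator is neighbor joining, intended
for small within-OG trees derived from similarity scores.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

__all__ = [
    "GAP_CHARS",
    "Alignment",
    "OrthologPair",
    "trim_alignment",
    "nj_tree",
    "root_tree",
    "label_events",
    "count_duplications",
    "pairwise_orthologs",
    "species_map_from_leaf_names",
]

GAP_CHARS = "-."

SPECIATION = "speciation"
DUPLICATION = "duplication"


@dataclass(frozen=True)
class Alignment:
    """A protein multiple sequence alignment (ids in fixed order, equal-length
    gapped rows)."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in count")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        if self.rows and len({len(r) for r in self.rows}) > 1:
            raise ValueError("ragged alignment: rows differ in length")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def from_records(cls, records: Sequence[tuple[str, str]]) -> "Alignment":
        return cls(tuple(r[0] for r in records), tuple(r[1] for r in records))

    def items(self):
        return zip(self.ids, self.rows)


def trim_alignment(a: Alignment, min_residues: int = 5) -> Alignment:
    """Soft trimming: drop columns with fewer than ``min_residues`` non-gap
    characters; row and column order otherwise preserved. Idempotent."""
    if not a.rows:
        return a
    mat = np.array([list(r) for r in a.rows])
    residues = ~np.isin(mat, list(GAP_CHARS))
    keep = residues.sum(axis=0) >= min_residues
    trimmed = ["".join(row) for row in mat[:, keep]]
    return Alignment(a.ids, tuple(trimmed))


@dataclass(frozen=True)
class OrthologPair:
    """An ortholog pair with its relation type.

    ``relation`` is one of one-to-one / one-to-many / many-to-one /
    many-to-many, oriented so that the count on ``protein_a``'s side comes
    first; pairs are canonicalized with ``protein_a < protein_b``.
    """

    protein_a: str
    protein_b: str
    relation: str


def species_map_from_leaf_names(
    tree: TreeNode, sep: str = "_"
) -> dict[str, str]:
    """Opt-in leaf-name convention ``proteinID<sep>speciesID`` (species is
    the suffix after the last separator)."""
    out = {}
    for tip in tree.tips():
        if sep not in tip.name:
            raise ValueError(f"leaf {tip.name!r} lacks separator {sep!r}")
        out[tip.name] = tip.name.rsplit(sep, 1)[1]
    return out


def nj_tree(dm: DistanceMatrix | tuple[np.ndarray, Sequence[str]]) -> TreeNode:
    """Neighbor-joining tree from a symmetric distance matrix.

    Taxa are canonicalized to lexicographic order first, so the result is
    independent of input ordering. Requires at least three taxa.
    """
    if not isinstance(dm, DistanceMatrix):
        data, ids = dm
        dm = DistanceMatrix(data, list(ids))
    if dm.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    order = sorted(dm.ids)
    dm = dm.filter(order)
    return _skbio_nj(dm)


def _resolve_species(
    tree: TreeNode,
    species_of: Mapping[str, str] | Callable[[str], str] | None,
    sep: str = "_",
) -> dict[str, str]:
    if species_of is None:
        return species_map_from_leaf_names(tree, sep)
    tips = [tree] if tree.is_tip() else list(tree.tips())
    if callable(species_of):
        return {tip.name: species_of(tip.name) for tip in tips}
    return {tip.name: species_of[tip.name] for tip in tips}


def label_events(
    t: TreeNode,
    species_of: Mapping[str, str] | Callable[[str], str] | None = None,
    sep: str = "_",
) -> TreeNode:
    """Annotate a rooted gene tree with species sets and events in place.

    Every node gets ``species_set`` (union of descendant leaf species); every
    internal node gets ``event`` (duplication iff any two children's species
    sets intersect, else speciation — multifurcations use pairwise
    intersection). Returns the same tree object.
    """
    spmap = _resolve_species(t, species_of, sep)
    for node in t.postorder(include_self=True):
        if node.is_tip():
            node.species_set = frozenset([spmap[node.name]])
            node.event = None
            continue
        sets = [c.species_set for c in node.children]
        node.species_set = frozenset().union(*sets)
        dup = any(
            s1 & s2 for s1, s2 in combinations(sets, 2)
        )
        node.event = DUPLICATION if dup else SPECIATION
    return t


def count_duplications(t: TreeNode) -> int:
    """Number of duplication-labeled internal nodes (labels if needed is the
    caller's job; raises on unlabeled nodes)."""
    n = 0
    for node in t.non_tips(include_self=True):
        ev = getattr(node, "event", None)
        if ev is None:
            raise ValueError("tree is not event-labeled")
        n += ev == DUPLICATION
    return n


def _bipartition_key(node: TreeNode, all_tips: frozenset[str]) -> tuple:
    below = frozenset(t.name for t in node.tips()) if not node.is_tip() else frozenset([node.name])
    other = all_tips - below
    return min(tuple(sorted(below)), tuple(sorted(other)))


def root_tree(
    t: TreeNode,
    mode: str = "min_dup",
    species_of: Mapping[str, str] | Callable[[str], str] | None = None,
    sep: str = "_",
) -> TreeNode:
    """Root an unrooted gene tree.

    ``min_dup`` places the root on the edge minimizing the number of
    duplication nodes under species-overlap labeling (ties: smaller maximum
    root-to-leaf depth, then lexicographically smallest bipartition);
    ``midpoint`` is standard midpoint rooting. The returned tree is labeled
    (``min_dup``) or unlabeled (``midpoint``).
    """
    if mode == "midpoint":
        return t.root_at_midpoint(inplace=False)
    if mode != "min_dup":
        raise ValueError(f"unknown rooting mode {mode!r}")

    all_tips = frozenset(tip.name for tip in t.tips())
    spmap = _resolve_species(t, species_of, sep)
    best = None
    best_key = None
    work = t.copy()
    candidates = [n for n in work.traverse(include_self=False)]
    for node in candidates:
        if node.length is None:
            node.length = 1.0
        rooted = work.root_at(node, above=True, reset=True)
        label_events(rooted, spmap)
        dups = count_duplications(rooted)
        depth = max(
            len(list(tip.ancestors())) for tip in rooted.tips()
        )
        key = (dups, depth, _bipartition_key(node, all_tips))
        if best_key is None or key < best_key:
            best_key = key
            best = rooted
    assert best is not None
    return best


def _mrca(t: TreeNode, names: Sequence[str]) -> TreeNode:
    return t.lca(list(names)) if len(names) > 1 else t.find(names[0])


def pairwise_orthologs(t: TreeNode) -> list[OrthologPair]:
    """Typed ortholog pairs from an event-labeled rooted gene tree.

    For each speciation node and each pair of its child subtrees, every
    cross-subtree leaf pair of different species is an ortholog pair; the
    relation counts, within each of the two subtrees, the leaves belonging
    to that pair's own species (1 vs 1 -> one-to-one, 1 vs k -> one-to-many,
    k vs m -> many-to-many). Leaf pairs whose MRCA is a duplication are
    paralogs and are not emitted.
    """
    for node in t.non_tips(include_self=True):
        if getattr(node, "event", None) is None:
            raise ValueError("tree is not event-labeled; run label_events first")

    pairs: list[OrthologPair] = []
    for node in t.non_tips(include_self=True):
        if node.event != SPECIATION:
            continue
        child_leaves = []
        for c in node.children:
            leaves = [c] if c.is_tip() else list(c.tips())
            by_species: dict[str, list[str]] = {}
            for lf in leaves:
                sp = next(iter(lf.species_set))
                by_species.setdefault(sp, []).append(lf.name)
            child_leaves.append(by_species)
        for bs1, bs2 in combinations(child_leaves, 2):
            for sp1, names1 in bs1.items():
                for sp2, names2 in bs2.items():
                    if sp1 == sp2:
                        continue
                    n1, n2 = len(names1), len(names2)
                    for x in names1:
                        for y in names2:
                            a, b, ca, cb = (
                                (x, y, n1, n2) if x < y else (y, x, n2, n1)
                            )
                            if ca == 1 and cb == 1:
                                rel = "one-to-one"
                            elif ca == 1:
                                rel = "one-to-many"
                            elif cb == 1:
                                rel = "many-to-one"
                            else:
                                rel = "many-to-many"
                            pairs.append(OrthologPair(a, b, rel))
    pairs.sort(key=lambda p: (p.protein_a, p.protein_b))
    return pairs
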