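"""Species taxonomy: the tree of taxonomic levels at which orthologous groups
are computed.

A *taxonomic level* is an internal node of the species tree. Each level owns
the set of species in its clade; levels are strictly nested, and orthologous
groups are inferred independently per level and later reconciled for
hierarchical consistency.
"""
from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

from skbio import TreeNode

__all__ = ["TaxonomyLevel", "Taxonomy"]


@dataclass(frozen=True)
class TaxonomyLevel:
    """One taxonomic level: an internal node of the species tree.

    Parameters
    ----------
    level_id : str
        Unique identifier (internal node label).
    parent : str or None
        Identifier of the enclosing level; ``None`` for the root.
    species : frozenset of str
        Species identifiers of the clade below this node.
    """

    level_id: str
    parent: str | None
    species: frozenset[str]


class Taxonomy:
    """The nested set of taxonomic levels defined by a species tree.

    Internal nodes must carry unique labels; leaves are species. Levels with
    a single species are not levels (no speciation event below them), so the
    minimal taxonomy is a single root over two species.
    """

    def __init__(self, levels: dict[str, TaxonomyLevel], root_id: str):
        self.levels = levels
        self.root_id = root_id
        self._children: dict[str, list[str]] = {lid: [] for lid in levels}
        for lvl in levels.values():
            if lvl.parent is not None:
                self._children[lvl.parent].append(lvl.level_id)
        for kids in self._children.values():
            kids.sort()
        self._validate()

    def _validate(self) -> None:
        root = self.levels[self.root_id]
        if root.parent is not None:
            raise ValueError("root level must have no parent")
        for lvl in self.levels.values():
            if lvl.parent is not None:
                parent = self.levels[lvl.parent]
                if not lvl.species < parent.species:
                    raise ValueError(
                        f"level {lvl.level_id} species set is not a proper "
                        f"subset of its parent {lvl.parent}"
                    )

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_tree(cls, tree: TreeNode) -> "Taxonomy":
        """Build from a species tree whose internal nodes are labeled."""
        levels: dict[str, TaxonomyLevel] = {}
        root_id = None
        for node in tree.traverse(include_self=True):
            if node.is_tip():
                continue
            if not node.name:
                raise ValueError("every internal node needs a label")
            species = frozenset(t.name for t in node.tips())
            parent = None
            if node.parent is not None:
                parent = node.parent.name
            if parent is None:
                root_id = node.name
            if node.name in levels:
                raise ValueError(f"duplicate level id {node.name!r}")
            levels[node.name] = TaxonomyLevel(node.name, parent, species)
        if root_id is None:
            raise ValueError("tree has no internal node")
        return cls(levels, root_id)

    @classmethod
    def from_newick(cls, source: str | Path) -> "Taxonomy":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        tree = TreeNode.read(_io.StringIO(text))
        return cls.from_tree(tree)

    @classmethod
    def from_edges(cls, edges: list[tuple[str, str | None]]) -> "Taxonomy":
        """Build from (child_id, parent_id) rows.

        Identifiers that never appear as a parent are species; the rest are
        levels. Exactly one row must have a ``None`` parent (the root).
        """
        parents = {child: parent for child, parent in edges}
        parent_ids = {p for p in parents.values() if p is not None}
        species_ids = [c for c in parents if c not in parent_ids]
        level_ids = [c for c in parents if c in parent_ids]
        roots = [c for c, p in parents.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {roots}")

        kids: dict[str, list[str]] = {}
        for child, parent in parents.items():
            if parent is not None:
                kids.setdefault(parent, []).append(child)

        species_below: dict[str, frozenset[str]] = {}

        def collect(node: str) -> frozenset[str]:
            if node in species_below:
                return species_below[node]
            if node in kids:
                out = frozenset().union(*(collect(k) for k in kids[node]))
            else:
                out = frozenset([node])
            species_below[node] = out
            return out

        collect(roots[0])
        levels = {
            lid: TaxonomyLevel(lid, parents[lid], species_below[lid])
            for lid in level_ids
        }
        for sid in species_ids:
            if sid in levels:
                raise ValueError(f"id {sid!r} used as both species and level")
        return cls(levels, roots[0])

    # -- queries -----------------------------------------------------------
    def __contains__(self, level_id: str) -> bool:
        return level_id in self.levels

    def __getitem__(self, level_id: str) -> TaxonomyLevel:
        return self.levels[level_id]

    @property
    def root(self) -> TaxonomyLevel:
        return self.levels[self.root_id]

    @property
    def species(self) -> frozenset[str]:
        return self.root.species

    def children_of(self, level_id: str) -> list[str]:
        return list(self._children[level_id])

    def parent_of(self, level_id: str) -> str | None:
        return self.levels[level_id].parent

    def iter_top_down(self) -> Iterator[TaxonomyLevel]:
        """Yield levels root-first (preorder, children in sorted order)."""
        stack = [self.root_id]
        while stack:
            lid = stack.pop()
            yield self.levels[lid]
            stack.extend(reversed(self._children[lid]))

    def junctions(self) -> Iterator[tuple[str, str]]:
        """Yield (parent_level_id, child_level_id) pairs, top-down."""
        for lvl in self.iter_top_down():
            for kid in self._children[lvl.level_id]:
                yield lvl.level_id, kid

    def clade_contains(self, level_id: str, species_set: frozenset[str]) -> bool:
        """True iff the species-tree LCA of ``species_set`` lies at or below
        the node of ``level_id`` (i.e. the set is within the level's clade)."""
        return species_set <= self.levels[level_id].species

    def to_edges(self) -> list[tuple[str, str | None]]:
        rows: list[tuple[str, str | None]] = []
        for lvl in sorted(self.levels.values(), key=lambda l: l.level_id):
            rows.append((lvl.level_id, lvl.parent))
        leaf_parent: dict[str, str] = {}
        for lvl in self.levels.values():
            direct = set(lvl.species)
            for kid in self._children[lvl.level_id]:
                direct -= self.levels[kid].species
            for sp in direct:
                leaf_parent[sp] = lvl.level_id
        for sp in sorted(leaf_parent):
            rows.append((sp, leaf_parent[sp]))
        return rows
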