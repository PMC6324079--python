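"""Synthetic data generation: species trees, duplication/loss gene families,
similarity scores, and planted hierarchical conflicts.

The generator instantiates the orthologous-group definition literally: genes
evolve from one ancestral copy down an ultrametric species tree, duplicating
as a Poisson process along branches and disappearing by Poisson loss, so the
true OG at a taxonomic level is exactly the set of extant genes descending
from one gene lineage present at that level's ancestral species node.

Sequence evolution is not simulated. Similarity scores are derived directly
from patristic distances (``S0 * exp(-d)`` plus optional Gaussian noise),
with sparse uniform background scores between families; the pipeline
consumes scores, and this keeps the noise model explicit. A toy sequence
emitter exists only to exercise FASTA round-trips.

Event labels exported by the generator are *observable* labels: after
losses, a duplication whose surviving copies occupy disjoint species sets is
indistinguishable from a speciation in the extant tree, and is exported as
one.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from skbio import TreeNode

from .cluster import OrthologousGroup
from .simgraph import ScoreTable
from .taxonomy import Taxonomy
from .treeevents import label_events, pairwise_orthologs

__all__ = [
    "SimulationConfig",
    "FamilyTruth",
    "GroundTruth",
    "PlantedConflict",
    "simulate_species_tree",
    "simulate_gene_family",
    "simulate_scores",
    "simulate_dataset",
    "plant_conflict",
    "simulate_sequences",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults are the clean regime: 8 species, 50 families, no duplication,
    no loss, noise-free scores. Scores follow ``s0 * exp(-d)`` within a
    family; cross-family background pairs appear with probability
    ``background_p`` and scores uniform on ``(0, background_max)``.
    """

    seed: int
    n_species: int = 8
    n_families: int = 50
    dup_rate: float = 0.0
    loss_rate: float = 0.0
    score_noise_sd: float = 0.0
    s0: float = 100.0
    background_p: float = 0.05
    background_max: float = 5.0

    def __post_init__(self):
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if min(self.dup_rate, self.loss_rate, self.score_noise_sd) < 0:
            raise ValueError("rates and noise must be non-negative")
        if not all(
            math.isfinite(x) for x in (self.dup_rate, self.loss_rate, self.score_noise_sd)
        ):
            raise ValueError("rates must be finite")


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

def simulate_species_tree(
    n_species: int, seed: int | np.random.Generator
) -> tuple[TreeNode, Taxonomy]:
    """Random ultrametric species tree with named internal nodes.

    The topology is uniform over labeled rooted binary topologies (stepwise
    addition: each new species attaches to one of the 2n-1 possible
    positions with equal probability). Depth is normalized to 1; internal
    node times are drawn recursively between parent time and the present.
    Internal nodes are named ``L0`` (root), ``L1``, ... in preorder and
    become the taxonomic levels.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = [f"s{i:02d}" for i in range(n_species)]

    root = TreeNode()
    root.extend([TreeNode(name=names[0]), TreeNode(name=names[1])])
    for name in names[2:]:
        positions = list(root.traverse(include_self=False))
        k = int(rng.integers(0, len(positions) + 1))
        leaf = TreeNode(name=name)
        if k == len(positions):  # new root above the old one
            new_root = TreeNode()
            new_root.extend([root, leaf])
            root = new_root
        else:
            target = positions[k]
            parent = target.parent
            parent.remove(target)
            mid = TreeNode()
            mid.extend([target, leaf])
            parent.append(mid)

    # times: root at 0, tips at 1, internal times recursive
    root.time = 0.0
    for node in root.preorder(include_self=False):
        if node.is_tip():
            node.time = 1.0
        else:
            u = float(rng.uniform(0.1, 0.9))
            node.time = node.parent.time + u * (1.0 - node.parent.time)
        node.length = node.time - node.parent.time
    idx = 0
    for node in root.preorder(include_self=True):
        if not node.is_tip():
            node.name = f"L{idx}"
            idx += 1
    return root, Taxonomy.from_tree(root)


# ---------------------------------------------------------------------------
# gene families
# ---------------------------------------------------------------------------

@dataclass
class FamilyTruth:
    """One simulated gene family: pruned extant gene tree with observable
    event labels, the gene->species map, and the redraw count."""

    family_id: str
    tree: TreeNode
    species_of: dict[str, str]
    n_redraws: int = 0

    @property
    def proteins(self) -> list[str]:
        return sorted(self.species_of)


def _evolve_branch(
    sp_node: TreeNode,
    t: float,
    rng: np.random.Generator,
    dup_rate: float,
    loss_rate: float,
    family_id: str,
    counters: dict[str, int],
) -> TreeNode | None:
    """Evolve one gene copy alive at time ``t`` on the branch leading to
    ``sp_node``; returns the extant subtree (unary nodes suppressed inline)
    or ``None`` if the lineage leaves no extant descendant."""
    total = dup_rate + loss_rate
    t_end = sp_node.time
    while True:
        wait = rng.exponential(1.0 / total) if total > 0 else math.inf
        if t + wait < t_end:
            t += wait
            if rng.random() < dup_rate / total:  # duplication
                kids = [
                    _evolve_branch(sp_node, t, rng, dup_rate, loss_rate, family_id, counters)
                    for _ in range(2)
                ]
                kids = [k for k in kids if k is not None]
                if not kids:
                    return None
                if len(kids) == 1:
                    return kids[0]
                node = TreeNode()
                node.time = t
                node.raw_event = "duplication"
                node.extend(kids)
                return node
            return None  # loss
        break
    if sp_node.is_tip():
        sp = sp_node.name
        counters[sp] = counters.get(sp, 0) + 1
        leaf = TreeNode(name=f"{family_id}.{sp}.g{counters[sp]}")
        leaf.time = t_end
        leaf.species = sp
        return leaf
    kids = [
        _evolve_branch(c, t_end, rng, dup_rate, loss_rate, family_id, counters)
        for c in sp_node.children
    ]
    kids = [k for k in kids if k is not None]
    if not kids:
        return None
    if len(kids) == 1:
        return kids[0]
    node = TreeNode()
    node.time = t_end
    node.raw_event = "speciation"
    node.species_node = sp_node.name
    node.extend(kids)
    return node


def _finalize_family(tree: TreeNode) -> dict[str, str]:
    """Set branch lengths from times and observable event labels; return the
    gene->species map."""
    species_of: dict[str, str] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            node.species_set = frozenset([node.species])
            node.event = None
            species_of[node.name] = node.species
            continue
        sets = [c.species_set for c in node.children]
        node.species_set = frozenset().union(*sets)
        overlap = any(a & b for a, b in combinations(sets, 2))
        if node.raw_event == "duplication":
            node.event = "duplication" if overlap else "speciation"
        else:
            node.event = "speciation"
    for node in tree.preorder(include_self=False):
        node.length = node.time - node.parent.time
    tree.length = None
    return species_of


def simulate_gene_family(
    species_tree: TreeNode,
    dup_rate: float,
    loss_rate: float,
    seed: int | np.random.Generator,
    family_id: str = "F0",
) -> FamilyTruth:
    """Birth–death evolution of one gene family along the species tree.

    One ancestral copy enters at the root; duplications arise at
    ``dup_rate`` and losses at ``loss_rate`` per unit branch length. A
    family extinct in all species is re-drawn (count reported in
    ``n_redraws``). Losses are pruned inline, so the returned tree is the
    extant (observable) gene tree.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_redraws = 0
    while True:
        counters: dict[str, int] = {}
        kids = [
            _evolve_branch(c, species_tree.time, rng, dup_rate, loss_rate, family_id, counters)
            for c in species_tree.children
        ]
        kids = [k for k in kids if k is not None]
        if kids:
            break
        n_redraws += 1
    if len(kids) == 1:
        tree = kids[0]
    else:
        tree = TreeNode()
        tree.time = species_tree.time
        tree.raw_event = "speciation"
        tree.species_node = species_tree.name
        tree.extend(kids)
    species_of = _finalize_family(tree)
    return FamilyTruth(family_id, tree, species_of, n_redraws)


# ---------------------------------------------------------------------------
# ground truth container
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    species_tree: TreeNode
    taxonomy: Taxonomy
    families: list[FamilyTruth]
    config: SimulationConfig | None = None
    species_of: dict[str, str] = field(default_factory=dict)
    family_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.species_of:
            for fam in self.families:
                self.species_of.update(fam.species_of)
                for p in fam.species_of:
                    self.family_of[p] = fam.family_id
        self._by_id = {f.family_id: f for f in self.families}
        self._level_time = {
            lvl.level_id: self.species_tree.find(lvl.level_id).time
            for lvl in self.taxonomy.levels.values()
        }

    def true_ogs(self, level_id: str) -> list[frozenset[str]]:
        """True OGs at a level: leaves of the level's species clade grouped
        by gene lineage present at the level's ancestral node (gene-tree
        divergence time at or after the node's time)."""
        t_level = self._level_time[level_id]
        clade = self.taxonomy[level_id].species
        out: list[frozenset[str]] = []
        for fam in self.families:
            stack = [fam.tree]
            while stack:
                node = stack.pop()
                if node.time >= t_level:
                    tips = [node] if node.is_tip() else list(node.tips())
                    og = frozenset(t.name for t in tips if t.species in clade)
                    if og:
                        out.append(og)
                else:  # diverged before the level: descend into each lineage
                    stack.extend(node.children)
        out.sort(key=min)
        return out

    def true_og_map(self, min_members: int = 3) -> dict[str, list[OrthologousGroup]]:
        """True OGs as :class:`OrthologousGroup` objects (valid OGs only:
        >=3 members, >=2 species)."""
        out: dict[str, list[OrthologousGroup]] = {}
        for lvl in self.taxonomy.iter_top_down():
            ogs = []
            for members in self.true_ogs(lvl.level_id):
                n_sp = len({self.species_of[p] for p in members})
                if len(members) >= min_members and n_sp >= 2:
                    ogs.append(
                        OrthologousGroup(
                            f"{lvl.level_id}.{min(members)}", lvl.level_id, members, n_sp
                        )
                    )
            out[lvl.level_id] = sorted(ogs, key=lambda o: o.og_id)
        return out

    def true_pairs(self) -> dict[frozenset[str], str]:
        """True ortholog pairs (unordered) -> relation type, from the true
        labeled trees."""
        pairs: dict[frozenset[str], str] = {}
        for fam in self.families:
            if len(fam.species_of) < 2:
                continue
            for p in pairwise_orthologs(fam.tree):
                pairs[frozenset((p.protein_a, p.protein_b))] = p.relation
        return pairs

    def gene_tree_for(
        self, proteins: Iterable[str]
    ) -> tuple[TreeNode, dict[str, str]]:
        """Rooted, event-labeled true gene tree covering a protein set.

        Proteins of one family give the sheared family tree; proteins of
        several families are joined under an artificial ancient root (long
        branches), since the families share no common ancestor within the
        simulation.
        """
        prots = sorted(set(proteins))
        fams = sorted({self.family_of[p] for p in prots})
        subtrees = []
        for fid in fams:
            fam = self._by_id[fid]
            names = [p for p in prots if self.family_of[p] == fid]
            if len(names) == 1:
                sub = TreeNode(name=names[0], length=1.0)
            else:
                sub = fam.tree.shear(names)
            subtrees.append(sub)
        if len(subtrees) == 1:
            tree = subtrees[0]
        else:
            tree = TreeNode()
            for sub in subtrees:
                sub.length = 10.0
                tree.append(sub)
        spmap = {p: self.species_of[p] for p in prots}
        label_events(tree, spmap)
        return tree, spmap


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------

def simulate_scores(
    families: Sequence[FamilyTruth],
    seed: int | np.random.Generator,
    score_noise_sd: float = 0.0,
    s0: float = 100.0,
    background_p: float = 0.05,
    background_max: float = 5.0,
) -> ScoreTable:
    """Similarity scores from patristic distances.

    Within a family ``score(a, b) = s0 * exp(-d(a, b)) + N(0, sd)`` clipped
    at zero (zero means absent); between families, each pair carries a
    background score uniform on ``(0, background_max)`` with probability
    ``background_p``. Symmetric by construction.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    entries: dict[tuple[str, str], float] = {}
    species_of: dict[str, str] = {}
    for fam in families:
        species_of.update(fam.species_of)
        if len(fam.species_of) < 2:
            continue
        dm = fam.tree.tip_tip_distances()
        ids = list(dm.ids)
        for i, j in combinations(range(len(ids)), 2):
            s = s0 * math.exp(-dm.data[i, j])
            if score_noise_sd > 0:
                s += float(rng.normal(0.0, score_noise_sd))
            if s > 0:
                a, b = sorted((ids[i], ids[j]))
                entries[(a, b)] = s
    fams = sorted(families, key=lambda f: f.family_id)
    for f1, f2 in combinations(fams, 2):
        p1, p2 = f1.proteins, f2.proteins
        mask = rng.random((len(p1), len(p2))) < background_p
        vals = rng.uniform(0.0, background_max, size=mask.shape)
        for i, a in enumerate(p1):
            for j, b in enumerate(p2):
                if mask[i, j] and vals[i, j] > 0:
                    x, y = sorted((a, b))
                    entries[(x, y)] = float(vals[i, j])
    return ScoreTable(entries, species_of)


def simulate_dataset(config: SimulationConfig) -> tuple[ScoreTable, GroundTruth]:
    """Full synthetic dataset: species tree, families, and score table.

    All randomness derives from ``config.seed``; identical configs give
    byte-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    species_tree, taxonomy = simulate_species_tree(config.n_species, rng)
    families = [
        simulate_gene_family(
            species_tree, config.dup_rate, config.loss_rate, rng, f"F{i:03d}"
        )
        for i in range(config.n_families)
    ]
    scores = simulate_scores(
        families,
        rng,
        score_noise_sd=config.score_noise_sd,
        s0=config.s0,
        background_p=config.background_p,
        background_max=config.background_max,
    )
    truth = GroundTruth(species_tree, taxonomy, families, config)
    return scores, truth


# ---------------------------------------------------------------------------
# planted conflicts
# ---------------------------------------------------------------------------

@dataclass
class PlantedConflict:
    """An OG map with one artificial hierarchical inconsistency and the
    verdict a correct resolution must reach."""

    og_map: dict[str, list[OrthologousGroup]]
    parent_level: str
    child_level: str
    child_og_id: str
    verdict: str
    edit: str  # "split_parent" or "fuse_children"


def _og_from(members: frozenset[str], level: str, species_of) -> OrthologousGroup:
    n_sp = len({species_of[p] for p in members})
    return OrthologousGroup(f"{level}.{min(members)}", level, members, n_sp)


def _try_split_parent(
    og_map, taxonomy, species_of, rng
) -> PlantedConflict | None:
    """Split a true parent OG in two so that one child OG straddles the
    parts; a correct resolver must vote merge_parents. The root is never
    used as the parent level (root merges are typically protected)."""
    candidates = []
    for parent_id, child_id in taxonomy.junctions():
        if parent_id == taxonomy.root_id:
            continue
        parents = og_map.get(parent_id, [])
        children = og_map.get(child_id, [])
        for c in children:
            for p in parents:
                if c.members <= p.members and len(c.members) >= 4 and len(p.members) >= 6:
                    candidates.append((parent_id, child_id, p, c))
    if not candidates:
        return None
    candidates.sort(key=lambda x: (x[0], x[1], x[2].og_id, x[3].og_id))
    parent_id, child_id, p, c = candidates[int(rng.integers(len(candidates)))]

    # atoms that must not straddle: every *other* child OG nested in p
    atoms: list[frozenset[str]] = []
    covered: set[str] = set()
    for kid_level in taxonomy.children_of(parent_id):
        for d in og_map.get(kid_level, []):
            if d.og_id != c.og_id and d.members <= p.members:
                atoms.append(d.members)
                covered |= d.members
    loose = sorted(p.members - c.members - covered)

    cm = sorted(c.members)
    order = rng.permutation(len(cm))
    half = len(cm) // 2
    part_a = {cm[i] for i in order[:half]}
    part_b = {cm[i] for i in order[half:]}
    for atom in atoms:
        if len(part_a) <= len(part_b):
            part_a |= atom
        else:
            part_b |= atom
    for x in loose:
        if len(part_a) <= len(part_b):
            part_a.add(x)
        else:
            part_b.add(x)

    def valid(part: set[str]) -> bool:
        return len(part) >= 3 and len({species_of[q] for q in part}) >= 2

    if not (valid(part_a) and valid(part_b)):
        return None
    new_map = {lid: list(ogs) for lid, ogs in og_map.items()}
    new_map[parent_id] = sorted(
        [o for o in og_map[parent_id] if o.og_id != p.og_id]
        + [
            _og_from(frozenset(part_a), parent_id, species_of),
            _og_from(frozenset(part_b), parent_id, species_of),
        ],
        key=lambda o: o.og_id,
    )
    return PlantedConflict(
        new_map, parent_id, child_id, c.og_id, "merge_parents", "split_parent"
    )


def _try_fuse_children(
    og_map, taxonomy, species_of, rng
) -> PlantedConflict | None:
    """Fuse two true child OGs lying in different parent OGs; a correct
    resolver must vote split_child."""
    candidates = []
    for parent_id, child_id in taxonomy.junctions():
        parents = og_map.get(parent_id, [])
        children = og_map.get(child_id, [])
        for c1, c2 in combinations(sorted(children, key=lambda o: o.og_id), 2):
            p1 = [p for p in parents if c1.members <= p.members]
            p2 = [p for p in parents if c2.members <= p.members]
            if p1 and p2 and p1[0].og_id != p2[0].og_id:
                candidates.append((parent_id, child_id, c1, c2))
    if not candidates:
        return None
    candidates.sort(key=lambda x: (x[0], x[1], x[2].og_id, x[3].og_id))
    parent_id, child_id, c1, c2 = candidates[int(rng.integers(len(candidates)))]
    fused = _og_from(c1.members | c2.members, child_id, species_of)
    new_map = {lid: list(ogs) for lid, ogs in og_map.items()}
    new_map[child_id] = sorted(
        [o for o in og_map[child_id] if o.og_id not in (c1.og_id, c2.og_id)]
        + [fused],
        key=lambda o: o.og_id,
    )
    return PlantedConflict(
        new_map, parent_id, child_id, fused.og_id, "split_child", "fuse_children"
    )


def plant_conflict(truth: GroundTruth, seed: int) -> PlantedConflict:
    """Edit the true OG map to contain exactly one nested-OG inconsistency.

    The edit (split a parent OG / fuse two child OGs) is chosen by seed;
    when the chosen edit has no eligible OG the other is tried, and if
    neither applies an error is raised.
    """
    rng = np.random.default_rng(seed)
    og_map = truth.true_og_map()
    first_split = bool(rng.integers(2))
    tries = (
        (_try_split_parent, _try_fuse_children)
        if first_split
        else (_try_fuse_children, _try_split_parent)
    )
    for fn in tries:
        planted = fn(og_map, truth.taxonomy, truth.species_of, rng)
        if planted is not None:
            return planted
    raise ValueError("no eligible OG to plant a conflict in")


# ---------------------------------------------------------------------------
# toy sequences (FASTA round-trip exercise only)
# ---------------------------------------------------------------------------

_AA = "ACDEFGHIKLMNPQRSTVWY"


def simulate_sequences(
    truth: GroundTruth, seed: int, length: int = 60
) -> dict[str, str]:
    """Toy peptide emitter: one random ancestral peptide per family with
    Poisson substitutions along branches. Not a substitution model; exists
    to exercise FASTA I/O."""
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    for fam in truth.families:
        anc = rng.integers(0, len(_AA), size=length)

        def descend(node, seq):
            if node.length:
                n_sub = rng.poisson(node.length * length * 0.5)
                seq = seq.copy()
                for _ in range(n_sub):
                    seq[rng.integers(0, length)] = rng.integers(0, len(_AA))
            if node.is_tip():
                seqs[node.name] = "".join(_AA[i] for i in seq)
            else:
                for c in node.children:
                    descend(c, seq)

        descend(fam.tree, anc)
    return seqs
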