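"""Hierarchical consistency of nested orthologous groups.

OGs are inferred independently per taxonomic level, so a child-level OG may
straddle two or more parent-level OGs. Each such conflict is resolved by
subsampling the proteins spanning the affected OGs, building (or pruning) a
gene tree per subsample, reconciling it against the species taxonomy, and
majority-voting over the per-sample verdicts:

* ``merge_parents`` — the sampled child-OG members form a single-ancestry
  clade (their MRCA is a speciation node whose species set maps at or below
  the parent level), so the parent partition cuts through a coherent group;
* ``split_child`` — otherwise; the child OG is partitioned by parent-OG
  membership.

Exact vote ties resolve conservatively to ``split_child``, and protected
levels (by default the root, where the ancient curated groups live) never
merge.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Mapping

import numpy as np
from skbio import TreeNode

from .cluster import OrthologousGroup
from .simgraph import ScoreTable
from .taxonomy import Taxonomy
from .treeevents import label_events, nj_tree, root_tree

__all__ = [
    "MERGE_PARENTS",
    "SPLIT_CHILD",
    "ConflictCase",
    "Resolution",
    "UnresolvableConflictError",
    "detect_inconsistencies",
    "reconcile_sample",
    "gene_tree_from_scores",
    "resolve",
    "enforce_hierarchy",
    "check_nestedness",
]

MERGE_PARENTS = "merge_parents"
SPLIT_CHILD = "split_child"


class UnresolvableConflictError(RuntimeError):
    """Raised when no subsample yields a valid reconciliation vote."""


@dataclass
class ConflictCase:
    """A child OG whose parent-assigned members lie in >=2 parent OGs."""

    child_og: OrthologousGroup
    parent_ogs: tuple[OrthologousGroup, ...]
    votes: list[str] = field(default_factory=list)

    def __post_init__(self):
        if len(self.parent_ogs) < 2:
            raise ValueError("a conflict needs at least two parent OGs")

    @property
    def proteins(self) -> frozenset[str]:
        out = set(self.child_og.members)
        for p in self.parent_ogs:
            out |= p.members
        return frozenset(out)


@dataclass
class Resolution:
    conflict: ConflictCase
    verdict: str
    applied_edits: list[tuple] = field(default_factory=list)


def detect_inconsistencies(
    parent_ogs: list[OrthologousGroup],
    child_ogs: list[OrthologousGroup],
) -> list[ConflictCase]:
    """Find child OGs straddling two or more parent OGs.

    Child OGs whose members are all unassigned at the parent level, or fall
    in exactly one parent OG, are consistent and produce no conflict.
    """
    of_parent: dict[str, OrthologousGroup] = {}
    for og in parent_ogs:
        for p in og.members:
            of_parent[p] = og
    conflicts = []
    for child in sorted(child_ogs, key=lambda o: o.og_id):
        hit = {of_parent[p].og_id: of_parent[p] for p in child.members if p in of_parent}
        if len(hit) >= 2:
            parents = tuple(hit[k] for k in sorted(hit))
            conflicts.append(ConflictCase(child, parents))
    return conflicts


def gene_tree_from_scores(
    proteins: list[str],
    scores: ScoreTable,
    floor_ratio: float = 1e-6,
) -> tuple[TreeNode, dict[str, str]]:
    """Rooted, event-labeled gene tree for a protein sample, estimated by
    neighbor joining on score-derived distances.

    Distance is ``-log(score / max_score)`` with missing or tiny scores
    floored at ``floor_ratio * max_score``; the tree is rooted by minimizing
    the duplication count under species-overlap labeling.
    """
    prots = sorted(proteins)
    smax = max(
        (scores.score(a, b) for a, b in combinations(prots, 2)), default=0.0
    )
    if smax <= 0:
        raise ValueError("sample has no positive pairwise scores")
    n = len(prots)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = max(scores.score(prots[i], prots[j]), floor_ratio * smax)
            d[i, j] = d[j, i] = -np.log(s / smax)
    spmap = {p: scores.species_of[p] for p in prots}
    unrooted = nj_tree((d, prots))
    rooted = root_tree(unrooted, mode="min_dup", species_of=spmap)
    return rooted, spmap


def reconcile_sample(
    proteins_sample: set[str],
    gene_tree: TreeNode | None,
    taxonomy: Taxonomy,
    conflict: ConflictCase,
    parent_level_id: str,
    species_of: Mapping[str, str] | None = None,
    scores: ScoreTable | None = None,
) -> str | None:
    """One reconciliation vote for a protein subsample.

    The gene tree is pruned to the sample and event-labeled; the verdict is
    ``merge_parents`` iff the MRCA of the sampled child-OG members is a
    speciation node whose species set lies within the parent level's clade.
    Samples covering fewer than two parent OGs, or fewer than two child-OG
    members, are discarded (``None``: not a vote).
    """
    sample = sorted(proteins_sample)
    child_members = [p for p in sample if p in conflict.child_og.members]
    hit_parents = {
        og.og_id for og in conflict.parent_ogs if og.members & set(sample)
    }
    if len(hit_parents) < 2 or len(child_members) < 2:
        return None

    if gene_tree is None:
        tree, _ = gene_tree_from_scores(sample, scores)  # already labeled
    else:
        tree = gene_tree.shear(sample)
        label_events(tree, dict(species_of) if species_of is not None else None)

    mrca = tree.lca(child_members)
    if mrca.is_tip():
        return None
    is_speciation = mrca.event == "speciation"
    maps_within_parent = taxonomy.clade_contains(parent_level_id, mrca.species_set)
    return MERGE_PARENTS if (is_speciation and maps_within_parent) else SPLIT_CHILD


def _stratified_sample(
    conflict: ConflictCase, sample_size: int, rng: np.random.Generator
) -> set[str]:
    """Sample proteins of the conflict, guaranteeing >=2 members per
    implicated parent OG, child-OG members preferred within each stratum."""
    chosen: set[str] = set()
    for og in conflict.parent_ogs:
        in_child = sorted(og.members & conflict.child_og.members)
        others = sorted(og.members - conflict.child_og.members)
        want = 2
        take = list(rng.permutation(in_child)[:want])
        if len(take) < want:
            take += list(rng.permutation(others)[: want - len(take)])
        chosen.update(take)
    pool = sorted(conflict.proteins - chosen)
    extra = max(0, sample_size - len(chosen))
    if pool and extra:
        chosen.update(rng.permutation(pool)[:extra])
    return chosen


def resolve(
    conflict: ConflictCase,
    taxonomy: Taxonomy,
    parent_level_id: str,
    child_level_id: str,
    species_of: Mapping[str, str],
    *,
    n_samples: int = 11,
    sample_size: int = 10,
    seed: int = 0,
    scores: ScoreTable | None = None,
    gene_tree_provider: Callable[[set[str]], tuple[TreeNode, dict[str, str]]] | None = None,
    protected_levels: frozenset[str] | None = None,
) -> Resolution:
    """Majority-vote resolution of one conflict.

    Gene trees come from ``gene_tree_provider`` (e.g. the simulator's true
    trees) or, failing that, NJ estimation on ``scores``. Exact ties are
    conservative (``split_child``); merging is forbidden when the parent
    level is protected.
    """
    if n_samples < 1 or sample_size < 4:
        raise ValueError("need n_samples >= 1 and sample_size >= 4")
    protected = protected_levels if protected_levels is not None else frozenset({taxonomy.root_id})
    rng = np.random.default_rng(seed)
    votes: list[str] = []
    for _ in range(n_samples):
        sample = _stratified_sample(conflict, sample_size, rng)
        if gene_tree_provider is not None:
            tree, spmap = gene_tree_provider(sample)
            v = reconcile_sample(
                sample, tree, taxonomy, conflict, parent_level_id, species_of=spmap
            )
        else:
            v = reconcile_sample(
                sample, None, taxonomy, conflict, parent_level_id, scores=scores
            )
        if v is not None:
            votes.append(v)
    if not votes:
        raise UnresolvableConflictError(
            f"conflict on {conflict.child_og.og_id}: no valid votes "
            f"(consider raising sample_size)"
        )
    conflict.votes = votes
    n_merge = votes.count(MERGE_PARENTS)
    n_split = votes.count(SPLIT_CHILD)
    verdict = MERGE_PARENTS if n_merge > n_split else SPLIT_CHILD
    if parent_level_id in protected:
        verdict = SPLIT_CHILD

    edits: list[tuple] = []
    if verdict == MERGE_PARENTS:
        union = frozenset().union(*(p.members for p in conflict.parent_ogs))
        new_id = f"{parent_level_id}.{min(union)}"
        n_sp = len({species_of[p] for p in union})
        merged = OrthologousGroup(new_id, parent_level_id, union, n_sp)
        edits.append(("replace_parents", tuple(p.og_id for p in conflict.parent_ogs), merged))
    else:
        of_parent: dict[str, str] = {}
        for og in conflict.parent_ogs:
            for p in og.members:
                of_parent[p] = og.og_id
        parts: dict[str | None, set[str]] = {}
        for p in conflict.child_og.members:
            parts.setdefault(of_parent.get(p), set()).add(p)
        new_children = []
        unassigned: set[str] = set()
        for key in sorted(parts, key=lambda k: (k is None, k)):
            members = frozenset(parts[key])
            n_sp = len({species_of[p] for p in members})
            if len(members) >= 3 and n_sp >= 2:
                new_children.append(
                    OrthologousGroup(
                        f"{child_level_id}.{min(members)}", child_level_id, members, n_sp
                    )
                )
            else:
                unassigned |= members
        edits.append(("drop_child", conflict.child_og.og_id))
        for og in new_children:
            edits.append(("add_child", og))
        if unassigned:
            edits.append(("unassign", frozenset(unassigned)))
    return Resolution(conflict, verdict, edits)


def _apply_edits(
    parent_ogs: list[OrthologousGroup],
    child_ogs: list[OrthologousGroup],
    res: Resolution,
) -> tuple[list[OrthologousGroup], list[OrthologousGroup]]:
    parents = list(parent_ogs)
    children = list(child_ogs)
    for edit in res.applied_edits:
        if edit[0] == "replace_parents":
            _, old_ids, merged = edit
            parents = [p for p in parents if p.og_id not in old_ids]
            parents.append(merged)
        elif edit[0] == "drop_child":
            children = [c for c in children if c.og_id != edit[1]]
        elif edit[0] == "add_child":
            children.append(edit[1])
    parents.sort(key=lambda o: o.og_id)
    children.sort(key=lambda o: o.og_id)
    return parents, children


def enforce_hierarchy(
    all_levels_ogs: Mapping[str, list[OrthologousGroup]],
    taxonomy: Taxonomy,
    species_of: Mapping[str, str],
    *,
    seed: int = 0,
    n_samples: int = 11,
    sample_size: int = 10,
    scores: ScoreTable | None = None,
    gene_tree_provider=None,
    protected_levels: frozenset[str] | None = None,
) -> tuple[dict[str, list[OrthologousGroup]], list[Resolution]]:
    """Top-down sweep resolving every parent/child conflict.

    Junctions are visited root-first; at each junction conflicts are
    re-detected and resolved one at a time (a parent merge can dissolve
    sibling conflicts). Because a merge deep in the taxonomy can make the
    merged OG straddle groups at an already-visited junction above, the
    sweep repeats until a full pass resolves nothing. A merge whose
    conflict signature (parent level, child membership) has been seen
    before is forced to the conservative split verdict, so opposing
    verdicts at adjacent junctions cannot oscillate. Per-conflict RNG
    streams derive deterministically from ``seed``.
    """
    state = {lid: list(ogs) for lid, ogs in all_levels_ogs.items()}
    resolutions: list[Resolution] = []
    seen: set[tuple[str, frozenset[str]]] = set()
    counter = 0
    for _sweep in range(1000):
        n_before = len(resolutions)
        for parent_id, child_id in taxonomy.junctions():
            if parent_id not in state or child_id not in state:
                continue
            guard = 0
            while True:
                conflicts = detect_inconsistencies(state[parent_id], state[child_id])
                if not conflicts:
                    break
                guard += 1
                if guard > 10_000:
                    raise RuntimeError(
                        f"junction {parent_id}/{child_id} did not converge"
                    )
                signature = (parent_id, conflicts[0].child_og.members)
                protect = protected_levels
                if signature in seen:
                    base = (
                        protect
                        if protect is not None
                        else frozenset({taxonomy.root_id})
                    )
                    protect = base | {parent_id}
                seen.add(signature)
                res = resolve(
                    conflicts[0],
                    taxonomy,
                    parent_id,
                    child_id,
                    species_of,
                    n_samples=n_samples,
                    sample_size=sample_size,
                    seed=int(
                        np.random.SeedSequence([seed, counter]).generate_state(1)[0]
                        % (2**31)
                    ),
                    scores=scores,
                    gene_tree_provider=gene_tree_provider,
                    protected_levels=protect,
                )
                counter += 1
                state[parent_id], state[child_id] = _apply_edits(
                    state[parent_id], state[child_id], res
                )
                resolutions.append(res)
        if len(resolutions) == n_before:
            break
    else:
        raise RuntimeError("hierarchy enforcement did not reach a fixed point")
    return state, resolutions


def check_nestedness(
    all_levels_ogs: Mapping[str, list[OrthologousGroup]],
    taxonomy: Taxonomy,
) -> list[tuple[str, tuple[str, ...]]]:
    """Violations of hierarchical consistency: child OGs whose
    parent-assigned members span >=2 parent OGs. Empty list = consistent."""
    bad = []
    for parent_id, child_id in taxonomy.junctions():
        if parent_id not in all_levels_ogs or child_id not in all_levels_ogs:
            continue
        for c in detect_inconsistencies(
            all_levels_ogs[parent_id], all_levels_ogs[child_id]
        ):
            bad.append((c.child_og.og_id, tuple(p.og_id for p in c.parent_ogs)))
    return bad
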