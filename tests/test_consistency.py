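"""Nested-OG conflict detection and reconciliation-vote resolution."""
import numpy as np
import pytest

from ogforge.cluster import OrthologousGroup
from ogforge.consistency import (
    MERGE_PARENTS,
    SPLIT_CHILD,
    ConflictCase,
    UnresolvableConflictError,
    check_nestedness,
    detect_inconsistencies,
    enforce_hierarchy,
    reconcile_sample,
    resolve,
)
from ogforge.io import read_newick
from ogforge.simulate import SimulationConfig, plant_conflict, simulate_dataset
from ogforge.taxonomy import Taxonomy
from ogforge.treeevents import label_events


def og(og_id, level, members, species_of):
    n_sp = len({species_of[m] for m in members})
    return OrthologousGroup(og_id, level, frozenset(members), n_sp)


SP = {p: p.split("_")[1] for p in
      ["a_A", "b_B", "c_C", "d_D", "e_A", "f_B", "g_C", "h_D"]}


def test_detection_definition_instances():
    parents = [og("P.a_A", "P", {"a_A", "b_B", "c_C"}, SP),
               og("P.e_A", "P", {"e_A", "f_B", "g_C"}, SP)]
    consistent = og("C.a_A", "C", {"a_A", "b_B", "c_C"}, SP)
    assert detect_inconsistencies(parents, [consistent]) == []
    straddler = og("C2.a_A", "C", {"a_A", "b_B", "e_A"}, SP)
    found = detect_inconsistencies(parents, [straddler])
    assert len(found) == 1
    assert {p.og_id for p in found[0].parent_ogs} == {"P.a_A", "P.e_A"}
    # all members unassigned at parent level -> no conflict
    orphan = og("C3.d_D", "C", {"d_D", "h_D", "g_C"}, SP)
    assert detect_inconsistencies(parents, [orphan]) == []


def test_detection_matches_bruteforce_on_random_nestings():
    rng = np.random.default_rng(2)
    for _ in range(50):
        prots = [f"p{i:02d}_s{i % 4}" for i in range(24)]
        spmap = {p: p.split("_")[1] for p in prots}
        perm = list(rng.permutation(prots))
        parents, children = [], []
        i = 0
        while i + 3 <= len(perm) and len(parents) < 4:
            k = int(rng.integers(3, 7))
            grp = perm[i: i + k]
            if len({spmap[p] for p in grp}) >= 2 and len(grp) >= 3:
                parents.append(og(f"P.{min(grp)}", "P", grp, spmap))
            i += k
        perm2 = list(rng.permutation(prots))
        i = 0
        while i + 3 <= len(perm2) and len(children) < 4:
            k = int(rng.integers(3, 7))
            grp = perm2[i: i + k]
            if len({spmap[p] for p in grp}) >= 2:
                children.append(og(f"C.{min(grp)}", "C", grp, spmap))
            i += k
        found = {c.child_og.og_id for c in detect_inconsistencies(parents, children)}
        expect = set()
        for c in children:
            hit = set()
            for p in parents:
                if c.members & p.members:
                    hit.add(p.og_id)
            if len(hit) >= 2:
                expect.add(c.og_id)
        assert found == expect


TAX = Taxonomy.from_newick("(((A,B)inner,C)mid,D)root;")


def test_vote_split_when_child_mrca_is_above_parent_clade():
    """Child members spanning the root of the gene tree, with the parent
    level deep in the taxonomy: the MRCA maps above the parent -> split."""
    tree = read_newick("((a_A,b_B),(c_C,d_D));")
    spmap = {n: n.split("_")[1] for n in ["a_A", "b_B", "c_C", "d_D"]}
    label_events(tree, spmap)
    child = og("mid.a_A", "mid", {"a_A", "b_B", "c_C"}, spmap)
    p1 = og("P1", "mid", {"a_A", "b_B", "x_C"}, {**spmap, "x_C": "C"})
    p2 = og("P2", "mid", {"c_C", "d_D", "y_A"}, {**spmap, "y_A": "A"})
    conflict = ConflictCase(child, (p1, p2))
    v = reconcile_sample(
        {"a_A", "b_B", "c_C", "d_D"}, tree, TAX, conflict, "inner", species_of=spmap
    )
    assert v == SPLIT_CHILD


def test_vote_merge_when_child_forms_clean_clade_within_parent():
    tree = read_newick("(((a_A,b_B),(c_A,d_B)),(e_C,f_D));")
    spmap = {n: n.split("_")[1] for n in ["a_A", "b_B", "c_A", "d_B", "e_C", "f_D"]}
    label_events(tree, spmap)
    child = og("inner.a_A", "inner", {"a_A", "b_B", "c_A", "d_B"}, spmap)
    p1 = og("mid.a_A", "mid", {"a_A", "b_B", "e_C"}, spmap)
    p2 = og("mid.c_A", "mid", {"c_A", "d_B", "f_D"}, spmap)
    conflict = ConflictCase(child, (p1, p2))
    # sampled child members a,b,c,d: MRCA is a duplication ({A,B}&{A,B}) -> split
    v = reconcile_sample(
        {"a_A", "b_B", "c_A", "d_B"}, tree, TAX, conflict, "mid", species_of=spmap
    )
    assert v == SPLIT_CHILD
    # but a coherent speciation clade within the parent clade -> merge
    tree2 = read_newick("(((a_A,b_B),c_C),(x_D,y_D));")
    spmap2 = {n: n.split("_")[1] for n in ["a_A", "b_B", "c_C", "x_D", "y_D"]}
    label_events(tree2, spmap2)
    child2 = og("mid.a_A", "mid", {"a_A", "b_B", "c_C"}, spmap2)
    q1 = og("mid.a2", "mid", {"a_A", "b_B", "x_D"}, spmap2)
    q2 = og("mid.c2", "mid", {"c_C", "y_D", "x2_D"}, {**spmap2, "x2_D": "D"})
    conflict2 = ConflictCase(child2, (q1, q2))
    v2 = reconcile_sample(
        {"a_A", "b_B", "c_C"}, tree2, TAX, conflict2, "root", species_of=spmap2
    )
    assert v2 == MERGE_PARENTS


def test_degenerate_samples_are_discarded():
    tree = read_newick("((a_A,b_B),(c_C,d_D));")
    spmap = {n: n.split("_")[1] for n in ["a_A", "b_B", "c_C", "d_D"]}
    label_events(tree, spmap)
    child = og("C", "C", {"a_A", "b_B", "c_C"}, SP)
    p1 = og("P1", "P", {"a_A", "b_B", "e_A"}, SP)
    p2 = og("P2", "P", {"c_C", "d_D", "h_D"}, SP)
    conflict = ConflictCase(child, (p1, p2))
    # sample hits only one parent OG -> not a vote
    assert reconcile_sample({"a_A", "b_B"}, tree, TAX, conflict, "root",
                            species_of=spmap) is None


def planted_case(seed):
    cfg = SimulationConfig(seed=9000 + seed, n_species=8, n_families=12,
                           dup_rate=0.1, loss_rate=0.05)
    _, truth = simulate_dataset(cfg)
    return truth, plant_conflict(truth, seed=seed)


def test_resolution_recovers_planted_verdicts():
    hits = 0
    for seed in range(10):
        truth, planted = planted_case(seed)
        conflicts = detect_inconsistencies(
            planted.og_map[planted.parent_level], planted.og_map[planted.child_level]
        )
        assert len(conflicts) == 1  # exactly the planted conflict
        res = resolve(
            conflicts[0], truth.taxonomy, planted.parent_level,
            planted.child_level, truth.species_of, seed=seed,
            gene_tree_provider=truth.gene_tree_for,
        )
        hits += res.verdict == planted.verdict
        assert len(conflicts[0].votes) >= 1
    assert hits >= 9


def test_resolution_deterministic_per_seed():
    truth, planted = planted_case(3)
    conflict = detect_inconsistencies(
        planted.og_map[planted.parent_level], planted.og_map[planted.child_level]
    )[0]
    kwargs = dict(
        taxonomy=truth.taxonomy, parent_level_id=planted.parent_level,
        child_level_id=planted.child_level, species_of=truth.species_of,
        gene_tree_provider=truth.gene_tree_for,
    )
    r1 = resolve(conflict, seed=5, **kwargs)
    v1 = list(conflict.votes)
    r2 = resolve(conflict, seed=5, **kwargs)
    assert r1.verdict == r2.verdict and conflict.votes == v1


def test_root_protection_forbids_merges():
    # find a planted split_parent case (true verdict merge) and protect its
    # parent level: the verdict must flip to split_child
    for seed in range(20):
        truth, planted = planted_case(seed)
        if planted.verdict != MERGE_PARENTS:
            continue
        conflict = detect_inconsistencies(
            planted.og_map[planted.parent_level], planted.og_map[planted.child_level]
        )[0]
        res = resolve(
            conflict, truth.taxonomy, planted.parent_level, planted.child_level,
            truth.species_of, seed=seed, gene_tree_provider=truth.gene_tree_for,
            protected_levels=frozenset({planted.parent_level}),
        )
        assert res.verdict == SPLIT_CHILD
        assert conflict.votes.count(MERGE_PARENTS) > len(conflict.votes) / 2
        return
    pytest.fail("no merge-verdict planted case found")


def test_enforce_is_fixed_point_on_consistent_input():
    cfg = SimulationConfig(seed=77, n_species=6, n_families=8)
    _, truth = simulate_dataset(cfg)
    og_map = truth.true_og_map()
    fixed, resolutions = enforce_hierarchy(
        og_map, truth.taxonomy, truth.species_of, seed=1,
        gene_tree_provider=truth.gene_tree_for,
    )
    assert resolutions == []
    assert {k: [o.og_id for o in v] for k, v in fixed.items()} == {
        k: [o.og_id for o in v] for k, v in og_map.items()
    }


def test_enforce_restores_nestedness_on_planted_conflicts():
    for seed in (0, 1, 2):
        truth, planted = planted_case(seed)
        assert check_nestedness(planted.og_map, truth.taxonomy) != []
        fixed, resolutions = enforce_hierarchy(
            planted.og_map, truth.taxonomy, truth.species_of, seed=seed,
            gene_tree_provider=truth.gene_tree_for,
        )
        assert len(resolutions) >= 1
        assert check_nestedness(fixed, truth.taxonomy) == []


def test_unresolvable_conflict_raises():
    spmap = {**SP, "x_A": "A", "y_B": "B", "z_C": "C"}
    # child OG disjoint from both parent OGs: no sample can include two
    # child members and two parent OGs
    child = og("C", "C", {"x_A", "y_B", "z_C"}, spmap)
    p1 = og("P1", "P", {"a_A", "b_B", "c_C"}, spmap)
    p2 = og("P2", "P", {"e_A", "f_B", "g_C"}, spmap)
    conflict = ConflictCase(child, (p1, p2))
    # sample_size 4 is consumed by the two parent strata, so no sample ever
    # contains two child members: every vote is discarded
    with pytest.raises(UnresolvableConflictError):
        resolve(conflict, TAX, "root", "mid", spmap, seed=1, sample_size=4,
                gene_tree_provider=lambda s: _dummy_tree(s, spmap))


def _dummy_tree(sample, spmap):
    from ogforge.treeevents import label_events as le

    names = sorted(sample)
    nwk = "(" + ",".join(names) + ");"
    t = read_newick(nwk)
    le(t, spmap)
    return t, {n: spmap[n] for n in names}


def test_split_verdict_partitions_child_by_parent_membership():
    truth, planted = planted_case(1)
    if planted.verdict != SPLIT_CHILD:
        truth, planted = planted_case(0)
    if planted.verdict != SPLIT_CHILD:
        pytest.skip("no fuse case in first seeds")
    fixed, resolutions = enforce_hierarchy(
        planted.og_map, truth.taxonomy, truth.species_of, seed=9,
        gene_tree_provider=truth.gene_tree_for,
    )
    res = resolutions[0]
    assert res.verdict == SPLIT_CHILD
    new_children = [e[1] for e in res.applied_edits if e[0] == "add_child"]
    of_parent = {}
    for p in res.conflict.parent_ogs:
        for x in p.members:
            of_parent[x] = p.og_id
    for c in new_children:
        assert len({of_parent.get(m) for m in c.members}) == 1
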