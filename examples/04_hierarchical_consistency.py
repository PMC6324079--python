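"""Detect and resolve a nested-OG inconsistency by reconciliation voting.

Orthologous groups are inferred independently per taxonomic level, so a
child-level OG can straddle two parent-level OGs. Protein subsamples of the
affected OGs are reconciled against the taxonomy; each sample votes to
merge the parents (the child is a coherent speciation clade inside the
parent clade) or to split the child. Here a conflict is planted into a
simulated truth, so the correct answer is known.
"""
from ogforge import (
    SimulationConfig,
    check_nestedness,
    detect_inconsistencies,
    enforce_hierarchy,
    resolve,
    simulate_dataset,
)
from ogforge.simulate import plant_conflict

_, truth = simulate_dataset(
    SimulationConfig(seed=7003, n_species=8, n_families=12,
                     dup_rate=0.1, loss_rate=0.05)
)
planted = plant_conflict(truth, seed=3)
print(f"planted edit: {planted.edit} at junction "
      f"{planted.parent_level}/{planted.child_level}; "
      f"correct verdict: {planted.verdict}")

conflict = detect_inconsistencies(
    planted.og_map[planted.parent_level], planted.og_map[planted.child_level]
)[0]
print(f"conflict: child {conflict.child_og.og_id} straddles "
      f"{[p.og_id for p in conflict.parent_ogs]}")

res = resolve(conflict, truth.taxonomy, planted.parent_level,
              planted.child_level, truth.species_of, seed=1,
              gene_tree_provider=truth.gene_tree_for)
print(f"votes: {res.conflict.votes.count('merge_parents')} merge / "
      f"{res.conflict.votes.count('split_child')} split -> {res.verdict}")

fixed, _ = enforce_hierarchy(planted.og_map, truth.taxonomy, truth.species_of,
                             seed=1, gene_tree_provider=truth.gene_tree_for)
print(f"violations after enforcement: {len(check_nestedness(fixed, truth.taxonomy))}")
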