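# ogforge

Desk-scale inference of **orthologous groups** (OGs) across a species
taxonomy, in the style of large orthology databases: species-aware
clustering of best-reciprocal-hit graphs by triangulation, hierarchical
consistency of nested OGs via gene-tree/species-tree reconciliation with
majority voting, and speciation/duplication annotation of gene trees by the
species-overlap rule, yielding typed pairwise orthology tables. A
synthetic-data generator with complete ground truth makes every stage
testable without any external dataset.

It is written for comparative genomicists and method developers who want
the construction machinery of an orthology resource as an inspectable,
seedable library rather than a production pipeline: the inputs are plain
text (FASTA, Newick, BLAST-like score TSVs), the outputs are diffable TSVs,
and every stochastic step takes an explicit seed.

## The method

Given an all-vs-all similarity table *S(a, b)* (bit-score-like; the
Smith–Waterman/BLAST search itself is upstream) and a species taxonomy
whose internal nodes are the *taxonomic levels*, per level *ℓ* with species
clade *C(ℓ)*:

1. **Best reciprocal hits.** For each protein *p* and each other species
   *t* ∈ *C(ℓ)*, the best hits are argmax over *S(p, ·)* restricted to
   species *t* (ties retained). Edge (*a*, *b*) is a BRH iff each is among
   the other's best hits in the partner's species.
2. **In-paralogs.** Same-species proteins *a*, *b* cluster (transitively)
   iff *S(a, b)* ≥ both proteins' best cross-species scores within
   *C(ℓ)* — the classic "closer to each other than to anything in any other
   species" criterion.
3. **Triangulation.** Seed clusters are the components of 3-clique
   percolation on the BRH graph (triangles merged whenever they share an
   edge); in-paralog clusters then attach atomically to the seed reached by
   their highest-scoring supporting BRH edge. Clusters with < 3 proteins or
   < 2 species are left unassigned: an OG is ≥ 3 sequences diverging from
   one speciation event.
4. **Hierarchical consistency.** A child-level OG whose members lie in ≥ 2
   parent-level OGs is a conflict. Protein subsamples spanning the affected
   OGs are turned into gene trees (given, or NJ on −log *S*/*S*max
   distances), rooted by duplication-minimization, and event-labeled; a
   sample votes **merge_parents** iff the sampled child members' MRCA is a
   speciation node mapping inside the parent clade, else **split_child**.
   Majority wins, ties split, and protected levels (the root by default)
   never merge.
5. **Events and pairs.** An internal node of a rooted gene tree is a
   *duplication* iff ≥ 2 of its children's species sets intersect
   (species overlap), else a *speciation*. Ortholog pairs are
   different-species leaf pairs with a speciation MRCA, typed
   one-to-one / one-to-many / many-to-many by per-side in-paralog counts.

Genome quality control applies the printed filters up front: ≤ 4 of 40
universal single-copy markers missing, < 300 contigs, N50 ≥ 10 kb for
cellular genomes; ≥ 3 proteins for viral proteomes. Benchmarking uses
pair-based precision / recall / F over co-membership pairs.

## Worked example

```python
from ogforge import (SimulationConfig, simulate_dataset, build_all_levels,
                     GroupSet, fmeasure)

config = SimulationConfig(seed=42, n_species=8, n_families=20,
                          dup_rate=0.2, loss_rate=0.05, score_noise_sd=2.0)
table, truth = simulate_dataset(config)
predicted = build_all_levels(table, truth.taxonomy)
```

Scoring each level against the simulated truth
(`examples/02_infer_orthologous_groups.py`) prints:

```
159 proteins, 1228 score pairs, 7 taxonomic levels
level    species  OGs pair-F vs truth
L0             8   19           0.960
L1             7   19           1.000
L2             6   19           1.000
...
```

pair-F is the F-measure over co-membership protein pairs: 1.000 means the
level's groups match the truth exactly; the root level loses a few pairs
where an ancient duplication fragments a family (see
`docs/methods.md`). Two-species levels emit no OGs — no three-species
triangle can exist there.

The other `examples/` scripts are equally small: quality filtering
(`01`), event labeling and typed ortholog pairs (`03`), planted-conflict
resolution with vote counts (`04`), and the benchmark metrics (`05`). The
same functionality is exposed as a thin CLI:

```bash
ogforge simulate --seed 5 --n-species 6 --n-families 8 --out-dir sim/
ogforge cluster --scores sim/scores.tsv --species-map sim/species_map.tsv \
                --taxonomy sim/taxonomy.tsv --out-dir out/
ogforge consistency --ogs out/ogs.tsv --species-map sim/species_map.tsv \
                    --taxonomy sim/taxonomy.tsv --scores sim/scores.tsv \
                    --out fixed.tsv --seed 1
ogforge bench groups --pred out/ogs.tsv --ref sim/true_ogs.tsv
```

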