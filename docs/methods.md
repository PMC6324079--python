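# Methods

This note documents the models, rules and numerical choices behind
`ogforge`, in the order the pipeline applies them, together with what the
synthetic-data generator does and does not emulate.

## Quality control (`ogforge.qc`)

Cellular genomes are excluded iff they miss **more than 4** of a universe
of **40** universal single-copy marker genes, have **300 contigs or more**
("fewer than 300" is the passing condition), or have an assembly **N50
below 10 000 bp**. Viral proteomes are excluded iff they retain **fewer
than 3** proteins after in-silico polyprotein cleaving. All boundaries are
read literally and are inclusive on the passing side; a genome missing
exactly 4 markers with exactly 299 contigs and N50 exactly 10 000 passes.
N50 is the contig length at which the cumulative sum, in non-increasing
order, first reaches half the assembly total. Marker detection and
polyprotein cleaving are upstream inputs: this module filters on their
results, it does not compute them.

## Score table and graph stages (`ogforge.simgraph`)

Scores are non-negative, bit-score-like (larger = more similar) and
symmetrized on input by taking the maximum over both directions; self-hits
are dropped and zero scores mean *absent* (sparse-table semantics). Every
operation takes an explicit species subset so it can run per taxonomic
level.

*Best hits* are computed per (protein, target species) with **all ties
retained**, so results never depend on input order. *Reciprocal best hits*
(BRH) require membership in each other's best-hit sets. *In-paralog
clusters* use the transitive closure of: two same-species proteins join
iff their mutual score is at least each one's best cross-species score
within the subset. This is the standard in-paralogy criterion; the exact
production rule of large databases is not published in a reusable form, so
the classic version is used and tested against a brute-force oracle.

A useful consequence of per-target-species argmax: removing a species from
the subset never changes BRH edges among the remaining species (asserted
as a property test).

## Clustering (`ogforge.cluster`)

Seeds are the connected components of **3-clique percolation** on the BRH
graph: triangles merged whenever they share an edge. Triangles on a BRH
graph necessarily span three species, because BRH edges never join
same-species proteins. Each in-paralog cluster — singletons included —
then attaches *as a unit* to the seed reached by its highest-scoring
supporting BRH edge (tie: lexicographically smallest seed id, the seed's
smallest member); clusters with no BRH edge into any seed stay unattached.
Final clusters with fewer than 3 members or fewer than 2 species are
reported as unassigned rather than emitted, keeping the "three or more
sequences from one speciation event" definition strict. OG identifiers are
`<level>.<smallest member>`, which makes them unique across levels and
stable under any permutation of the input rows.

Levels with fewer than two species are skipped (no speciation event is
definable); two-species levels run but can only produce OGs through
in-paralog attachment, since no three-species triangle exists.

## Hierarchical consistency (`ogforge.consistency`)

OGs are inferred independently per level, so a child OG may straddle
several parent OGs. For each conflict, `n_samples = 11` protein subsamples
of `sample_size = 10` are drawn (odd count avoids most ties; stratified to
include two members per implicated parent OG, child members preferred, so
votes are almost always valid). Each sample yields a gene tree — supplied
(e.g. the simulator's true trees) or estimated by neighbor joining on
distances `−log(S/S_max)` with the score ratio floored at `1e−6`, rooted
by duplication-minimization — and one vote:

* **merge_parents** iff the MRCA of the sampled child-OG members is a
  *speciation* node whose species set lies within the parent level's
  clade: the child is one coherent post-speciation lineage and the parent
  partition cuts through it;
* **split_child** otherwise (duplication MRCA, or ancestry older than the
  parent level).

Samples touching fewer than two parent OGs or fewer than two child members
are discarded; a conflict with zero valid votes raises an explicit error.
Majority decides; an exact tie resolves conservatively to split. A
configurable set of **protected levels** (default: the taxonomy root, where
ancient curated groups live) can never merge — the verdict is forced to
split regardless of votes. Splitting partitions the child OG by parent-OG
membership; parts below 3 members or 2 species go to unassigned. The
enforcement sweep is top-down over parent/child junctions, re-detecting
after each resolution (a merge can dissolve sibling conflicts). One pass
is not always enough: a merge deep in the taxonomy can make the merged OG
straddle groups at a junction above, so the sweep repeats until a full
pass resolves nothing; and because opposing verdicts at adjacent junctions
could otherwise merge and re-split the same groups forever, a conflict
whose signature (parent level, child membership) recurs is forced to the
conservative split verdict — splits strictly refine the partition, so
enforcement terminates. A post-condition checker re-verifies global
nestedness. Per-conflict RNG streams are spawned deterministically from
the run seed.

## Gene-tree analysis (`ogforge.treeevents`)

Alignment trimming removes columns with **fewer than 5** non-gap residues
(gap characters `-` and `.`), preserving row and column order; the
operation is idempotent. Production alignment and maximum-likelihood tree
inference are out of scope by design — trees and alignments are accepted
as Newick / aligned FASTA — and the only built-in estimator is neighbor
joining (scikit-bio's implementation, taxa pre-sorted lexicographically so
the result is order-independent).

Rooting: `min_dup` evaluates every branch as a root position and keeps the
one minimizing the number of duplication-labeled nodes under species
overlap, breaking ties by smaller maximum root-to-leaf depth, then by the
lexicographically smallest bipartition; `midpoint` is the standard
fallback for trees without species structure. Species overlap labels an
internal node a duplication iff **any two** of its children's species sets
intersect (threshold zero — any overlap counts; multifurcations use
pairwise intersection, which is the conservative reading). On loss-free
gene trees this labeling coincides with classic LCA-mapping reconciliation,
which the tests assert with an independent oracle.

Ortholog pairs: for each speciation node and each pair of its child
subtrees, every cross-subtree leaf pair of different species is emitted;
the relation counts, in each of the two subtrees, the leaves of that
side's own species (1 vs 1 → one-to-one, 1 vs k → one-to-many, k vs m →
many-to-many). Pairs with a duplication MRCA are paralogs and never
emitted.

## Benchmark metrics (`ogforge.bench`)

Both group predictions and fine-grained pair predictions are scored on
co-membership pairs: precision = |pred ∩ ref| / |pred| (1.0 for an empty
prediction), recall = |pred ∩ ref| / |ref|, F = harmonic mean. Predicted
proteins outside the reference universe are dropped first, the standard
benchmark convention. Reference groups may overlap.

Two monotonicity facts are asserted on random group sets: merging
predicted groups never decreases recall, and splitting a predicted group
**along reference boundaries** never decreases precision (such a split
removes only false-positive pairs). Note that an *arbitrary* split can
lower precision — the removed cross-part pairs may be disproportionately
true — so the boundary-respecting form is the correct statement of the
folk rule.

## The generator (`ogforge.simulate`)

The generator instantiates the OG definition literally, so ground truth is
exact by construction rather than curated.

* **Species tree**: uniform over labeled rooted binary topologies
  (stepwise addition over all 2n−1 attachment positions), made ultrametric
  with root at time 0 and tips at 1; internal node times are drawn
  recursively as parent + U(0.1, 0.9)·(remaining depth), which avoids
  degenerate zero-length branches. Internal nodes, named in preorder, are
  the taxonomic levels.
* **Families**: one ancestral copy per family enters at the root;
  duplications are a Poisson process at `dup_rate` and losses at
  `loss_rate` per unit branch length, with losses pruned inline (lineage
  thinning — same extant-data distribution as explicit loss nodes).
  Families extinct everywhere are redrawn and the count reported.
* **Observable event labels**: after loss, a duplication whose surviving
  copies occupy disjoint species sets is indistinguishable from a
  speciation in the extant tree; the generator therefore exports the
  observable type, computed by its own recursion. This is what makes
  "species-overlap labeling reproduces the simulated labels exactly" a
  well-posed check under loss.
* **True OGs** at a level are the leaves of the level's clade grouped by
  gene-tree divergence time at or after the level node's time — exactly
  "descendants of one gene lineage present at that ancestral species
  node". True pairs come from the true labeled trees via the same
  pairwise-orthologs routine the package exposes.
* **Scores**: `S(a,b) = 100·exp(−d(a,b)) + N(0, sd)` within a family
  (patristic distance *d*, clipped at zero = absent), and sparse uniform
  background on (0, 5] between families (each cross pair present with
  probability 0.05). Sequence evolution is deliberately **not** simulated:
  the pipeline consumes scores, and deriving them from distances keeps the
  noise model explicit and the tests fast. A toy peptide emitter exists
  only to exercise FASTA round-trips.
* **Planted conflicts** edit the true OG map by either splitting a parent
  OG across a child OG (correct verdict: merge) or fusing two child OGs
  from different parents (correct verdict: split), leaving exactly one
  inconsistency; eligibility rules keep all edited groups valid OGs and
  never plant merge-requiring conflicts at the protected root.

Defaults (`SimulationConfig`): 8 species, 50 families, rates and noise
zero — the clean regime, in which the pipeline must recover the truth with
pair-F = 1.0 at every level, and does. The consistency study uses 12
families with `dup_rate = 0.1`, `loss_rate = 0.05` over 8 species — enough
structure for plantable junctions while keeping gene trees close to the
species tree.

What the generator does **not** emulate: sequence-level evolution and
alignment error, horizontal transfer, gene fusion ("mosaic" multi-domain
proteins), rate heterogeneity, and assembly artifacts. Passing tests
therefore demonstrate correctness of the graph/tree machinery under the
stated noise model, not robustness to real proteome messiness.

## Known limitations

* **Ancient paralog fragmentation.** Under duplication/loss with noisy
  scores (dup 0.3, loss 0.1, score sd 5), root-level recovery runs at
  pair-F ≈ 0.84–0.90 (mean over 20 seeds; precision ≈ 1.0). The loss is
  recall: a duplication that predates the divergences within its clade
  creates two subfamilies with no cross-subfamily BRH edges, so triangle
  percolation cannot reunite them at ancestral levels. This is inherent to
  BRH-triangulation clustering, and the spread across seed blocks comes
  from the shared species tree: one deep-branching tree affects all its
  families at once.
* The in-paralog rule and the clustering merge operator are the standard
  readings of a method whose production parameters are not published; both
  are pinned down by brute-force oracles rather than by comparison to the
  original implementation.
* Two-species levels cannot yield triangle-seeded OGs; their groups exist
  only at ancestral levels or via in-paralog attachment.
* The reconciliation vote uses MRCA species-mapping only; duplication–loss
  costs over alternative repartitions are out of scope.
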