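"""Pair-based precision / recall / F-measure for orthology predictions.

A grouping induces the set of unordered protein pairs that co-occur in a
group; predictions are scored against a reference on those pair sets. The
same machinery scores fine-grained pairwise predictions directly.
"""
from ogforge import GroupSet, copair_set, fmeasure, pairwise_pr

# four proteins, one true family, prediction split in two
pred = GroupSet.from_iterable([{"a", "b"}, {"c", "d"}])
ref = GroupSet.from_iterable([{"a", "b", "c", "d"}])
p, r, f = fmeasure(pred, ref)
print(f"groups: precision={p:.3f} recall={r:.3f} F={f:.3f}")
# 2 of the 6 true co-pairs are predicted: precision 1, recall 1/3, F 0.5

truth_pairs = copair_set(ref)
pred_pairs = copair_set(pred) | {frozenset(("a", "x"))}
p, r, f = pairwise_pr(pred_pairs, truth_pairs)
print(f"pairs:  precision={p:.3f} recall={r:.3f} F={f:.3f}")
# the spurious (a,x) pair now costs precision
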