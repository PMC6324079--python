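"""Root a gene tree, label duplication/speciation events, extract typed
ortholog pairs.

Leaf names follow the opt-in ``protein_species`` convention. The rooting
minimizes the duplication count under species-overlap labeling; an internal
node is a duplication iff its children's species sets intersect. Ortholog
pairs are leaf pairs whose most recent common ancestor is a speciation,
typed one-to-one / one-to-many / many-to-many by in-paralog counts.
"""
from ogforge import label_events, pairwise_orthologs, root_tree
from ogforge.io import read_newick

newick = "((human1_hsa,(mouse1_mmu,mouse2_mmu)),(human2_hsa,fly1_dme));"
tree = root_tree(read_newick(newick), mode="min_dup")
label_events(tree)

print("internal node events:")
for node in tree.non_tips(include_self=True):
    tips = ",".join(sorted(t.name for t in node.tips()))
    print(f"  {node.event:11s} over [{tips}]")

print("ortholog pairs:")
for pair in pairwise_orthologs(tree):
    print(f"  {pair.protein_a:12s} {pair.protein_b:12s} {pair.relation}")

# mouse1/mouse2 descend from a duplication, so each is an ortholog of
# human1 (one-to-many) and they are never paired with each other.
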