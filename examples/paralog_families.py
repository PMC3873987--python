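"""Paralog families by reciprocal-hit criteria and iterative bridge removal.

A toy graph first: two triangles joined by one weak edge.  The joining edge
is the only bridge inside a component larger than two, so it is removed and
the component splits into two families of three.
"""

from immunostrata.families import ParalogEdge, build_families, multi_copy_flags


def edge(a, b, bs):
    return ParalogEdge(*sorted((a, b)), bitscore_ab=bs, bitscore_ba=bs)


edges = [
    edge("defensin1", "defensin2", 210),
    edge("defensin2", "defensin3", 190),
    edge("defensin1", "defensin3", 230),
    edge("nasonin1", "nasonin2", 180),
    edge("nasonin2", "nasonin3", 170),
    edge("nasonin1", "nasonin3", 160),
    edge("defensin3", "nasonin1", 45),  # weak link between the two clusters
]
genes = sorted({g for e in edges for g in (e.gene_a, e.gene_b)}) + ["orphan"]

families = build_families(edges, genes)
for fam in families:
    print(fam.family_id, sorted(fam.members))

flags = multi_copy_flags(families)
n_multi = sum(flags.values())
print(f"\n{n_multi}/{len(genes)} genes are in multi-gene families;")
print("the weak inter-cluster edge was the lowest-bitscore bridge and was cut,")
print("while the bridge-free triangles stayed intact and 'orphan' is a singleton.")
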