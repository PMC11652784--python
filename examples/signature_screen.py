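"""Screen the packaged perturbagen and gene-fold tables.

The packaged tables transcribe a connectivity-scoring screen: perturbagen
classes (PCLs) per comparison group with scores in [-100, 100], and genes
two-fold up/down in the reference comparison annotated with the treatment
groups sharing each change.  The screen keeps PCLs with scores strictly
above 80, then intersects the per-group gene sets into exact Venn regions.
"""

from gliaquant.signatures import (
    filter_scores,
    intersect_sets,
    load_packaged_table,
    packaged_gene_sets,
    shared_annotations,
)

pcl = load_packaged_table("pcl_scores")
kept, counts = filter_scores(pcl, threshold=80.0, kind="PCL")
print("PCLs with score > 80 per group:", {g: n for (g, _k), n in sorted(counts.items())})

up_venn = intersect_sets(packaged_gene_sets("upregulated_genes"))
down_venn = intersect_sets(packaged_gene_sets("downregulated_genes"))
print("upregulated genes shared by all three treatment groups :", up_venn.count("A1", "S1", "C1"))
print("  ->", ", ".join(up_venn.regions[frozenset({'A1', 'S1', 'C1'})]))
print("upregulated genes shared by A1 and C1 only             :", up_venn.count("A1", "C1"))
print("downregulated genes shared by all three treatment groups:", down_venn.count("A1", "S1", "C1"))
print()
print(shared_annotations(up_venn).head(8).to_string(index=False))
print()
print(
    "Each Venn region is disjoint: a gene shared by all three groups is not "
    "re-counted in any pairwise region."
)
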