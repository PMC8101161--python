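"""Classical overrepresentation analysis on a small worked example.

Eight candidate DEGs in a 20-gene background are tested against two gene
sets.  The printed p-value is the upper-tail hypergeometric probability
(the chance of seeing at least that many DEGs in the set if DEG status
were assigned at random), and q is its Benjamini-Hochberg adjustment.
"""
from lpia import Category, DEGRecord, DEGTable, GeneSet, GeneSetCollection, enrich

background = [f"g{i}" for i in range(20)]
degs = DEGTable(records={
    g: DEGRecord(gene_id=g, log2fc=2.0, pvalue=1e-6, qvalue=1e-4)
    for g in background[:8]
})

coll = GeneSetCollection(category=Category.KEGG)
coll.add(GeneSet("S1", "mostly-DEG set", Category.KEGG,
                 frozenset({"g0", "g1", "g2", "g3", "g15"})))
coll.add(GeneSet("S2", "background-like set", Category.KEGG,
                 frozenset({"g14", "g15", "g16", "g17", "g18"})))

rows = enrich(coll, degs, background=background)
print(rows.to_string(index=False))
print(
    "\nS1 holds 4 of the 8 DEGs among its 5 genes (rich ratio 0.8), "
    "p ~ 0.058; S2 holds none, so its upper-tail p is 1."
)
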