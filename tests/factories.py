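"""Plain-function test factories, usable from hypothesis-driven tests."""
from lpia import Category, DEGRecord, DEGTable, GeneSet, GeneSetCollection


def build_collection(sets, category=Category.KEGG):
    category = Category(category)
    coll = GeneSetCollection(category=category)
    for set_id, members in sets.items():
        coll.add(GeneSet(set_id=set_id, name=set_id, category=category,
                         members=frozenset(members)))
    return coll


def build_degs(lfc, qvalue=1e-4, background=None):
    records = {
        g: DEGRecord(gene_id=g, log2fc=float(v), pvalue=qvalue / 2, qvalue=qvalue)
        for g, v in lfc.items()
    }
    bg = frozenset(background) if background is not None else None
    return DEGTable(records=records, background=bg)
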