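# lpia — latent pathway identification analysis

`lpia` finds pathways that matter in a transcriptomic comparison even when
standard overrepresentation statistics rank them unremarkably. It is aimed
at analysts who already have a differential-expression (DE) table — from
DESeq2, edgeR, limma or similar — plus KEGG-pathway and GO
biological-process annotations, and who want to know which pathways sit at
the centre of the *network* of transcriptional change rather than which
are individually most enriched. A classic use case is metabolic disease
transcriptomics, where a modestly enriched pathway (e.g. a cell-death
program such as ferroptosis) can be the mechanistic hub connecting many
strongly enriched metabolic pathways.

## The method

Given a pathway collection *P*, a GO biological-process collection *G*
(both restricted to the differentially expressed genes, DEGs) and a DE
magnitude DE<sub>x</sub> = |log2 fold change| per gene *x*:

1. **Bipartite weighting.** Every (GO term *G*, pathway *P*) pair sharing
   at least one DEG gets the weight

   W<sub>GP</sub> = (|G ∩ P| / |G ∪ P|) · median{ DE<sub>x</sub> : x ∈ G ∩ P }

   — Jaccard overlap of the two DEG-restricted sets scaled by the median
   DE magnitude of the shared genes.

2. **One-mode projection.** The pathway–pathway weight is

   A<sub>ij</sub> = Σ<sub>k</sub> W(G<sub>k</sub>, P<sub>i</sub>) · W(G<sub>k</sub>, P<sub>j</sub>)  (i ≠ j),

   so two pathways are coupled in proportion to the GO processes they
   co-occupy.

3. **Eigenvector centrality.** Pathway importance is the principal
   eigenvector of A (shifted power iteration on the largest connected
   component, scores L2-normalised and nonnegative).

4. **Bootstrap significance.** DE magnitudes are resampled with
   replacement and reassigned to the genes (annotation topology fixed),
   the pipeline is rerun B times (default 1000), and each pathway's raw
   p-value is (1 + #{null ≥ observed}) / (B + 1). Adjusted p-values use
   the Westfall–Young / Dudoit–van der Laan step-down max-statistic over
   the joint replicates, controlling the family-wise error rate. Pathways
   with adjusted p ≤ α (default 0.05) are the **latent pathways**.

The package also provides native hypergeometric/Benjamini–Hochberg
overrepresentation (`lpia.enrichment`), thresholded network export for
Cytoscape (edge weight > 0.1 by default; TSV / SIF / GraphML), and a
synthetic-data generator with a planted latent pathway so the whole
pipeline is testable without downloads.

## Worked example

`examples/03_run_lpia.py` generates the default synthetic study (2000
genes, 400 DEGs, 40 pathways, 120 GO terms, planted pathway `P0000`) and
runs the pipeline at B = 200:

```
stage counts: {'deg_total': 2000, 'deg_kept': 400, 'pathways_in': 40,
 'go_terms_in': 120, 'pathways_in_network': 40, 'go_terms_in_network': 119,
 'bipartite_edges': 1953, 'latent_pathways': 1}

top of the centrality ranking:
pathway_id    score    raw_p  adjusted_p component_flag
     P0000 0.499730 0.004975    0.004975      principal
     P0003 0.298668 0.074627    0.333333      principal
     P0028 0.279044 0.059701    0.462687      principal

latent pathways at alpha=0.05: ['P0000']
planted pathway was 'P0000' (15 forced GO links)
```

(Table truncated; run the script for the full output.) The
planted pathway tops the centrality ranking with adjusted p ≈ 0.005 and is
the only latent call; across 20 generator seeds this recovery succeeds in
roughly 19 of 20 runs, while on null scenarios (no planted effect) a false
latent call occurs in about 1 run in 20, consistent with α = 0.05.

The other examples show scenario generation (`01`), classical enrichment
on a 20-gene toy (`02` — a 5-gene set holding 4 of 8 DEGs has rich ratio
0.8 and upper-tail hypergeometric p ≈ 0.058), and network export (`04`).

A `lpia` console script mirrors the library for shell use
(`lpia simulate | enrich | lpia | export`; see `lpia --help`). Every run
directory contains a YAML manifest with input hashes, the resolved
configuration and the seed, and reruns are byte-identical.

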