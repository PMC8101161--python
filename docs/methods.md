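# Methods

## Model and procedure

Latent pathway identification analysis (LPIA) treats a transcriptomic
comparison as three coupled objects: a pathway collection P, a GO
biological-process collection G, and a per-gene differential-expression
magnitude DE_x. Both collections are first intersected with the list of
differentially expressed genes (DEGs) — a pathway or GO term sharing no
DEG leaves the analysis — so all set sizes below count DEGs only. This
restriction is a modelling choice, not just plumbing: the Jaccard factor
then measures how much of the *transcriptional response* two annotations
share, not how much curated overlap they have overall.

The pipeline is:

1. bipartite weight for every (GO term, pathway) pair with a nonempty
   intersection: `W_GP = |G∩P|/|G∪P| * median{DE_x : x in G∩P}`. The
   median of an even-sized multiset is the mean of its two middle values.
2. one-mode projection `A_ij = sum_k W(G_k,P_i) W(G_k,P_j)` for `i != j`,
   diagonal forced to zero, symmetry exact by construction (the upper
   triangle of `WᵀW` is mirrored rather than trusting floating-point
   symmetry).
3. eigenvector centrality of A: the principal eigenvector restricted to
   the largest connected component, L2-normalised; off-component pathways
   score exactly 0 and carry an `off_component` flag.
4. bootstrap significance: B resamples of the DE-magnitude multiset,
   reassigned to the genes with memberships fixed; raw p =
   `(1 + #{null >= obs}) / (B+1)`; adjusted p by step-down max-statistic
   over the joint replicates; latent pathways are those with adjusted
   p <= alpha.

### DE magnitude

DE_x defaults to |log2 fold change|: edge weights should not cancel
between up- and downregulated shared genes, and a pathway's relevance is
indifferent to the direction of its members' response. Signed log2FC and
−log10(q) are available as configuration alternatives
(`LPIAConfig.de_value`) for sensitivity analyses; with the signed variant
a non-positive pair weight simply drops the edge.

### Power iteration

The iteration runs on `A + I`. The shift leaves eigenvectors unchanged,
makes the Perron root strictly dominant in magnitude for any symmetric
nonnegative A (a bipartite-structured component otherwise has −λmax in
its spectrum and the iteration oscillates), and keeps every iterate
strictly positive from the uniform positive start vector. Convergence is
declared when the successive-iterate L2 residual falls below `power_tol`
(default 1e-10, well inside the 1e-8 agreement we verify against a dense
eigendecomposition); `power_max_iter` defaults to 10,000 and
non-convergence is an error reporting the final residual, never a silent
partial answer.

Disconnected networks: centrality is defined on the largest connected
component, ties broken by total edge weight then smallest node index.
This keeps the score vector identifiable; the flags make the restriction
visible downstream.

### Bootstrap null and multiplicity

The resampling unit is the DE magnitude: the observed magnitude multiset
is sampled with replacement and reassigned to the genes of the analysis
universe while every set membership stays fixed. This holds the
annotation topology — set sizes, overlaps, Jaccard factors — constant and
asks whether the observed *placement* of strong fold changes drives a
pathway's centrality more than a random placement would. The alternative
of bootstrapping the DEG list itself (memberships fixed, genes dropping
in and out of intersections) is implemented behind
`LPIAConfig.resample="genes"` for comparison; it perturbs topology as
well as placement and is the harsher null.

Raw p-values use the add-one estimator, so the floor is 1/(B+1) and a
literal zero is never reported; the centrality TSV renders values below
twice that floor as `<floor` alongside the numeric value. Adjusted
p-values use the Westfall–Young free step-down max-statistic computed
from the same joint replicate matrix: hypotheses are ordered by observed
score, each is compared against the replicate-wise maximum over itself
and all lower-ranked hypotheses, and monotonicity is enforced down the
ranking. This controls the family-wise error rate under the joint null
and is what the selection step consumes; Benjamini–Hochberg on the raw
p-values is available as `multiplicity="bh"` for users who prefer FDR
semantics.

"1000 iterations" in this method family refers to bootstrap replicates;
`n_boot` defaults to 1000, and the power-iteration count is an internal
tolerance matter.

## Enrichment stage

The overrepresentation statistic is the upper-tail hypergeometric
probability P(X ≥ k) including the observed count (the semantics of R's
`phyper(k-1, ..., lower.tail=FALSE)`), with Benjamini–Hochberg q-values
computed across the whole collection and inclusive (≤) threshold
comparisons. The background defaults to the union of genes annotated to
at least one set in the tested collection and can be overridden with the
full measured universe; the choice is recorded in the output. The rich
ratio is k/K, candidate DEGs over the set's background genes. Sets with
zero overlap are retained at p = 1 so the BH correction spans the
collection. The DEG filter threshold is configurable and defaults to
q ≤ 0.001, the stricter of the two conventions in circulation for this
pipeline's inputs (q ≤ 0.05 remains a flag away).

## Synthetic scenarios

The generator emulates DE summaries, not reads or counts, because the
pipeline consumes DE summaries. A scenario has `n_genes` measured genes,
an `n_deg` DEG subset with magnitudes |N(0, lfc_null_sd)| (default sd
1.5, a typical strong-contrast log2FC scale), non-DEG magnitudes
|N(0, 0.3)|, and q-values rank-paired to magnitudes within each stratum
(DEGs uniform on (0, 0.001], the rest above), so larger fold changes get
smaller q and the default DEG filter recovers exactly the planted subset.
Pathways draw members from the DEG pool; each GO term takes up to half
its members from a random parent pathway with probability `base_overlap`
(default 0.6) and the rest from the whole universe. One planted pathway
of ordinary size is forced to share 3–6 genes with each of
`planted_go_links` GO terms (default 15 of 120), and those shared genes'
magnitudes are multiplied by `planted_lfc_boost` (default 3). The
defaults are chosen so the planted effect is strong but not trivial:
recovery (selected *and* ranked first) succeeds in roughly 19 of 20
seeds, and drops to near zero when the boost is removed.

What the generator does **not** emulate: correlated fold changes within a
pathway, hierarchical GO structure (parent/child term nesting),
annotation bias toward well-studied genes, and measurement error in the
DE estimates. Passing tests therefore demonstrate that the statistics
behave as designed under a clean planted-signal model, not that any
particular biological dataset will yield a latent pathway.

Because pathway members are drawn entirely from the DEG pool, every
pathway's rich ratio is 1 on synthetic data — which deliberately realises
the method's premise that the planted pathway is *not* distinguishable by
enrichment — and the informative overrepresentation signal lives on the
GO side, whose sets mix DEG and background genes.

## Numerical and design choices

- Exact, case-sensitive gene-id matching; no alias resolution.
- GMT (3+ columns) and two-column long-format gene-set files are
  auto-detected by the first line's column count.
- All thresholds compare inclusively (≤) except the network display
  threshold, which is strictly `>` (an edge of weight exactly 0.1 is
  excluded at the default 0.1).
- Exported files are byte-deterministic: sorted rows, floats at 6
  significant digits, `NA` for missing joins (never fabricated zeros).
- A single integer seed drives all resampling (default 20210505);
  manifests record it together with SHA-256 hashes of the inputs.
- Problem sizes in the test-suite experiments (B = 100–2000, 20 seeds,
  the 4-gene exhaustively enumerable toy) are chosen so each validation
  answers its question at conventional Monte-Carlo precision — e.g. 3·SE
  agreement with exact enumeration at B = 2000, and a binomial 95%
  acceptance band around α for the 20-run familywise-error check.

## Known limitations

- Centrality on a disconnected network ignores cross-component structure;
  pathways off the principal component get score 0 rather than a
  within-component ranking.
- The magnitude-resampling null conditions on the observed annotation
  topology; it does not account for uncertainty in the gene-set
  curations themselves.
- The bootstrap p-value floor 1/(B+1) bounds attainable significance
  after multiplicity adjustment; with B = 1000 and many pathways, maxT
  adjusted p-values below ~0.001 are not resolvable.
- No parallel execution; a full run at default synthetic scale and
  B = 1000 takes a few seconds on one core, and scales roughly linearly
  in B times the number of (GO term, pathway) pairs.
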