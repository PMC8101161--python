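"""Latent pathway identification analysis (LPIA).

The method couples three inputs — a pathway collection P, a GO
biological-process collection G, and per-gene differential-expression (DE)
magnitudes — into a pathway-pathway network and asks which pathways sit at
its centre:

1. every (GO term, pathway) pair sharing at least one DEG receives a
   bipartite edge weight

       W_GP = |G ∩ P| / |G ∪ P| × median{ DE_x : x ∈ G ∩ P },

   the Jaccard overlap of the two DEG-restricted sets scaled by the median
   DE magnitude of the shared genes;

2. the bipartite graph is projected onto pathways,

       A_ij = Σ_k W(G_k, P_i) × W(G_k, P_j)   (i ≠ j),

   so two pathways are tied in proportion to the GO terms they co-occupy;

3. pathway importance is the eigenvector centrality of A (principal
   eigenvector, computed by shifted power iteration on the largest
   connected component);

4. significance is assessed by a bootstrap null: DE magnitudes are
   resampled with replacement and reassigned to the genes while every set
   membership is held fixed, the pipeline is rerun, and each pathway's
   observed centrality is compared with its null distribution.  Adjusted
   p-values use the step-down max-statistic (Westfall-Young / Dudoit-van
   der Laan) correction over the joint bootstrap replicates, which
   controls the family-wise error rate.

A pathway that rises to the top of this ranking without being strongly
enriched itself is a "latent" pathway: its DEGs connect it, through shared
biological-process annotations, to the transcriptional response at large.
"""
from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml
from scipy.sparse import csr_array
from scipy.sparse.csgraph import connected_components

from .errors import ConfigError, DataError, LPIAError
from .genesets import (
    DEGTable,
    GeneSetCollection,
    filter_degs,
    read_deg_table,
    read_gene_sets,
    restrict_to_universe,
)

logger = logging.getLogger(__name__)

PRINCIPAL = "principal"
OFF_COMPONENT = "off_component"


@dataclass
class LPIAConfig:
    """Tunable parameters of an LPIA run.

    Defaults follow the method family's conventional settings: 1000
    bootstrap replicates, a 0.1 edge-weight display threshold, and a 0.05
    family-wise significance level.
    """

    n_boot: int = 1000
    edge_threshold: float = 0.1
    alpha: float = 0.05
    power_tol: float = 1e-10
    power_max_iter: int = 10_000
    seed: int = 20210505
    #: DE magnitude attached to each gene: "abs_log2fc" (default),
    #: "signed_log2fc" or "neg_log10_q"
    de_value: str = "abs_log2fc"
    #: bootstrap unit: "magnitudes" (resample the DE-magnitude multiset and
    #: reassign to genes) or "genes" (resample the DEG list itself)
    resample: str = "magnitudes"
    #: multiplicity correction: "maxT" (step-down max-statistic) or "bh"
    multiplicity: str = "maxT"

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ConfigError(f"n_boot must be >= 1, got {self.n_boot}")
        if self.edge_threshold < 0:
            raise ConfigError(f"edge_threshold must be >= 0, got {self.edge_threshold}")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.de_value not in ("abs_log2fc", "signed_log2fc", "neg_log10_q"):
            raise ConfigError(f"unknown de_value {self.de_value!r}")
        if self.resample not in ("magnitudes", "genes"):
            raise ConfigError(f"unknown resample mode {self.resample!r}")
        if self.multiplicity not in ("maxT", "bh"):
            raise ConfigError(f"unknown multiplicity mode {self.multiplicity!r}")


@dataclass
class BipartiteWeightMatrix:
    """Sparse (GO term, pathway) -> W_GP weights; absent pair means no edge."""

    go_ids: list[str]
    pathway_ids: list[str]
    entries: dict[tuple[str, str], float]

    def to_array(self) -> np.ndarray:
        """Dense (n_go, n_pathway) weight matrix, zeros for absent pairs."""
        gi = {g: i for i, g in enumerate(self.go_ids)}
        pi = {p: i for i, p in enumerate(self.pathway_ids)}
        out = np.zeros((len(self.go_ids), len(self.pathway_ids)))
        for (g, p), w in self.entries.items():
            out[gi[g], pi[p]] = w
        return out


@dataclass
class PathwayNetwork:
    """Symmetric pathway-pathway weight matrix with zero diagonal."""

    pathway_ids: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.weights, dtype=float)
        if a.shape != (len(self.pathway_ids),) * 2:
            raise DataError("weights shape does not match pathway_ids")
        if not np.array_equal(a, a.T):
            raise DataError("pathway network matrix is not symmetric")
        if np.any(np.diag(a) != 0):
            raise DataError("pathway network diagonal must be zero")
        if np.any(a < 0):
            raise DataError("pathway network weights must be nonnegative")
        self.weights = a

    @property
    def n(self) -> int:
        return len(self.pathway_ids)


@dataclass
class CentralityResult:
    """Per-pathway eigenvector centrality with bootstrap significance."""

    pathway_ids: list[str]
    scores: dict[str, float]
    raw_p: dict[str, float]
    adjusted_p: dict[str, float]
    n_boot: int
    seed: int
    component_flag: dict[str, str]

    def to_frame(self):
        import pandas as pd

        rows = sorted(
            self.pathway_ids,
            key=lambda p: (-self.scores[p], p),
        )
        return pd.DataFrame(
            {
                "pathway_id": rows,
                "score": [self.scores[p] for p in rows],
                "raw_p": [self.raw_p[p] for p in rows],
                "adjusted_p": [self.adjusted_p[p] for p in rows],
                "component_flag": [self.component_flag[p] for p in rows],
            }
        )


# ---------------------------------------------------------------------------
# bipartite weighting and projection


def _de_values(degs: DEGTable, mode: str) -> dict[str, float]:
    if mode == "abs_log2fc":
        return {g: abs(r.log2fc) for g, r in degs.records.items()}
    if mode == "signed_log2fc":
        return {g: r.log2fc for g, r in degs.records.items()}
    if mode == "neg_log10_q":
        return {g: -np.log10(max(r.qvalue, 1e-300)) for g, r in degs.records.items()}
    raise ConfigError(f"unknown de_value {mode!r}")


class _BipartiteStructure:
    """Fixed annotation topology of a run, separated from the DE magnitudes.

    Intersections, unions and Jaccard factors depend only on the gene-set
    memberships, so they are computed once; each bootstrap replicate only
    re-evaluates the per-pair medians against a new magnitude vector.
    """

    def __init__(self, P: GeneSetCollection, G: GeneSetCollection, degs: DEGTable,
                 de_value: str = "abs_log2fc") -> None:
        self.pathway_ids = sorted(P.sets)
        self.go_ids = sorted(G.sets)
        values = _de_values(degs, de_value)
        universe: set[str] = set()
        for coll in (P, G):
            for gs in coll:
                universe |= gs.members
        missing = universe - set(values)
        if missing:
            raise DataError(
                f"gene(s) without a DE record, e.g. {sorted(missing)[:3]} — "
                "restrict collections to the DEG universe first"
            )
        self.gene_ids = sorted(universe)
        gidx = {g: i for i, g in enumerate(self.gene_ids)}
        self.magnitudes = np.array([values[g] for g in self.gene_ids])

        pair_go: list[int] = []
        pair_path: list[int] = []
        pair_jaccard: list[float] = []
        pair_members: list[np.ndarray] = []
        pmembers = [frozenset(P[p].members) for p in self.pathway_ids]
        for gi, go_id in enumerate(self.go_ids):
            gset = G[go_id].members
            for pi, pset in enumerate(pmembers):
                inter = gset & pset
                if not inter:
                    continue
                union = len(gset | pset)
                pair_go.append(gi)
                pair_path.append(pi)
                pair_jaccard.append(len(inter) / union)
                pair_members.append(
                    np.fromiter((gidx[g] for g in sorted(inter)), dtype=np.intp)
                )
        self.pair_go = np.asarray(pair_go, dtype=np.intp)
        self.pair_path = np.asarray(pair_path, dtype=np.intp)
        self.pair_jaccard = np.asarray(pair_jaccard)
        self.pair_members = pair_members
        # pairs grouped by intersection size for vectorised medians
        self._groups: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        sizes = np.array([len(m) for m in pair_members], dtype=np.intp)
        for s in np.unique(sizes):
            which = np.nonzero(sizes == s)[0]
            idx = np.stack([pair_members[i] for i in which]) if s else None
            self._groups[int(s)] = (which, idx)

    @property
    def n_pairs(self) -> int:
        return len(self.pair_jaccard)

    def pair_weights(self, magnitudes: np.ndarray) -> np.ndarray:
        """W_GP values for every stored pair under a gene-magnitude vector."""
        vals = np.empty(self.n_pairs)
        for _, (which, idx) in self._groups.items():
            vals[which] = self.pair_jaccard[which] * np.median(magnitudes[idx], axis=1)
        return vals

    def adjacency(self, pair_vals: np.ndarray) -> np.ndarray:
        """Project pair weights to the symmetric pathway-pathway matrix."""
        W = np.zeros((len(self.go_ids), len(self.pathway_ids)))
        W[self.pair_go, self.pair_path] = pair_vals
        A = W.T @ W
        A = np.triu(A, k=1)
        return A + A.T


def build_bipartite(
    P: GeneSetCollection, G: GeneSetCollection, degs: DEGTable,
    de_value: str = "abs_log2fc",
) -> BipartiteWeightMatrix:
    """Compute W_GP for every (GO term, pathway) pair sharing >= 1 gene.

    Both collections must already be restricted to the DEG universe: a set
    member without a DE record raises, naming the gene.  Pairs whose
    weight is not strictly positive are omitted (with the default absolute
    log2-fold-change magnitude this only happens for genes with log2fc
    exactly zero).
    """
    s = _BipartiteStructure(P, G, degs, de_value)
    vals = s.pair_weights(s.magnitudes)
    entries = {
        (s.go_ids[g], s.pathway_ids[p]): float(v)
        for g, p, v in zip(s.pair_go, s.pair_path, vals)
        if v > 0
    }
    return BipartiteWeightMatrix(go_ids=s.go_ids, pathway_ids=s.pathway_ids,
                                 entries=entries)


def project(W: BipartiteWeightMatrix) -> PathwayNetwork:
    """One-mode projection A_ij = Σ_k W(G_k, P_i) W(G_k, P_j), zero diagonal.

    Pathways without any bipartite edge are retained as isolated nodes.
    """
    if not W.entries:
        raise DataError("bipartite weight matrix has no entries")
    M = W.to_array()
    A = M.T @ M
    A = np.triu(A, k=1)
    return PathwayNetwork(pathway_ids=list(W.pathway_ids), weights=A + A.T)


# ---------------------------------------------------------------------------
# eigenvector centrality


def _principal_component(A: np.ndarray) -> np.ndarray:
    """Boolean mask of the largest connected component of the nonzero graph.

    Isolated nodes (zero rows) form singleton components and never win
    unless the whole graph is edgeless.  Ties on size are broken by total
    within-component edge weight, then by the smallest node index.
    """
    n = A.shape[0]
    ncomp, labels = connected_components(csr_array(A != 0), directed=False)
    best: tuple[int, float, int] | None = None
    best_label = 0
    for lab in range(ncomp):
        mask = labels == lab
        size = int(mask.sum())
        weight = float(A[np.ix_(mask, mask)].sum())
        first = int(np.nonzero(mask)[0][0])
        key = (size, weight, -first)
        if best is None or key > best:
            best = key
            best_label = lab
    return labels == best_label


def _power_iteration(M: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    n = M.shape[0]
    v = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        w = M @ v
        nw = np.linalg.norm(w)
        if nw == 0:
            raise LPIAError("power iteration collapsed to the zero vector")
        w /= nw
        resid = float(np.linalg.norm(w - v))
        v = w
        if resid <= tol:
            return v
    raise LPIAError(
        f"power iteration did not converge after {max_iter} iterations "
        f"(final residual {resid:.3e})"
    )


def _centrality_array(A: np.ndarray, tol: float, max_iter: int) -> tuple[np.ndarray, np.ndarray]:
    """Centrality scores and principal-component mask for a weight matrix.

    Scores are the principal eigenvector of A restricted to the largest
    connected component, L2-normalised and nonnegative; other nodes score
    exactly zero.  Iterating on A + I keeps convergence monotone for
    symmetric nonnegative matrices (the shift moves every eigenvalue by +1
    without touching eigenvectors, so the Perron root strictly dominates
    in magnitude and ±λ oscillation cannot occur).
    """
    if not np.any(A):
        raise DataError("pathway network has no edges")
    mask = _principal_component(A)
    sub = A[np.ix_(mask, mask)]
    v = _power_iteration(sub + np.eye(sub.shape[0]), tol, max_iter)
    scores = np.zeros(A.shape[0])
    scores[mask] = np.abs(v)  # Perron vector is nonnegative; guard rounding
    return scores, mask


def eigenvector_centrality(
    net: PathwayNetwork, tol: float = 1e-10, max_iter: int = 10_000
) -> dict[str, float]:
    """Eigenvector-centrality scores keyed by pathway id.

    Deterministic for a fixed network; raises on an edgeless network or if
    the power iteration fails to reach ``tol`` within ``max_iter``.
    """
    scores, _ = _centrality_array(net.weights, tol, max_iter)
    return dict(zip(net.pathway_ids, (float(s) for s in scores)))


def component_flags(net: PathwayNetwork) -> dict[str, str]:
    """Label each pathway ``principal`` or ``off_component``."""
    mask = _principal_component(net.weights)
    return {
        p: (PRINCIPAL if m else OFF_COMPONENT)
        for p, m in zip(net.pathway_ids, mask)
    }


# ---------------------------------------------------------------------------
# bootstrap significance


def _null_scores_magnitudes(
    s: _BipartiteStructure, cfg: LPIAConfig, rng: np.random.Generator
) -> np.ndarray:
    """Null centralities under magnitude resampling (memberships fixed)."""
    B = cfg.n_boot
    n_genes = len(s.gene_ids)
    out = np.empty((B, len(s.pathway_ids)))
    for b in range(B):
        mags = rng.choice(s.magnitudes, size=n_genes, replace=True)
        A = s.adjacency(s.pair_weights(mags))
        out[b], _ = _centrality_array(A, cfg.power_tol, cfg.power_max_iter)
    return out


def _null_scores_genes(
    s: _BipartiteStructure, cfg: LPIAConfig, rng: np.random.Generator
) -> np.ndarray:
    """Null centralities under gene resampling: the DEG list itself is
    bootstrapped, magnitudes stay attached to their genes, and set members
    absent from a replicate drop out of the intersections."""
    B = cfg.n_boot
    n_genes = len(s.gene_ids)
    out = np.zeros((B, len(s.pathway_ids)))
    for b in range(B):
        present = np.zeros(n_genes, dtype=bool)
        present[rng.integers(0, n_genes, size=n_genes)] = True
        vals = np.zeros(s.n_pairs)
        for i, members in enumerate(s.pair_members):
            kept = members[present[members]]
            if kept.size:
                vals[i] = s.pair_jaccard[i] * np.median(s.magnitudes[kept])
        A = s.adjacency(vals)
        if not np.any(A):
            continue  # degenerate replicate: every pathway scores zero
        out[b], _ = _centrality_array(A, cfg.power_tol, cfg.power_max_iter)
    return out


def _maxt_stepdown(obs: np.ndarray, null: np.ndarray, ids: list[str]) -> np.ndarray:
    """Westfall-Young free step-down max-statistic adjusted p-values.

    Pathways are ordered by decreasing observed score (ties by id);
    successive maxima of the null scores are taken from the bottom of the
    ranking up, each adjusted p compares the observed score with the
    replicate-wise max over the pathway and everything ranked below it,
    and monotonicity is enforced down the ranking.
    """
    B = null.shape[0]
    order = sorted(range(len(obs)), key=lambda i: (-obs[i], ids[i]))
    null_ord = null[:, order]
    succ_max = np.maximum.accumulate(null_ord[:, ::-1], axis=1)[:, ::-1]
    p_tilde = (1 + (succ_max >= obs[order]).sum(axis=0)) / (B + 1)
    p_adj_ord = np.maximum.accumulate(p_tilde)
    p_adj = np.empty_like(p_adj_ord)
    p_adj[order] = p_adj_ord
    return p_adj


def bootstrap_significance(
    P: GeneSetCollection,
    G: GeneSetCollection,
    degs: DEGTable,
    cfg: LPIAConfig | None = None,
) -> CentralityResult:
    """Observed centralities with bootstrap raw and adjusted p-values.

    Raw p-values use the add-one estimator (1 + #{null >= observed}) /
    (B + 1), so the smallest reportable value is 1/(B + 1), never zero.
    Adjusted p-values use the step-down max-statistic over the joint null
    replicates (FWER control) by default, or Benjamini-Hochberg when
    ``cfg.multiplicity == "bh"``.
    """
    cfg = cfg or LPIAConfig()
    s = _BipartiteStructure(P, G, degs, cfg.de_value)
    if s.n_pairs == 0:
        raise DataError("no (GO term, pathway) pair shares a DEG")
    connected = np.unique(s.pair_path)
    if connected.size < 2:
        raise DataError(
            "degenerate universe: fewer than 2 pathways carry bipartite edges"
        )
    obs_A = s.adjacency(s.pair_weights(s.magnitudes))
    obs, mask = _centrality_array(obs_A, cfg.power_tol, cfg.power_max_iter)

    rng = np.random.default_rng(cfg.seed)
    if cfg.resample == "magnitudes":
        null = _null_scores_magnitudes(s, cfg, rng)
    else:
        null = _null_scores_genes(s, cfg, rng)

    B = cfg.n_boot
    raw = (1 + (null >= obs).sum(axis=0)) / (B + 1)
    if cfg.multiplicity == "maxT":
        adj = _maxt_stepdown(obs, null, s.pathway_ids)
    else:
        from .enrichment import bh_adjust

        adj = np.maximum(bh_adjust(raw), raw)
    ids = s.pathway_ids
    return CentralityResult(
        pathway_ids=list(ids),
        scores={p: float(v) for p, v in zip(ids, obs)},
        raw_p={p: float(v) for p, v in zip(ids, raw)},
        adjusted_p={p: float(v) for p, v in zip(ids, adj)},
        n_boot=B,
        seed=cfg.seed,
        component_flag={
            p: (PRINCIPAL if m else OFF_COMPONENT) for p, m in zip(ids, mask)
        },
    )


def select_latent(result: CentralityResult, alpha: float = 0.05) -> list[str]:
    """Pathways with adjusted p <= alpha, ranked by descending centrality.

    Ties on the score are broken by ascending pathway id.  An empty list is
    a legal outcome (e.g. when alpha is below 1/(B+1)).
    """
    if not (0.0 < alpha < 1.0):
        raise ConfigError(f"alpha must be in (0, 1), got {alpha}")
    hits = [p for p in result.pathway_ids if result.adjusted_p[p] <= alpha]
    return sorted(hits, key=lambda p: (-result.scores[p], p))


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass
class LPIARun:
    """Everything a full run produces: scores, network, and provenance."""

    result: CentralityResult
    network: PathwayNetwork
    bipartite: BipartiteWeightMatrix
    manifest: dict = field(default_factory=dict)


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, LPIAError):
                exc.args = (f"stage {name!r}: {exc.args[0]}",) + exc.args[1:]
            return False

    return _Ctx()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_from_objects(
    P: GeneSetCollection,
    G: GeneSetCollection,
    degs: DEGTable,
    cfg: LPIAConfig | None = None,
    deg_q_threshold: float = 0.001,
) -> LPIARun:
    """Run the LPIA pipeline on in-memory inputs.

    Composes DEG filtering, universe restriction, bipartite weighting,
    projection, and bootstrap significance.  The manifest records the
    object counts entering and leaving each stage.
    """
    cfg = cfg or LPIAConfig()
    with _stage("filter_degs"):
        kept = filter_degs(degs, deg_q_threshold)
        if len(kept) == 0:
            raise DataError(f"no DEG passes q <= {deg_q_threshold}")
    with _stage("restrict_to_universe"):
        P_r = restrict_to_universe(P, kept.gene_ids)
        G_r = restrict_to_universe(G, kept.gene_ids)
    with _stage("build_bipartite"):
        W = build_bipartite(P_r, G_r, kept, cfg.de_value)
    with _stage("project"):
        net = project(W)
    with _stage("bootstrap_significance"):
        result = bootstrap_significance(P_r, G_r, kept, cfg)
    latent = select_latent(result, cfg.alpha)
    manifest = {
        "config": asdict(cfg),
        "counts": {
            "deg_total": len(degs),
            "deg_kept": len(kept),
            "pathways_in": len(P),
            "go_terms_in": len(G),
            "pathways_in_network": len(P_r),
            "go_terms_in_network": len(G_r),
            "bipartite_edges": len(W.entries),
            "latent_pathways": len(latent),
        },
        "deg_q_threshold": deg_q_threshold,
        "latent_pathways": latent,
    }
    logger.info(
        "LPIA: %d/%d DEGs kept; %d pathways and %d GO terms enter the network; "
        "%d bipartite edges; %d latent pathway(s)",
        len(kept), len(degs), len(P_r), len(G_r), len(W.entries), len(latent),
    )
    return LPIARun(result=result, network=net, bipartite=W, manifest=manifest)


def run_lpia(
    pathways_path: str | Path,
    go_path: str | Path,
    deg_path: str | Path,
    cfg: LPIAConfig | None = None,
    deg_q_threshold: float = 0.001,
    column_map: Mapping[str, str] | None = None,
    out_dir: str | Path | None = None,
) -> LPIARun:
    """File-based entry point: read inputs, run the pipeline, write outputs.

    When ``out_dir`` is given, a centrality TSV and a YAML run manifest
    (input paths with SHA-256 hashes, resolved configuration, stage counts,
    seed) are written there; reruns with identical inputs and seed produce
    byte-identical files.
    """
    cfg = cfg or LPIAConfig()
    with _stage("read_inputs"):
        P = read_gene_sets(pathways_path, "KEGG")
        G = read_gene_sets(go_path, "GO_BP")
        degs = read_deg_table(deg_path, column_map)
    run = run_from_objects(P, G, degs, cfg, deg_q_threshold)
    run.manifest["inputs"] = {
        "pathways": {"path": str(pathways_path), "sha256": _sha256(Path(pathways_path))},
        "go_terms": {"path": str(go_path), "sha256": _sha256(Path(go_path))},
        "deg_table": {"path": str(deg_path), "sha256": _sha256(Path(deg_path))},
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_centrality(run.result, out_dir / "centrality.tsv")
        with (out_dir / "manifest.yaml").open("w") as fh:
            yaml.safe_dump(run.manifest, fh, sort_keys=True)
    return run


def write_centrality(result: CentralityResult, path: str | Path) -> None:
    """Write the per-pathway centrality table as TSV, best score first.

    Values below twice the estimator floor 1/(B+1) are additionally
    rendered as "<floor" in a display column, since a resampling p-value
    of exactly zero is never reported.
    """
    floor = 1.0 / (result.n_boot + 1)
    df = result.to_frame()
    df["raw_p_display"] = [
        f"<{2 * floor:.3g}" if v < 2 * floor else f"{v:.6g}" for v in df["raw_p"]
    ]
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
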