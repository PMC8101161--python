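"""Synthetic gene universes with a planted latent pathway.

The generator emulates the inputs of a latent-pathway analysis: a gene
universe with a differentially expressed subset, overlapping pathway and
GO-term annotations with controllable co-membership, and one planted
pathway whose GO-mediated connectivity — not its raw enrichment — is
elevated.  Pathways draw their members from the DEG pool; each GO term
draws part of its members from a randomly chosen "parent" pathway with
probability ``base_overlap`` and the rest from the whole universe, which
produces the GO-mediated pathway-pathway coupling the method detects.

The planted pathway is ordinary in size and in the fraction of its genes
that are DEGs, but ``planted_go_links`` GO terms are forced to share a few
genes with it and those shared genes carry fold-change magnitudes
multiplied by ``planted_lfc_boost``.  This realises the premise of latent
pathway identification: a pathway that standard overrepresentation ranks
unremarkably can still dominate the pathway-pathway network.

All randomness flows from the single scenario seed; two calls with the
same seed produce bit-identical outputs.
"""
from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import LPIAConfig, LPIARun, run_from_objects, select_latent
from .errors import ConfigError
from .genesets import (
    Category,
    DEGRecord,
    DEGTable,
    GeneSet,
    GeneSetCollection,
    write_deg_table,
    write_gmt,
)

#: q-value ceiling assigned to simulated DEGs; matches the pipeline's
#: default DEG filter so the planted subset is exactly what survives it
DEG_Q_MAX = 0.001


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one simulated study.

    Defaults describe a mid-sized transcriptome screen: 2000 measured
    genes of which 400 are differentially expressed, 40 pathways of 10-40
    DEGs each, 120 GO terms of 8-30 genes, and a planted pathway linked to
    15 GO terms through shared genes whose |log2 fold change| is tripled
    relative to the null magnitude scale (|N(0, 1.5)|).
    """

    n_genes: int = 2000
    n_deg: int = 400
    n_pathways: int = 40
    n_go: int = 120
    pathway_size_range: tuple[int, int] = (10, 40)
    go_size_range: tuple[int, int] = (8, 30)
    base_overlap: float = 0.6
    lfc_null_sd: float = 1.5
    planted_id: str = "P0000"
    planted_go_links: int = 15
    planted_lfc_boost: float = 3.0
    seed: int = 1

    def validate(self) -> None:
        if self.n_deg > self.n_genes:
            raise ConfigError(f"n_deg={self.n_deg} exceeds n_genes={self.n_genes}")
        for label, (lo, hi) in (
            ("pathway_size_range", self.pathway_size_range),
            ("go_size_range", self.go_size_range),
        ):
            if not (0 < lo <= hi):
                raise ConfigError(f"{label}={lo, hi} must be positive and ordered")
            if hi > self.n_deg:
                raise ConfigError(f"{label} upper bound {hi} exceeds n_deg={self.n_deg}")
        if not (0.0 <= self.base_overlap <= 1.0):
            raise ConfigError(f"base_overlap must be in [0, 1], got {self.base_overlap}")
        if self.planted_go_links > self.n_go:
            raise ConfigError(
                f"planted_go_links={self.planted_go_links} exceeds n_go={self.n_go}"
            )
        if self.planted_go_links < 0 or self.planted_lfc_boost <= 0:
            raise ConfigError("planted parameters must be nonnegative / positive")
        if self.lfc_null_sd <= 0:
            raise ConfigError(f"lfc_null_sd must be > 0, got {self.lfc_null_sd}")


@dataclass
class ScenarioTruth:
    """Ground truth of a generated scenario."""

    planted_id: str
    realized_go_links: int
    overlap_genes: dict[str, list[str]]


def _rank_paired(rng: np.random.Generator, magnitudes: np.ndarray,
                 low: float, high: float) -> np.ndarray:
    """Uniform(low, high] draws assigned so larger magnitude gets smaller q."""
    q = np.sort(low + (high - low) * rng.random(magnitudes.size))
    order = np.argsort(-magnitudes, kind="stable")
    out = np.empty_like(q)
    out[order] = q
    return out


def generate(
    scn: SyntheticScenario,
) -> tuple[GeneSetCollection, GeneSetCollection, DEGTable, ScenarioTruth]:
    """Generate (pathways, GO terms, DEG table, truth) for a scenario."""
    scn.validate()
    rng = np.random.default_rng(scn.seed)
    genes = np.array([f"g{i:05d}" for i in range(scn.n_genes)])
    deg_idx = rng.choice(scn.n_genes, size=scn.n_deg, replace=False)
    is_deg = np.zeros(scn.n_genes, dtype=bool)
    is_deg[deg_idx] = True
    deg_genes = genes[deg_idx]

    mags = np.empty(scn.n_genes)
    mags[is_deg] = np.abs(rng.normal(0.0, scn.lfc_null_sd, size=scn.n_deg))
    mags[~is_deg] = np.abs(rng.normal(0.0, 0.3, size=scn.n_genes - scn.n_deg))
    signs = rng.choice([-1.0, 1.0], size=scn.n_genes)

    # pathways: members drawn from the DEG pool
    lo, hi = scn.pathway_size_range
    P = GeneSetCollection(category=Category.KEGG)
    pathway_members: dict[str, np.ndarray] = {}
    for i in range(scn.n_pathways):
        pid = f"P{i:04d}"
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(deg_genes, size=size, replace=False)
        pathway_members[pid] = members
        P.add(GeneSet(set_id=pid, name=f"pathway {i}", category=Category.KEGG,
                      members=frozenset(map(str, members))))
    planted_active = scn.planted_go_links > 0 or scn.planted_lfc_boost != 1.0
    if planted_active and scn.planted_id not in pathway_members:
        raise ConfigError(f"planted_id {scn.planted_id!r} is not a generated pathway id")

    # GO terms: part parent pathway, part global pool
    glo, ghi = scn.go_size_range
    go_members: dict[str, set[str]] = {}
    for i in range(scn.n_go):
        gid = f"G{i:04d}"
        size = int(rng.integers(glo, ghi + 1))
        picked: list[str] = []
        if rng.random() < scn.base_overlap:
            parent = pathway_members[f"P{int(rng.integers(scn.n_pathways)):04d}"]
            take = min(size // 2, len(parent))
            picked.extend(rng.choice(parent, size=take, replace=False))
        while len(picked) < size:
            cand = rng.choice(genes, size=size - len(picked), replace=False)
            have = set(picked)
            picked.extend(g for g in cand if g not in have)
        go_members[gid] = set(picked)

    # force GO links onto the planted pathway and boost the shared genes
    truth_overlaps: dict[str, list[str]] = {}
    boosted: set[str] = set()
    if scn.planted_go_links > 0:
        planted = pathway_members[scn.planted_id]
        link_ids = rng.choice(scn.n_go, size=scn.planted_go_links, replace=False)
        for i in sorted(int(x) for x in link_ids):
            gid = f"G{i:04d}"
            o = int(rng.integers(3, min(7, len(planted)) + 1))
            overlap = set(rng.choice(planted, size=o, replace=False))
            members = go_members[gid]
            # swap in the overlap, evicting non-overlap members to keep size
            target = len(members)
            surplus = len(members | overlap) - target
            if surplus > 0:
                evictable = sorted(members - overlap)
                evict = rng.choice(len(evictable), size=min(surplus, len(evictable)),
                                   replace=False)
                members -= {evictable[j] for j in evict}
            members |= overlap
            go_members[gid] = members
            truth_overlaps[gid] = sorted(str(g) for g in overlap)
            boosted |= overlap
        gene_pos = {g: i for i, g in enumerate(genes)}
        for g in boosted:
            mags[gene_pos[g]] *= scn.planted_lfc_boost

    G = GeneSetCollection(category=Category.GO_BP)
    for gid in sorted(go_members):
        G.add(GeneSet(set_id=gid, name=f"process {int(gid[1:])}",
                      category=Category.GO_BP, members=frozenset(map(str, go_members[gid]))))

    # q-values rank-paired to the final magnitudes within each stratum
    qvals = np.empty(scn.n_genes)
    qvals[is_deg] = _rank_paired(rng, mags[is_deg], 0.0, DEG_Q_MAX)
    qvals[~is_deg] = _rank_paired(rng, mags[~is_deg], DEG_Q_MAX * 1.2, 1.0)
    records = {
        g: DEGRecord(gene_id=g, log2fc=float(signs[i] * mags[i]),
                     pvalue=float(qvals[i] / 2), qvalue=float(qvals[i]))
        for i, g in enumerate(genes)
    }
    table = DEGTable(records=records, background=frozenset(genes))
    truth = ScenarioTruth(
        planted_id=scn.planted_id,
        realized_go_links=len(truth_overlaps),
        overlap_genes=truth_overlaps,
    )
    return P, G, table, truth


def null_scenario(
    scn: SyntheticScenario,
) -> tuple[GeneSetCollection, GeneSetCollection, DEGTable, ScenarioTruth]:
    """Same generator with the planted effect switched off (boost 1, links 0)."""
    return generate(dataclasses.replace(scn, planted_lfc_boost=1.0, planted_go_links=0))


def write_scenario(scn: SyntheticScenario, out_dir: str | Path) -> dict[str, Path]:
    """Generate a scenario and write it in the formats the readers accept.

    Emits ``pathways.gmt``, ``go_bp.gmt``, ``degs.tsv`` and ``truth.yaml``
    into ``out_dir``; returns the paths keyed by role.
    """
    P, G, table, truth = generate(scn)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pathways": out_dir / "pathways.gmt",
        "go_terms": out_dir / "go_bp.gmt",
        "deg_table": out_dir / "degs.tsv",
        "truth": out_dir / "truth.yaml",
    }
    write_gmt(P, paths["pathways"])
    write_gmt(G, paths["go_terms"])
    write_deg_table(table, paths["deg_table"])
    with paths["truth"].open("w") as fh:
        yaml.safe_dump(
            {
                "scenario": dataclasses.asdict(scn),
                "planted_id": truth.planted_id,
                "realized_go_links": truth.realized_go_links,
                "overlap_genes": truth.overlap_genes,
            },
            fh, sort_keys=True,
        )
    return paths


# ---------------------------------------------------------------------------
# recovery experiments


def recovery_run(
    scn: SyntheticScenario,
    cfg: LPIAConfig,
    deg_q_threshold: float = DEG_Q_MAX,
) -> tuple[bool, int, float, LPIARun]:
    """Run the pipeline on one scenario and score planted-pathway recovery.

    Returns (selected, rank, adjusted_p, run): whether the planted pathway
    is called latent at ``cfg.alpha``, its 1-based rank by descending
    centrality, and its adjusted p-value.
    """
    P, G, table, truth = generate(scn)
    run = run_from_objects(P, G, table, cfg, deg_q_threshold)
    result = run.result
    ranked = sorted(result.pathway_ids, key=lambda p: (-result.scores[p], p))
    rank = ranked.index(truth.planted_id) + 1 if truth.planted_id in ranked else -1
    selected = truth.planted_id in select_latent(result, cfg.alpha)
    return selected, rank, result.adjusted_p.get(truth.planted_id, 1.0), run


def sweep(
    base: SyntheticScenario,
    grid: dict[str, Sequence],
    seeds: Iterable[int],
    cfg: LPIAConfig | None = None,
    out_path: str | Path | None = None,
) -> pd.DataFrame:
    """Planted-recovery frequency over a grid of scenario parameters.

    ``grid`` maps :class:`SyntheticScenario` field names to value lists;
    every cell of the cartesian product is run once per seed (the seed
    drives both the generator and the bootstrap).  Returns one row per
    cell with ``recovery_freq`` (fraction of seeds where the planted
    pathway is selected and ranked first) , ``selected_freq`` and
    ``mean_rank``; optionally written as TSV.
    """
    cfg = cfg or LPIAConfig()
    seeds = list(seeds)
    names = list(grid)
    rows = []
    for combo in itertools.product(*(grid[n] for n in names)):
        cell = dict(zip(names, combo))
        selected_n = first_n = 0
        ranks = []
        for seed in seeds:
            scn = dataclasses.replace(base, seed=seed, **cell)
            run_cfg = dataclasses.replace(cfg, seed=seed)
            selected, rank, _, _ = recovery_run(scn, run_cfg)
            selected_n += selected
            first_n += selected and rank == 1
            ranks.append(rank)
        rows.append({
            **cell,
            "n_seeds": len(seeds),
            "selected_freq": selected_n / len(seeds),
            "recovery_freq": first_n / len(seeds),
            "mean_rank": float(np.mean(ranks)),
        })
    df = pd.DataFrame(rows)
    if out_path is not None:
        df.to_csv(out_path, sep="\t", index=False, float_format="%.6g")
    return df
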