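"""Gene-set collections and differential-expression tables.

Containers and readers for the three inputs of a latent-pathway analysis:
a KEGG-pathway collection ``P``, a GO biological-process collection ``G``,
and a table of differentially expressed genes (DEGs) carrying signed
log2 fold changes and FDR-adjusted p-values.  Gene identifiers are matched
by exact, case-sensitive string equality throughout; no alias resolution
is attempted.
"""
from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .errors import ConfigError, DataError, ParseError

logger = logging.getLogger(__name__)

#: default column-name mapping for :func:`read_deg_table`
DEFAULT_DEG_COLUMNS = {
    "gene_id": "gene_id",
    "log2fc": "log2fc",
    "pvalue": "pvalue",
    "qvalue": "qvalue",
}


class Category(str, enum.Enum):
    """Annotation source of a gene-set collection."""

    KEGG = "KEGG"
    GO_BP = "GO_BP"


@dataclass(frozen=True)
class GeneSet:
    """One annotation term (a pathway or a GO term) with its member genes."""

    set_id: str
    name: str
    category: Category
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.set_id:
            raise DataError("gene set with empty set_id")
        if not self.members:
            raise DataError(f"gene set {self.set_id!r} has no members")
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    """A keyed collection of :class:`GeneSet` sharing one category."""

    category: Category
    sets: dict[str, GeneSet] = field(default_factory=dict)

    def add(self, gs: GeneSet) -> None:
        if gs.category != self.category:
            raise DataError(
                f"set {gs.set_id!r} has category {gs.category.value}, "
                f"collection expects {self.category.value}"
            )
        if gs.set_id in self.sets:
            raise DataError(f"duplicate set_id {gs.set_id!r}")
        self.sets[gs.set_id] = gs

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets.values())

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets

    def __getitem__(self, set_id: str) -> GeneSet:
        return self.sets[set_id]

    @property
    def ids(self) -> list[str]:
        return list(self.sets)

    def all_genes(self) -> frozenset[str]:
        """Union of member genes over every stored set."""
        out: set[str] = set()
        for gs in self:
            out |= gs.members
        return frozenset(out)


class Direction(str, enum.Enum):
    UP = "up"
    DOWN = "down"


@dataclass(frozen=True)
class DEGRecord:
    """One gene's differential-expression summary."""

    gene_id: str
    log2fc: float
    pvalue: float
    qvalue: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.log2fc):
            raise DataError(f"gene {self.gene_id!r}: non-finite log2fc")
        for label, v in (("pvalue", self.pvalue), ("qvalue", self.qvalue)):
            if not (0.0 <= v <= 1.0):
                raise DataError(f"gene {self.gene_id!r}: {label}={v} outside [0, 1]")

    @property
    def direction(self) -> Direction:
        return Direction.UP if self.log2fc >= 0 else Direction.DOWN


@dataclass
class DEGTable:
    """Differential-expression records keyed by gene id.

    ``background``, when given, is the full measured-gene universe and must
    be a superset of the recorded genes.
    """

    records: dict[str, DEGRecord] = field(default_factory=dict)
    background: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.background is not None:
            self.background = frozenset(self.background)
            missing = set(self.records) - self.background
            if missing:
                raise DataError(
                    f"{len(missing)} DEG record(s) absent from background, "
                    f"e.g. {sorted(missing)[:3]}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.records

    def __getitem__(self, gene_id: str) -> DEGRecord:
        return self.records[gene_id]

    @property
    def gene_ids(self) -> frozenset[str]:
        return frozenset(self.records)

    def magnitudes(self) -> dict[str, float]:
        """Map gene id -> |log2 fold change|."""
        return {g: abs(r.log2fc) for g, r in self.records.items()}


# ---------------------------------------------------------------------------
# readers / writers


def read_gmt(path: str | Path, category: Category | str) -> GeneSetCollection:
    """Read a GMT file (tab-separated: id, description, member genes...).

    Duplicate member ids within a line are collapsed; lines whose member
    list is empty after collapsing are dropped with a warning.  A line with
    fewer than three fields or a repeated set id is an error.
    """
    category = Category(category)
    path = Path(path)
    coll = GeneSetCollection(category=category)
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            set_id, name = fields[0], fields[1]
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                logger.warning("%s:%d: set %r has no members, dropped", path, lineno, set_id)
                continue
            coll.add(GeneSet(set_id=set_id, name=name, category=category, members=members))
    return coll


def read_membership_tsv(path: str | Path, category: Category | str) -> GeneSetCollection:
    """Read a two-column long-format file: ``set_id<TAB>gene_id`` per line."""
    category = Category(category)
    path = Path(path)
    grouped: dict[str, set[str]] = {}
    order: list[str] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}"
                )
            set_id, gene = fields
            if set_id not in grouped:
                grouped[set_id] = set()
                order.append(set_id)
            grouped[set_id].add(gene)
    coll = GeneSetCollection(category=category)
    for set_id in order:
        coll.add(GeneSet(set_id=set_id, name=set_id, category=category,
                         members=frozenset(grouped[set_id])))
    return coll


def read_gene_sets(path: str | Path, category: Category | str) -> GeneSetCollection:
    """Read gene sets, auto-detecting GMT vs two-column long format.

    Detection is by the column count of the first non-empty line: exactly
    two columns selects the long format, three or more selects GMT.
    """
    path = Path(path)
    with path.open() as fh:
        for raw in fh:
            if raw.strip():
                ncol = len(raw.rstrip("\n").split("\t"))
                break
        else:
            raise ParseError(f"{path}: empty file")
    if ncol == 2:
        return read_membership_tsv(path, category)
    return read_gmt(path, category)


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    """Write a collection as GMT with sorted set ids and sorted members."""
    path = Path(path)
    with path.open("w") as fh:
        for set_id in sorted(coll.sets):
            gs = coll[set_id]
            fh.write("\t".join([gs.set_id, gs.name, *sorted(gs.members)]) + "\n")


def read_deg_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    background: Iterable[str] | None = None,
) -> DEGTable:
    """Read a TSV of DEG records.

    ``column_map`` maps the roles ``gene_id``, ``log2fc``, ``pvalue`` and
    ``qvalue`` to the file's column names.  Rows with non-numeric statistics
    are rejected with a warning; a duplicated gene id is an error.
    """
    cmap = dict(DEFAULT_DEG_COLUMNS)
    if column_map:
        cmap.update(column_map)
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in cmap.values() if c not in df.columns]
    if missing:
        raise ConfigError(
            f"{path}: mapped column(s) {missing} not found; available: {list(df.columns)}"
        )
    df = df.rename(columns={v: k for k, v in cmap.items()})
    for col in ("log2fc", "pvalue", "qvalue"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df[["log2fc", "pvalue", "qvalue"]].isna().any(axis=1)
    if bad.any():
        logger.warning(
            "%s: rejected %d row(s) with non-numeric statistics (e.g. gene %r)",
            path, int(bad.sum()), df.loc[bad, "gene_id"].iloc[0],
        )
        df = df[~bad]
    dup = df["gene_id"].duplicated()
    if dup.any():
        dup_ids = sorted(df.loc[dup, "gene_id"].unique())
        raise DataError(f"{path}: duplicate gene id(s): {dup_ids[:5]}")
    records = {
        row.gene_id: DEGRecord(
            gene_id=row.gene_id,
            log2fc=float(row.log2fc),
            pvalue=float(row.pvalue),
            qvalue=float(row.qvalue),
        )
        for row in df.itertuples(index=False)
    }
    bg = frozenset(background) if background is not None else None
    return DEGTable(records=records, background=bg)


def write_deg_table(table: DEGTable, path: str | Path) -> None:
    """Write a DEG table as TSV with the default column names, sorted by gene id."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene_id\tlog2fc\tpvalue\tqvalue\n")
        for gene_id in sorted(table.records):
            r = table[gene_id]
            fh.write(f"{gene_id}\t{r.log2fc:.6g}\t{r.pvalue:.6g}\t{r.qvalue:.6g}\n")


# ---------------------------------------------------------------------------
# universe operations


def filter_degs(table: DEGTable, q_threshold: float = 0.001) -> DEGTable:
    """Keep records with adjusted p-value <= ``q_threshold`` (inclusive).

    The background, when present, is unchanged: filtering restricts the
    candidate list, not the measured universe.
    """
    if not (0.0 < q_threshold <= 1.0):
        raise ConfigError(f"q_threshold must be in (0, 1], got {q_threshold}")
    kept = {g: r for g, r in table.records.items() if r.qvalue <= q_threshold}
    return DEGTable(records=kept, background=table.background)


def restrict_to_universe(
    coll: GeneSetCollection, genes: Iterable[str]
) -> GeneSetCollection:
    """Intersect every set's members with ``genes``; drop emptied sets.

    This is the step that turns raw annotation collections into DEG-only
    sets before the bipartite weighting; a pathway or GO term sharing no
    gene with the universe leaves the analysis here.
    """
    universe = frozenset(genes)
    if not universe:
        raise DataError("restriction universe is empty")
    out = GeneSetCollection(category=coll.category)
    for gs in coll:
        inter = gs.members & universe
        if inter:
            out.add(GeneSet(set_id=gs.set_id, name=gs.name,
                            category=gs.category, members=inter))
    return out
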