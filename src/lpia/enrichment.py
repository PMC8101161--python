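"""Overrepresentation statistics for gene-set collections.

Classical hypergeometric enrichment of a DEG list against a collection of
gene sets, with Benjamini-Hochberg control of the false discovery rate.
The test is the upper tail P(X >= k) of Hypergeometric(N, K, n) — the same
quantity ``phyper(k - 1, K, N - K, n, lower.tail = FALSE)`` returns in R —
where N is the background size, K the set size within the background,
n the number of candidate DEGs in the background and k their overlap with
the set.  The "rich ratio" reported alongside is k/K.
"""
from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DataError
from .genesets import DEGTable, GeneSetCollection

#: fixed column order of the enrichment table
ENRICHMENT_COLUMNS = [
    "set_id", "name", "k", "K", "n", "N",
    "rich_ratio", "pvalue", "qvalue", "significant",
]


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts candidate genes falling in a set of size ``K`` when ``n``
    candidates are drawn without replacement from a background of ``N``.
    The observed count is included in the tail, so ``k == 0`` gives 1.
    """
    if K > N:
        raise DataError(f"require K <= N, got K={K}, N={N}")
    if n > N:
        raise DataError(f"require n <= N, got n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise DataError(f"require 0 <= k <= min(K, n), got k={k}, K={K}, n={n}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    coll: GeneSetCollection,
    degs: DEGTable,
    background: Iterable[str] | None = None,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Test every set in ``coll`` for DEG overrepresentation.

    ``background`` defaults to the union of all genes annotated to at least
    one set in the collection; pass the full measured-gene universe to use
    that instead.  Sets with zero DEG overlap are retained (p = 1) so the
    BH correction spans the whole collection.  Returns a DataFrame with the
    columns in :data:`ENRICHMENT_COLUMNS`, sorted by ascending q-value then
    set id.
    """
    if len(coll) == 0:
        raise DataError("empty gene-set collection")
    if background is None:
        bg = coll.all_genes()
    else:
        bg = frozenset(background)
    if not bg:
        raise DataError("empty background")
    deg_in_bg = degs.gene_ids & bg
    n = len(deg_in_bg)
    N = len(bg)
    rows = []
    for gs in coll:
        members = gs.members & bg
        K = len(members)
        k = len(members & deg_in_bg)
        if K == 0:
            continue
        rows.append((gs.set_id, gs.name, k, K, n, N, k / K,
                     hypergeom_pvalue(k, K, n, N)))
    df = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS[:8])
    df["qvalue"] = bh_adjust(df["pvalue"].to_numpy())
    df["significant"] = df["qvalue"] <= q_threshold
    df = df.sort_values(["qvalue", "set_id"], kind="mergesort").reset_index(drop=True)
    return df


def significant_sets(rows: pd.DataFrame, q_threshold: float = 0.05) -> pd.DataFrame:
    """Rows with q <= threshold (inclusive), ordered by ascending q then set id."""
    if not (0.0 < q_threshold <= 1.0):
        raise ConfigError(f"q_threshold must be in (0, 1], got {q_threshold}")
    if "qvalue" not in rows.columns:
        raise DataError("enrichment table lacks a qvalue column")
    out = rows[rows["qvalue"] <= q_threshold]
    return out.sort_values(["qvalue", "set_id"], kind="mergesort").reset_index(drop=True)


def write_enrichment(df: pd.DataFrame, path) -> None:
    """Write the enrichment table as TSV with fixed column order."""
    df.to_csv(path, sep="\t", index=False, columns=ENRICHMENT_COLUMNS,
              float_format="%.6g")
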