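"""Over-representation analysis of edge gene sets.

Each edge's shared genes are tested against a user-supplied gene-set
collection (GMT format) with the one-sided hypergeometric upper-tail test:
for a universe of M genes, a term of n genes and a query of N genes, the
p-value is P[overlap >= observed] under random sampling without replacement.
P-values are Benjamini-Hochberg adjusted per edge; terms with adjusted
p < alpha count as enriched. A cross-edge summary counts, per term, the
number of edges in which it is enriched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = [
    "edge_id", "term_id", "term_name", "term_size", "overlap_size",
    "overlap_genes", "raw_p", "adjusted_p", "significant",
]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets: term_id -> (description, genes)."""

    terms: dict[str, tuple[str, frozenset[str]]]

    def __len__(self) -> int:
        return len(self.terms)

    def items(self):
        return self.terms.items()


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: term_id <tab> description <tab> gene1 <tab> gene2 ..."""
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (need >= 3 fields): {line[:80]!r}")
        term_id, description = fields[0], fields[1]
        genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
        terms[term_id] = (description, genes)
    return GeneSetCollection(terms=terms)


def collection_from_dict(d: Mapping[str, Iterable[str]]) -> GeneSetCollection:
    return GeneSetCollection(
        terms={k: (k, frozenset(str(g).upper() for g in v)) for k, v in d.items()}
    )


def bh_adjust(pvalues: np.ndarray | Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment: p * m / rank with monotonicity."""
    _, adjusted, _, _ = multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")
    return adjusted


def hypergeometric_enrich(
    query: Iterable[str],
    universe: Iterable[str],
    collection: GeneSetCollection,
    alpha: float = 0.05,
    min_term_size: int = 10,
    max_term_size: int = 2000,
    edge_id: str = "",
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query set against a collection.

    Terms are intersected with the universe and filtered to
    [min_term_size, max_term_size] before testing; query genes outside the
    universe are dropped with a warning. Returns the full table (one row per
    tested term) with raw and BH-adjusted p-values and a ``significant``
    flag (adjusted_p < alpha).
    """
    universe_set = {str(g).upper() for g in universe}
    if not universe_set:
        raise ValueError("empty gene universe")
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")

    query_set = {str(g).upper() for g in query}
    outside = query_set - universe_set
    if outside:
        logger.warning(
            "dropping %d query gene(s) outside the universe", len(outside)
        )
        query_set &= universe_set

    M, N = len(universe_set), len(query_set)
    rows = []
    for term_id, (name, genes) in collection.items():
        term_in_universe = genes & universe_set
        n = len(term_in_universe)
        if n < min_term_size or n > max_term_size:
            continue
        overlap = term_in_universe & query_set
        k = len(overlap)
        raw_p = float(hypergeom.sf(k - 1, M, n, N))  # P[X >= k]
        rows.append(
            {
                "edge_id": edge_id,
                "term_id": term_id,
                "term_name": name,
                "term_size": n,
                "overlap_size": k,
                "overlap_genes": ",".join(sorted(overlap)),
                "raw_p": min(raw_p, 1.0),
            }
        )

    if not rows:
        logger.warning("no term within size bounds [%d, %d]", min_term_size, max_term_size)
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)

    table = pd.DataFrame(rows)
    table["adjusted_p"] = bh_adjust(table["raw_p"].to_numpy())
    table["significant"] = table["adjusted_p"] < alpha
    return table.sort_values(["raw_p", "term_id"]).reset_index(drop=True)[ENRICHMENT_COLUMNS]


def term_edge_summary(
    tables: Sequence[pd.DataFrame], alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-term count of edges in which the term is enriched.

    Returns (counts, matrix): ``counts`` has one row per term with the number
    of edges where adjusted_p < alpha, sorted descending; ``matrix`` is the
    binary term x edge enrichment indicator for external clustering.
    """
    frames = [t for t in tables if len(t)]
    if not frames:
        return (
            pd.DataFrame(columns=["term_id", "term_name", "n_edges_enriched"]),
            pd.DataFrame(),
        )
    merged = pd.concat(frames, ignore_index=True)
    enriched = merged[merged["adjusted_p"] < alpha]
    if enriched.empty:
        return (
            pd.DataFrame(columns=["term_id", "term_name", "n_edges_enriched"]),
            pd.DataFrame(),
        )

    counts = (
        enriched.groupby(["term_id", "term_name"])["edge_id"]
        .nunique()
        .rename("n_edges_enriched")
        .reset_index()
        .sort_values(["n_edges_enriched", "term_id"], ascending=[False, True])
        .reset_index(drop=True)
    )
    matrix = (
        enriched.assign(flag=1)
        .pivot_table(index="term_id", columns="edge_id", values="flag", fill_value=0)
        .astype(int)
    )
    return counts, matrix
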