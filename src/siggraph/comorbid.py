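"""Gene-level dissection of comorbid signature pairs.

A comorbid edge links signatures of two different diseases; its shared genes
are compared against the genes seen in each disease's own single-disease
edges (a-a and b-b). Genes found only in disease a's single edges are
"disease-a specific", only in b's are "disease-b specific", in both are
"shared", and genes appearing in neither single-disease edge set are
"distinct" — candidate novel comorbidity genes. Genes of an enriched process
are ranked by the geometric mean of their exposures in the two endpoint
signatures, and GWAS hit lists of the two diseases are overlaid as labels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .graph import Edge

logger = logging.getLogger(__name__)

GENE_CATEGORIES = ("disease_a_specific", "disease_b_specific", "shared", "distinct")


@dataclass
class EdgeGeneCategorization:
    """Partition of comorbid-edge genes relative to single-disease edges."""

    disease_a: str
    disease_b: str
    categories: dict[str, str]  # gene -> category

    @property
    def fraction_distinct(self) -> float:
        if not self.categories:
            return float("nan")
        n = sum(1 for c in self.categories.values() if c == "distinct")
        return n / len(self.categories)

    def genes_in(self, category: str) -> frozenset[str]:
        return frozenset(g for g, c in self.categories.items() if c == category)

    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in GENE_CATEGORIES}
        for c in self.categories.values():
            out[c] += 1
        return out


def _norm(genes: Iterable[str]) -> set[str]:
    return {str(g).upper() for g in genes}


def _edge_gene_union(edges: Sequence[Edge]) -> set[str]:
    out: set[str] = set()
    for e in edges:
        out |= _norm(e.shared_genes)
    return out


def categorize_comorbid_genes(
    comorbid_edges: Sequence[Edge],
    disease_a_edges: Sequence[Edge],
    disease_b_edges: Sequence[Edge],
    disease_a: str = "a",
    disease_b: str = "b",
) -> EdgeGeneCategorization:
    """Label every comorbid-edge gene by where else it appears.

    Let U be the union of shared genes over the comorbid (a-b) edges, A over
    the a-a edges and B over the b-b edges. A gene in U is disease_a_specific
    if it appears in A only, disease_b_specific if in B only, shared if in
    both, distinct if in neither. Gene symbols are upper-cased first.
    """
    U = _edge_gene_union(comorbid_edges)
    A = _edge_gene_union(disease_a_edges)
    B = _edge_gene_union(disease_b_edges)
    if not U:
        logger.warning("no genes in comorbid edges; empty categorization")

    categories: dict[str, str] = {}
    for g in U:
        in_a, in_b = g in A, g in B
        if in_a and in_b:
            categories[g] = "shared"
        elif in_a:
            categories[g] = "disease_a_specific"
        elif in_b:
            categories[g] = "disease_b_specific"
        else:
            categories[g] = "distinct"
    return EdgeGeneCategorization(
        disease_a=disease_a, disease_b=disease_b, categories=categories
    )


def rank_genes_for_term(
    edges: Sequence[Edge],
    term_genes: Iterable[str],
    exposures: Mapping[str, pd.Series],
    top_k: int = 30,
    categories: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Rank a process's genes by geometric-mean exposure across edge endpoints.

    For every gene of ``term_genes`` found in an edge's shared genes, the
    geometric mean sqrt(exposure_a * exposure_b) of its exposures in the two
    endpoint signatures is computed; a gene occurring in several edges keeps
    its maximum geometric mean (with the exposures of that edge, for
    plotting). Returns at most ``top_k`` rows sorted by descending geometric
    mean, ties broken by gene label.

    ``exposures`` maps a node id to that signature's gene-exposure Series.
    """
    term = _norm(term_genes)
    best: dict[str, tuple[float, float, float, str]] = {}
    for e in edges:
        exp_a = exposures[e.node_a]
        exp_b = exposures[e.node_b]
        upper_a = {str(g).upper(): g for g in exp_a.index}
        upper_b = {str(g).upper(): g for g in exp_b.index}
        for g in _norm(e.shared_genes) & term:
            if g not in upper_a or g not in upper_b:
                continue
            ea = float(exp_a[upper_a[g]])
            eb = float(exp_b[upper_b[g]])
            gm = math.sqrt(ea * eb)
            if g not in best or gm > best[g][0]:
                best[g] = (gm, ea, eb, e.edge_id)

    if not best:
        logger.warning("term genes do not occur in any edge's shared genes")
        return pd.DataFrame(
            columns=["gene", "exposure_a", "exposure_b", "geometric_mean", "edge_id", "category"]
        )

    rows = [
        {
            "gene": g,
            "exposure_a": ea,
            "exposure_b": eb,
            "geometric_mean": gm,
            "edge_id": eid,
            "category": categories.get(g, "") if categories else "",
        }
        for g, (gm, ea, eb, eid) in best.items()
    ]
    table = pd.DataFrame(rows).sort_values(
        ["geometric_mean", "gene"], ascending=[False, True]
    )
    return table.head(top_k).reset_index(drop=True)


def gwas_overlay(
    genes: Sequence[str],
    gwas_a: Iterable[str],
    gwas_b: Iterable[str],
    label_a: str = "gwas_a",
    label_b: str = "gwas_b",
    label_shared: str = "gwas_shared",
) -> pd.Series:
    """Label genes by GWAS membership: a-only, b-only, shared, or none."""
    set_a, set_b = _norm(gwas_a), _norm(gwas_b)
    labels = []
    for g in genes:
        gu = str(g).upper()
        if gu in set_a and gu in set_b:
            labels.append(label_shared)
        elif gu in set_a:
            labels.append(label_a)
        elif gu in set_b:
            labels.append(label_b)
        else:
            labels.append("none")
    return pd.Series(labels, index=list(genes), name="gwas_label")


def read_gene_list(path: str | Path) -> frozenset[str]:
    """Plain-text gene list: one symbol per line, or TSV whose first column is
    the symbol (further columns such as study counts ignored)."""
    genes = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        genes.add(line.split("\t")[0].strip().upper())
    return frozenset(genes)
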