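"""Cross-cohort signature graph: RBH matching, permutation test, edge taxonomy.

Signatures from different cohorts are compared through the Jaccard similarity
of their top-N gene sets (the N genes with the largest exposures; default
N = 1000 on the assumption that only a minority of genes carry real signal).
For every ordered cohort pair, each signature's best-Jaccard match in the
other cohort is found, and an edge is drawn when the choice is mutual — a
reciprocal best hit (RBH), as in ortholog matching.

Edge significance is assessed empirically: within each signature, the
assignment of exposure values to gene labels is shuffled, top-N sets and RBH
edges are recomputed, and this is repeated n_permutations times (default 20).
An observed edge's occurrence probability is (1 + c) / (1 + n_permutations)
where c counts the permutations in which the same signature pair re-linked;
edges with occurrence probability <= edge_alpha (default 0.05) are retained.
With 20 permutations that retains exactly the edges never seen under
shuffling.

Retained edges are then categorized from their endpoints' disease annotations:
same disease -> "single"; different disease within one class ->
"intra_class_comorbid"; across classes with a psychiatric endpoint ->
"inter_class_comorbid"; across non-psychiatric diseases -> "somatic"; plus a
same-tissue / cross-tissue flag.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .nmf import Signature, SignatureSet

logger = logging.getLogger(__name__)

EDGE_CATEGORIES = ("single", "intra_class_comorbid", "inter_class_comorbid", "somatic")
DEFAULT_KNOWN_CLASSES = frozenset({"PSY", "CVD", "T2D"})


@dataclass(frozen=True)
class GraphConfig:
    """Knobs of graph construction.

    top_n: size of the top-exposure gene set per signature.
    n_permutations: gene-label shuffles for the empirical edge test.
    edge_alpha: occurrence-probability threshold for keeping an edge (<=).
    occurrence: what counts as the edge "occurring" in a permutation round.
        'stronger_link' (default): some RBH link between the same two
        cohorts forms with Jaccard >= the observed edge's — the observed
        best-hit strength is compared against the null distribution of
        best chance-link strengths, matching its conditioning.
        'same_pair': the identical (cohort, rank, index) signature pair
        re-links, at any strength.
        'any_pair': any RBH link forms between the two cohorts (loosest).
    shuffle_mode: 'within_signature' shuffles each W column independently;
        'whole_matrix' shuffles the pooled W entries of a cohort.
    """

    top_n: int = 1000
    n_permutations: int = 20
    edge_alpha: float = 0.05
    seed: int = 0
    occurrence: str = "stronger_link"
    shuffle_mode: str = "within_signature"

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.occurrence not in ("stronger_link", "same_pair", "any_pair"):
            raise ValueError(f"unknown occurrence mode {self.occurrence!r}")
        if self.shuffle_mode not in ("within_signature", "whole_matrix"):
            raise ValueError(f"unknown shuffle_mode {self.shuffle_mode!r}")


@dataclass
class Edge:
    """An RBH link between two signatures from different cohorts."""

    node_a: str
    node_b: str
    cohort_a: str
    cohort_b: str
    jaccard: float
    shared_genes: frozenset[str]
    permutation_p: float | None = None
    category: str | None = None
    tissue_relation: str | None = None
    tied: bool = False

    @property
    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.node_a, self.node_b)))  # type: ignore[return-value]

    @property
    def edge_id(self) -> str:
        a, b = self.key
        return f"{a}--{b}"


@dataclass
class SignatureGraph:
    """Nodes (retained signatures with annotations) plus RBH edges."""

    nodes: dict[str, dict]
    edges: list[Edge]

    def edges_between(self, cohort_a: str, cohort_b: str) -> list[Edge]:
        pair = {cohort_a, cohort_b}
        return [e for e in self.edges if {e.cohort_a, e.cohort_b} == pair]

    def edges_by_disease_pair(self, disease_a: str, disease_b: str) -> list[Edge]:
        out = []
        for e in self.edges:
            da = self.nodes[e.node_a]["disease"]
            db = self.nodes[e.node_b]["disease"]
            if {da, db} == {disease_a, disease_b} or (
                disease_a == disease_b and da == db == disease_a
            ):
                out.append(e)
        return out

    def category_summary(self) -> pd.DataFrame:
        """Edge counts per (category x tissue_relation)."""
        rows = [
            {"category": e.category, "tissue_relation": e.tissue_relation}
            for e in self.edges
        ]
        if not rows:
            return pd.DataFrame(columns=["category", "tissue_relation", "n_edges"])
        return (
            pd.DataFrame(rows)
            .value_counts(["category", "tissue_relation"])
            .rename("n_edges")
            .reset_index()
            .sort_values(["category", "tissue_relation"])
            .reset_index(drop=True)
        )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for node_id, attrs in self.nodes.items():
            g.add_node(node_id, **attrs)
        for e in self.edges:
            g.add_edge(
                e.node_a,
                e.node_b,
                jaccard=e.jaccard,
                permutation_p=e.permutation_p if e.permutation_p is not None else float("nan"),
                category=e.category or "",
                tissue_relation=e.tissue_relation or "",
                n_shared_genes=len(e.shared_genes),
            )
        return g

    def to_json_dict(self) -> dict:
        return {
            "nodes": {nid: dict(sorted(attrs.items())) for nid, attrs in sorted(self.nodes.items())},
            "edges": [
                {
                    "node_a": e.key[0],
                    "node_b": e.key[1],
                    "cohorts": sorted((e.cohort_a, e.cohort_b)),
                    "jaccard": e.jaccard,
                    "permutation_p": e.permutation_p,
                    "category": e.category,
                    "tissue_relation": e.tissue_relation,
                    "shared_genes": sorted(e.shared_genes),
                }
                for e in sorted(self.edges, key=lambda e: e.key)
            ],
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_json_dict(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for e in sorted(self.edges, key=lambda e: e.key):
            rows.append(
                {
                    "edge_id": e.edge_id,
                    "node_a": e.key[0],
                    "node_b": e.key[1],
                    "jaccard": e.jaccard,
                    "permutation_p": e.permutation_p,
                    "category": e.category,
                    "tissue_relation": e.tissue_relation,
                    "n_shared_genes": len(e.shared_genes),
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Top-N gene sets and Jaccard


def top_genes(sig: Signature, top_n: int) -> list[str]:
    """The top_n genes by descending exposure; ties broken by gene label."""
    labels = sig.gene_exposures.index.to_numpy(dtype=object)
    values = sig.gene_exposures.to_numpy(dtype=float)
    if top_n > len(labels):
        raise ValueError(f"top_n={top_n} exceeds gene count {len(labels)}")
    order = np.lexsort((labels, -values))
    return list(labels[order[:top_n]])


def jaccard(set_a: Iterable[str], set_b: Iterable[str]) -> float:
    """|A n B| / |A u B|; symmetric, in [0, 1]. Empty inputs are an error."""
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise ValueError("jaccard requires nonempty gene sets")
    return len(a & b) / len(a | b)


def _top_index_matrix(
    exposure_matrix: np.ndarray, labels: np.ndarray, top_n: int
) -> np.ndarray:
    """Row-wise top-N gene indices with (descending value, ascending label) order."""
    n_sigs, n_genes = exposure_matrix.shape
    if top_n > n_genes:
        raise ValueError(f"top_n={top_n} exceeds gene count {n_genes}")
    label_rank = np.empty(n_genes, dtype=np.int64)
    label_rank[np.argsort(labels, kind="stable")] = np.arange(n_genes)
    out = np.empty((n_sigs, top_n), dtype=np.int64)
    for i in range(n_sigs):
        order = np.lexsort((label_rank, -exposure_matrix[i]))
        out[i] = order[:top_n]
    return out


def _membership(top_idx: np.ndarray, n_genes: int) -> np.ndarray:
    """Boolean signature x gene membership matrix from top-index rows."""
    m = np.zeros((top_idx.shape[0], n_genes), dtype=bool)
    rows = np.repeat(np.arange(top_idx.shape[0]), top_idx.shape[1])
    m[rows, top_idx.ravel()] = True
    return m


def _rbh_pairs(
    members_a: np.ndarray, members_b: np.ndarray
) -> list[tuple[int, int, float]]:
    """Reciprocal best hits between two boolean membership matrices.

    Returns (i, j, jaccard) triples; zero-Jaccard candidates are discarded,
    and exact ties keep all tied mutual bests.
    """
    inter = members_a.astype(np.int64) @ members_b.T.astype(np.int64)
    size_a = members_a.sum(axis=1)[:, None]
    size_b = members_b.sum(axis=1)[None, :]
    union = size_a + size_b - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        J = np.where(union > 0, inter / union, 0.0)

    best_a = J.max(axis=1)
    best_b = J.max(axis=0)
    out = []
    for i in range(J.shape[0]):
        if best_a[i] <= 0:
            continue
        for j in np.flatnonzero(J[i] == best_a[i]):
            if J[i, j] == best_b[j]:
                out.append((i, int(j), float(J[i, j])))
    return out


def _cohort_arrays(sigset: SignatureSet) -> tuple[np.ndarray, np.ndarray, list[Signature]]:
    sigs = list(sigset.signatures)
    if not sigs:
        return np.zeros((0, 0)), np.array([], dtype=object), sigs
    labels = sigs[0].gene_exposures.index.to_numpy(dtype="U64")
    matrix = np.vstack([s.gene_exposures.to_numpy(dtype=float) for s in sigs])
    return matrix, labels, sigs


def reciprocal_best_hits(
    sigs_a: SignatureSet, sigs_b: SignatureSet, cfg: GraphConfig
) -> list[Edge]:
    """RBH edges between two cohorts' signatures on top-N gene-set Jaccard.

    Jaccard is computed on gene labels: genes measured in only one cohort can
    never intersect. Symmetric in its arguments.
    """
    if sigs_a.cohort_id == sigs_b.cohort_id:
        raise ValueError("reciprocal best hits need two distinct cohorts")
    if not sigs_a.signatures or not sigs_b.signatures:
        return []

    mat_a, labels_a, list_a = _cohort_arrays(sigs_a)
    mat_b, labels_b, list_b = _cohort_arrays(sigs_b)

    universe = np.union1d(labels_a, labels_b)
    pos = {g: i for i, g in enumerate(universe)}
    map_a = np.array([pos[g] for g in labels_a])
    map_b = np.array([pos[g] for g in labels_b])

    top_a = map_a[_top_index_matrix(mat_a, labels_a, cfg.top_n)]
    top_b = map_b[_top_index_matrix(mat_b, labels_b, cfg.top_n)]
    members_a = _membership(top_a, len(universe))
    members_b = _membership(top_b, len(universe))

    pairs = _rbh_pairs(members_a, members_b)
    seen_a = [i for i, _, _ in pairs]
    tied_a = {i for i in seen_a if seen_a.count(i) > 1}
    seen_b = [j for _, j, _ in pairs]
    tied_b = {j for j in seen_b if seen_b.count(j) > 1}

    edges = []
    for i, j, jac in pairs:
        shared = frozenset(universe[members_a[i] & members_b[j]])
        edges.append(
            Edge(
                node_a=list_a[i].node_id,
                node_b=list_b[j].node_id,
                cohort_a=sigs_a.cohort_id,
                cohort_b=sigs_b.cohort_id,
                jaccard=jac,
                shared_genes=shared,
                tied=(i in tied_a) or (j in tied_b),
            )
        )
    if any(e.tied for e in edges):
        logger.info(
            "RBH %s-%s: tied best hits produced duplicate matches",
            sigs_a.cohort_id, sigs_b.cohort_id,
        )
    return edges


def build_candidate_edges(
    cohort_sets: Sequence[SignatureSet], cfg: GraphConfig
) -> list[Edge]:
    """RBH candidate edges over every unordered cohort pair."""
    edges: list[Edge] = []
    for set_a, set_b in combinations(cohort_sets, 2):
        edges.extend(reciprocal_best_hits(set_a, set_b, cfg))
    return edges


# ---------------------------------------------------------------------------
# Permutation edge test


def _shuffle_matrix(
    matrix: np.ndarray, shuffle_mode: str, rng: np.random.Generator
) -> np.ndarray:
    """Shuffle the assignment of exposure values to gene labels.

    'within_signature' permutes each row (one signature's W column)
    independently, preserving every signature's multiset of exposures;
    'whole_matrix' shuffles the cohort's pooled W entries.
    """
    if not matrix.size:
        return matrix
    if shuffle_mode == "within_signature":
        return rng.permuted(matrix, axis=1)
    flat = matrix.ravel().copy()
    rng.shuffle(flat)
    return flat.reshape(matrix.shape)


def _permuted_rbh_stats(
    cohort_sets: Sequence[SignatureSet],
    cfg: GraphConfig,
    rng: np.random.Generator,
) -> dict[frozenset, tuple[set[frozenset], float]]:
    """One permutation round: shuffle gene exposures, recompute RBH links.

    Returns, per unordered cohort pair, the set of re-linked node-id pairs
    and the maximum Jaccard among them.
    """
    shuffled: list[tuple[np.ndarray, np.ndarray, list[Signature], str]] = []
    for sigset in cohort_sets:
        matrix, labels, sigs = _cohort_arrays(sigset)
        matrix = _shuffle_matrix(matrix, cfg.shuffle_mode, rng)
        shuffled.append((matrix, labels, sigs, sigset.cohort_id))

    stats: dict[frozenset, tuple[set[frozenset], float]] = {}
    for (mat_a, labels_a, list_a, coh_a), (mat_b, labels_b, list_b, coh_b) in combinations(
        shuffled, 2
    ):
        if not list_a or not list_b:
            continue
        universe = np.union1d(labels_a, labels_b)
        pos = {g: i for i, g in enumerate(universe)}
        map_a = np.array([pos[g] for g in labels_a])
        map_b = np.array([pos[g] for g in labels_b])
        members_a = _membership(map_a[_top_index_matrix(mat_a, labels_a, cfg.top_n)], len(universe))
        members_b = _membership(map_b[_top_index_matrix(mat_b, labels_b, cfg.top_n)], len(universe))
        pairs = _rbh_pairs(members_a, members_b)
        keys = {frozenset((list_a[i].node_id, list_b[j].node_id)) for i, j, _ in pairs}
        max_j = max((jac for _, _, jac in pairs), default=0.0)
        stats[frozenset((coh_a, coh_b))] = (keys, max_j)
    return stats


def permutation_edge_test(
    cohort_sets: Sequence[SignatureSet],
    observed_edges: Sequence[Edge],
    cfg: GraphConfig,
) -> SignatureGraph:
    """Empirical edge test: keep edges rarely matched under gene shuffling.

    Occurrence probability of an edge = (1 + c) / (1 + n_permutations), c the
    number of permutation rounds in which the edge "occurred" under the
    configured criterion (default: a chance RBH link at least as strong
    formed between the same two cohorts); edges with probability <=
    edge_alpha are retained. Seeded and reproducible.
    """
    min_possible = 1.0 / (1.0 + cfg.n_permutations)
    if min_possible > cfg.edge_alpha:
        needed = math.ceil(1.0 / cfg.edge_alpha - 1.0)
        raise ValueError(
            f"n_permutations={cfg.n_permutations} cannot reach "
            f"edge_alpha={cfg.edge_alpha}: minimum attainable p = "
            f"{min_possible:.4g}; need n_permutations >= {needed}"
        )

    rng = np.random.default_rng(cfg.seed)
    counts = {e.key: 0 for e in observed_edges}
    empty: tuple[set[frozenset], float] = (set(), 0.0)
    for _ in range(cfg.n_permutations):
        stats = _permuted_rbh_stats(cohort_sets, cfg, rng)
        for e in observed_edges:
            keys, max_j = stats.get(frozenset((e.cohort_a, e.cohort_b)), empty)
            if cfg.occurrence == "stronger_link":
                hit = max_j >= e.jaccard
            elif cfg.occurrence == "same_pair":
                hit = frozenset(e.key) in keys
            else:  # any_pair
                hit = bool(keys)
            if hit:
                counts[e.key] += 1

    retained = []
    for e in observed_edges:
        p = (1.0 + counts[e.key]) / (1.0 + cfg.n_permutations)
        e = replace(e, permutation_p=p)
        if p <= cfg.edge_alpha:
            retained.append(e)

    nodes = {}
    for sigset in cohort_sets:
        for sig in sigset.signatures:
            nodes[sig.node_id] = {
                "cohort_id": sigset.cohort_id,
                "rank_k": sig.rank_k,
                "index_in_rank": sig.index_in_rank,
                "disease": sigset.disease,
                "disease_class": sigset.disease_class,
                "tissue": sigset.tissue,
                "diagnosis_p": sig.diagnosis_p,
            }
    return SignatureGraph(nodes=nodes, edges=retained)


# ---------------------------------------------------------------------------
# Edge taxonomy


def categorize_edges(
    graph: SignatureGraph,
    psychiatric_classes: frozenset[str] | set[str] = frozenset({"PSY"}),
    known_classes: frozenset[str] | set[str] | None = None,
) -> SignatureGraph:
    """Label every edge with its disease-pair category and tissue relation.

    single: same disease. intra_class_comorbid: different diseases, same
    class. inter_class_comorbid: different classes, one psychiatric endpoint.
    somatic: different diseases, no psychiatric endpoint. Classes outside
    ``known_classes`` (default: PSY/CVD/T2D plus the psychiatric set) are an
    error.
    """
    if known_classes is None:
        known_classes = DEFAULT_KNOWN_CLASSES | set(psychiatric_classes)

    for e in graph.edges:
        na, nb = graph.nodes[e.node_a], graph.nodes[e.node_b]
        for cls in (na["disease_class"], nb["disease_class"]):
            if cls not in known_classes:
                raise ValueError(f"unknown disease class code: {cls!r}")
        if na["disease"] == nb["disease"]:
            e.category = "single"
        elif na["disease_class"] == nb["disease_class"]:
            e.category = "intra_class_comorbid"
        elif (na["disease_class"] in psychiatric_classes) != (
            nb["disease_class"] in psychiatric_classes
        ):
            e.category = "inter_class_comorbid"
        else:
            e.category = "somatic"
        e.tissue_relation = (
            "same_tissue" if na["tissue"] == nb["tissue"] else "cross_tissue"
        )
    return graph
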