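import math

import numpy as np
import pandas as pd
import pytest

from siggraph import (
    bh_adjust,
    collection_from_dict,
    hypergeometric_enrich,
    read_gmt,
    term_edge_summary,
)


UNIVERSE20 = [f"G{i}" for i in range(20)]


class TestHypergeometricEnrich:
    def test_full_overlap_exact_tail(self):
        """Term = query of 5 genes in a 20-gene universe: p = 1/C(20,5)."""
        term = set(UNIVERSE20[:5])
        coll = collection_from_dict({"T": term})
        table = hypergeometric_enrich(term, UNIVERSE20, coll, min_term_size=1)
        assert table.loc[0, "raw_p"] == pytest.approx(1 / math.comb(20, 5), rel=1e-12)
        assert table.loc[0, "overlap_size"] == 5

    def test_zero_overlap_p_is_one(self):
        coll = collection_from_dict({"T": {UNIVERSE20[0]}})
        table = hypergeometric_enrich({UNIVERSE20[1]}, UNIVERSE20, coll, min_term_size=1)
        assert table.loc[0, "raw_p"] == 1.0

    def test_query_outside_universe_dropped(self):
        coll = collection_from_dict({"T": set(UNIVERSE20[:5])})
        t1 = hypergeometric_enrich(set(UNIVERSE20[:5]) | {"ZZZ"}, UNIVERSE20, coll,
                                   min_term_size=1)
        t2 = hypergeometric_enrich(set(UNIVERSE20[:5]), UNIVERSE20, coll, min_term_size=1)
        assert t1.loc[0, "raw_p"] == t2.loc[0, "raw_p"]

    def test_term_size_bounds_applied(self):
        coll = collection_from_dict({"small": set(UNIVERSE20[:2]), "ok": set(UNIVERSE20[:12])})
        table = hypergeometric_enrich(set(UNIVERSE20[:5]), UNIVERSE20, coll,
                                      min_term_size=10, max_term_size=2000)
        assert list(table["term_id"]) == ["ok"]

    def test_empty_universe_fatal(self):
        with pytest.raises(ValueError):
            hypergeometric_enrich({"G1"}, [], collection_from_dict({"T": {"G1"}}))

    def test_empty_collection_fatal(self):
        with pytest.raises(ValueError):
            hypergeometric_enrich({"G1"}, UNIVERSE20, collection_from_dict({}))

    def test_adjusted_monotone_in_raw(self, rng):
        genes = [f"G{i}" for i in range(100)]
        coll = collection_from_dict(
            {f"T{j}": set(rng.choice(genes, 20, replace=False)) for j in range(30)}
        )
        query = set(rng.choice(genes, 25, replace=False))
        table = hypergeometric_enrich(query, genes, coll, min_term_size=1)
        assert table["raw_p"].is_monotonic_increasing
        assert table["adjusted_p"].is_monotonic_increasing
        assert (table["adjusted_p"] >= table["raw_p"] - 1e-15).all()
        assert (table["adjusted_p"] <= 1.0).all()

    def test_null_raw_p_calibrated(self, rng):
        """Random query vs independent random terms: ~5% of raw p < 0.05."""
        genes = [f"G{i}" for i in range(300)]
        hits = 0
        total = 0
        for rep in range(5):
            coll = collection_from_dict(
                {f"T{j}": set(rng.choice(genes, 30, replace=False)) for j in range(200)}
            )
            query = set(rng.choice(genes, 40, replace=False))
            table = hypergeometric_enrich(query, genes, coll, min_term_size=1)
            hits += int((table["raw_p"] < 0.05).sum())
            total += len(table)
        # hypergeometric p-values are discrete and conservative, so the rate
        # sits at or below the nominal level
        assert hits / total < 0.08


def test_bh_step_up_closed_form():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])


class TestTermEdgeSummary:
    def table(self, edge_id, sig_terms, nonsig_terms=()):
        rows = []
        for t in sig_terms:
            rows.append({"edge_id": edge_id, "term_id": t, "term_name": t,
                         "adjusted_p": 0.01})
        for t in nonsig_terms:
            rows.append({"edge_id": edge_id, "term_id": t, "term_name": t,
                         "adjusted_p": 0.5})
        return pd.DataFrame(rows)

    def test_counting(self):
        tables = [
            self.table("e1", ["angio", "ros"]),
            self.table("e2", ["angio"]),
            self.table("e3", ["angio"], nonsig_terms=["ros"]),
        ]
        counts, matrix = term_edge_summary(tables)
        assert counts.set_index("term_id")["n_edges_enriched"].to_dict() == {
            "angio": 3, "ros": 1,
        }
        assert matrix.loc["angio"].sum() == 3

    def test_no_enrichment_empty(self):
        counts, matrix = term_edge_summary([self.table("e1", [], nonsig_terms=["x"])])
        assert counts.empty and matrix.empty

    def test_recount_oracle(self, rng):
        terms = [f"T{j}" for j in range(10)]
        tables = []
        for e in range(8):
            rows = [
                {"edge_id": f"e{e}", "term_id": t, "term_name": t,
                 "adjusted_p": float(rng.uniform(0, 0.1))}
                for t in terms
            ]
            tables.append(pd.DataFrame(rows))
        counts, _ = term_edge_summary(tables, alpha=0.05)
        merged = pd.concat(tables)
        for _, row in counts.iterrows():
            expected = sum(
                1
                for e in range(8)
                for _, r in merged[(merged.edge_id == f"e{e}") & (merged.term_id == row.term_id)].iterrows()
                if r.adjusted_p < 0.05
            )
            assert row.n_edges_enriched == expected


def test_read_gmt(tmp_path):
    gmt = tmp_path / "c.gmt"
    gmt.write_text(
        "GO:1\tangiogenesis\tVEGFA\tMMP9\til18\n"
        "GO:2\tacute inflammation\tIL6\tTNF\n"
    )
    coll = read_gmt(gmt)
    assert len(coll) == 2
    name, genes = coll.terms["GO:1"]
    assert name == "angiogenesis" and genes == {"VEGFA", "MMP9", "IL18"}
    bad = tmp_path / "bad.gmt"
    bad.write_text("only_one_field\n")
    with pytest.raises(ValueError):
        read_gmt(bad)
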