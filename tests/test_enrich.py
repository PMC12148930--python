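import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from misplice.enrich import (
    ContingencyTable2x2,
    classify_microexon,
    enrichment_table,
    event_level_enrichment,
    fisher_or,
    gene_level_enrichment,
    mie_enrichment,
    overlap_events,
)
from misplice.events import GeneSet
from oracles import fisher_p_enumeration


def diff_frame(n_events, in_set_called, in_set_total, out_called, set_genes="S", out_genes="O"):
    """Differential table with one gene per event, controlled set membership."""
    rows = []
    k = 0
    for i in range(in_set_total):
        rows.append(
            {"event_id": f"e{k}", "gene_id": f"{set_genes}{i}", "event_type": "SE",
             "exon_length": 100, "is_missplicing": i < in_set_called}
        )
        k += 1
    for i in range(n_events - in_set_total):
        rows.append(
            {"event_id": f"e{k}", "gene_id": f"{out_genes}{i}", "event_type": "SE",
             "exon_length": 100, "is_missplicing": i < out_called}
        )
        k += 1
    return pd.DataFrame(rows)


class TestFisherOr:
    def test_point_or_arithmetic(self):
        or_, lo, hi, p = fisher_or(ContingencyTable2x2(10, 5, 2, 12))
        assert or_ == pytest.approx(12.0)
        assert lo < or_ < hi

    def test_balanced_table_is_null(self):
        or_, _, _, p = fisher_or(ContingencyTable2x2(5, 5, 5, 5))
        assert or_ == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_infinite_and_zero_or(self):
        assert math.isinf(fisher_or(ContingencyTable2x2(5, 0, 0, 5))[0])
        assert fisher_or(ContingencyTable2x2(0, 5, 5, 5))[0] == 0.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(0, 0, 0, 0)

    @settings(max_examples=100, deadline=None)
    @given(st.tuples(*[st.integers(0, 15)] * 4).filter(lambda t: sum(t) >= 1))
    def test_p_matches_hypergeometric_enumeration(self, cells):
        a, b, c, d = cells
        p = fisher_or(ContingencyTable2x2(a, b, c, d))[3]
        assert p == pytest.approx(fisher_p_enumeration(a, b, c, d), rel=1e-9, abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.tuples(*[st.integers(0, 20)] * 4).filter(lambda t: sum(t) >= 1))
    def test_or_invariant_under_transposition(self, cells):
        a, b, c, d = cells
        r1 = fisher_or(ContingencyTable2x2(a, b, c, d))
        r2 = fisher_or(ContingencyTable2x2(a, c, b, d))  # transpose
        assert r1[0] == r2[0] or (math.isnan(r1[0]) and math.isnan(r2[0]))
        assert r1[3] == pytest.approx(r2[3], rel=1e-9)

    def test_ci_covers_point_or_when_cells_positive(self):
        or_, lo, hi, _ = fisher_or(ContingencyTable2x2(8, 3, 4, 9))
        assert lo <= or_ <= hi


class TestEventLevel:
    def test_worked_table(self):
        # 100 events, 20 in set; called: 10 in-set, 10 of the 80 out-set
        df = diff_frame(100, in_set_called=10, in_set_total=20, out_called=10)
        gs = GeneSet.from_iterable("asd", {f"S{i}" for i in range(20)})
        res = event_level_enrichment(df, gs)
        assert (res.table.a, res.table.b, res.table.c, res.table.d) == (10, 10, 10, 70)
        assert res.odds_ratio == pytest.approx(7.0)

    def test_no_called_events_warns(self):
        df = diff_frame(50, 0, 10, 0)
        gs = GeneSet.from_iterable("asd", {f"S{i}" for i in range(10)})
        with pytest.warns(UserWarning, match="degenerate margin"):
            res = event_level_enrichment(df, gs)
        assert math.isnan(res.odds_ratio) or res.odds_ratio == 0.0

    def test_planted_or_recovered_in_simulation(self, rng):
        # direct Bernoulli simulation of membership x call with true OR = 3
        n, or_true = 4000, 3.0
        p_out = 0.08
        odds_in = or_true * p_out / (1 - p_out)
        p_in = odds_in / (1 + odds_in)
        hits, cover = [], 0
        n_rep = 100
        for _ in range(n_rep):
            in_set = rng.random(n) < 0.25
            called = np.where(in_set, rng.random(n) < p_in, rng.random(n) < p_out)
            df = pd.DataFrame(
                {"event_id": [f"e{i}" for i in range(n)],
                 "gene_id": [f"g{i}" for i in range(n)],
                 "event_type": "SE", "exon_length": 100, "is_missplicing": called}
            )
            gs = GeneSet.from_iterable("s", {f"g{i}" for i in range(n) if in_set[i]})
            res = event_level_enrichment(df, gs)
            hits.append(res.odds_ratio)
            cover += res.ci_low <= or_true <= res.ci_high
        assert 2.0 <= float(np.median(hits)) <= 4.5
        assert cover >= 90


class TestGeneLevel:
    def test_worked_table(self):
        # 50 genes, 10 in set; mis-spliced: 5 in-set, 5 out-set
        rows = []
        for i in range(10):
            rows.append({"event_id": f"e{i}", "gene_id": f"S{i}", "event_type": "SE",
                         "exon_length": 50, "is_missplicing": i < 5})
        for i in range(40):
            rows.append({"event_id": f"o{i}", "gene_id": f"O{i}", "event_type": "SE",
                         "exon_length": 50, "is_missplicing": i < 5})
        df = pd.DataFrame(rows)
        genes = [f"S{i}" for i in range(10)] + [f"O{i}" for i in range(40)]
        gs = GeneSet.from_iterable("asd", {f"S{i}" for i in range(10)})
        res = gene_level_enrichment(df, gs, genes)
        assert (res.table.a, res.table.b, res.table.c, res.table.d) == (5, 5, 5, 35)
        assert res.odds_ratio == pytest.approx(7.0)

    def test_detected_genes_must_cover_tested(self):
        df = diff_frame(10, 2, 5, 1)
        gs = GeneSet.from_iterable("asd", {"S0"})
        with pytest.raises(ValueError, match="detected_genes"):
            gene_level_enrichment(df, gs, ["S0"])

    def test_infinite_or_when_set_saturated(self):
        rows = [
            {"event_id": "e1", "gene_id": "S0", "event_type": "SE", "exon_length": 50,
             "is_missplicing": True},
            {"event_id": "e2", "gene_id": "O0", "event_type": "SE", "exon_length": 50,
             "is_missplicing": False},
        ]
        res = gene_level_enrichment(
            pd.DataFrame(rows), GeneSet.from_iterable("asd", {"S0"}), ["S0", "O0"]
        )
        assert math.isinf(res.odds_ratio)


class TestMicroexon:
    @pytest.mark.parametrize(
        "etype,length,expected",
        [("SE", 12, True), ("SE", 3, True), ("SE", 33, True),
         ("SE", 34, False), ("SE", 2, False), ("RI", 20, False), ("MXE", 10, False)],
    )
    def test_classification_band(self, etype, length, expected):
        assert classify_microexon(etype, length) is expected

    def test_mie_enrichment_directionality(self):
        # miE share 5% overall but 20% among called in-set events -> OR > 1
        rows = []
        for i in range(200):
            in_set = i < 40
            called = in_set and i < 20
            is_mie = (i < 4) or (called and i < 8)
            rows.append({"event_id": f"e{i}", "gene_id": f"{'S' if in_set else 'O'}{i}",
                         "event_type": "SE", "exon_length": 20 if is_mie else 100,
                         "is_missplicing": called})
        df = pd.DataFrame(rows)
        gs = GeneSet.from_iterable("asd", {r["gene_id"] for r in rows if r["gene_id"].startswith("S")})
        res = mie_enrichment(df, gs)
        assert res.odds_ratio > 1.0
        assert res.extras["pct_mie_missplice_in_set"] > res.extras["pct_mie_detected_se"]

    def test_no_mie_events_degenerate(self):
        df = diff_frame(30, 3, 10, 3)  # all exon_length 100
        gs = GeneSet.from_iterable("asd", {f"S{i}" for i in range(10)})
        with pytest.warns(UserWarning, match="degenerate margin"):
            res = mie_enrichment(df, gs)
        assert res.odds_ratio == 0.0 or math.isnan(res.odds_ratio)


class TestOverlap:
    def test_worked_overlap_table(self):
        universe = [f"a{i}" for i in range(100)]
        mapping = [(f"a{i}", f"b{i}") for i in range(100)]
        called_a = {f"a{i}" for i in range(30)}
        called_b = {f"b{i}" for i in range(15)} | {f"b{i}" for i in range(95, 100)}
        res = overlap_events(called_a, called_b, mapping, universe)
        assert res.n_overlap == 15
        t = res.table
        assert (t.a, t.b, t.c, t.d) == (15, 15, 5, 65)
        assert res.odds_ratio == pytest.approx(13.0)

    def test_disjoint_calls_depleted(self):
        universe = [f"a{i}" for i in range(40)]
        mapping = [(f"a{i}", f"b{i}") for i in range(40)]
        res = overlap_events(
            {f"a{i}" for i in range(10)}, {f"b{i}" for i in range(10, 20)}, mapping, universe
        )
        assert res.n_overlap == 0 and res.odds_ratio < 1

    def test_unknown_universe_id_rejected(self):
        with pytest.raises(ValueError, match="missing from mapping"):
            overlap_events(set(), set(), [("a1", "b1")], ["a1", "a2"])

    def test_independent_calls_give_null_or(self, rng):
        medians = []
        for _ in range(100):
            universe = [f"a{i}" for i in range(200)]
            mapping = [(f"a{i}", f"b{i}") for i in range(200)]
            ca = {u for u in universe if rng.random() < 0.3}
            cb = {f"b{i}" for i in range(200) if rng.random() < 0.3}
            or_ = overlap_events(ca, cb, mapping, universe).odds_ratio
            if np.isfinite(or_) and or_ > 0:
                medians.append(or_)
        assert 0.6 <= float(np.median(medians)) <= 1.6

    def test_gene_set_fractions(self):
        universe = ["a1", "a2"]
        mapping = [("a1", "b1"), ("a2", "b2")]
        res = overlap_events(
            {"a1", "a2"}, {"b1", "b2"}, mapping, universe,
            gene_of={"a1": "g1", "a2": "g2"},
            gene_sets=[GeneSet.from_iterable("s", {"g1"})],
        )
        assert res.fraction_in_focal_sets["s"] == pytest.approx(0.5)


class TestEnrichmentTable:
    def test_bh_across_sets_monotone(self, small_bundle):
        from misplice.events import events_to_frame
        from misplice.psi import call_missplicing, differential_table

        diff = call_missplicing(
            differential_table(small_bundle.counts, small_bundle.design,
                               events_to_frame(small_bundle.events))
        )
        table = enrichment_table(diff, small_bundle.gene_sets, mode="event")
        assert len(table) == len(small_bundle.gene_sets)
        srt = table.sort_values("p")
        assert (srt["q"].diff().dropna() >= -1e-12).all()
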