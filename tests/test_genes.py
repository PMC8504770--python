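"""Gene context: nearest features, category partition, orientation tests."""

import math

import numpy as np
import pandas as pd
import pytest

from mobilome.genes import (CATEGORIES, GeneFeature, InsertionContext,
                            classify_all, classify_insertion, nearest_gene,
                            orientation_chi_square, read_gene_gff,
                            recent_insertion_report)
from mobilome.inventory import TECopy


def _te(start, end, strand="+", seq="chr1", cid="t1"):
    return TECopy(seq, start, end, strand, "famA", "DTX", cid)


def _gene(start, end, strand="+", seq="chr1", gid="g1", exons=None):
    g = GeneFeature(seq, start, end, strand, gid,
                    exons if exons is not None else [(start, end)])
    g.validate()
    return g


class TestNearestGene:
    def test_overlapping_gene_distance_zero(self):
        hits = nearest_gene(_te(100, 200), [_gene(150, 400)])
        assert hits == [(hits[0][0], 0)]

    def test_gap_measured_edge_to_edge(self):
        (g, gap), = nearest_gene(_te(100, 200), [_gene(300, 400)])
        assert gap == 100

    def test_equidistant_genes_both_reported(self):
        genes = [_gene(0, 50, gid="left"), _gene(250, 300, gid="right")]
        hits = nearest_gene(_te(100, 200), genes)
        assert sorted(h[0].gene_id for h in hits) == ["left", "right"]
        assert all(gap == 50 for _, gap in hits)

    def test_different_sequence_not_considered(self):
        assert nearest_gene(_te(0, 100), [_gene(0, 100, seq="chr2")]) == []

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            genes = [_gene(int(s), int(s) + int(l), gid=f"g{k}",
                           seq=f"chr{rng.integers(1, 3)}")
                     for k, (s, l) in enumerate(zip(rng.integers(0, 5000, 12),
                                                    rng.integers(50, 400, 12)))]
            te = _te(int(rng.integers(0, 5000)),
                     int(rng.integers(0, 5000)) + 100,
                     seq=f"chr{rng.integers(1, 3)}")
            same = [g for g in genes if g.seq_id == te.seq_id]
            if same:
                def gap(g):
                    if te.end <= g.start:
                        return g.start - te.end
                    if g.end <= te.start:
                        return te.start - g.end
                    return 0
                best = min(gap(g) for g in same)
                expect = sorted(g.gene_id for g in same if gap(g) == best)
            else:
                expect = []
            got = sorted(h[0].gene_id for h in nearest_gene(te, genes))
            assert got == expect


class TestClassification:
    def test_te_inside_gene_overlapping_exon_is_exonic_sense(self):
        g = _gene(100, 1000, "+", exons=[(100, 300), (600, 1000)])
        ctx = classify_insertion(_te(150, 400, "+"), g)
        assert (ctx.category, ctx.orientation) == ("te_inside_gene_exonic",
                                                   "sense")

    def test_te_between_exons_is_intronic(self):
        g = _gene(100, 1000, "+", exons=[(100, 300), (600, 1000)])
        ctx = classify_insertion(_te(350, 500, "-"), g)
        assert (ctx.category, ctx.orientation) == ("te_inside_gene_intronic",
                                                   "antisense")

    def test_te_spanning_plus_strand_start_is_5prime_overlap(self):
        ctx = classify_insertion(_te(50, 150), _gene(100, 500, "+"))
        assert ctx.category == "overlap_5prime"

    def test_strand_awareness_flips_gene_ends(self):
        # same coordinates, minus-strand gene: its 5' end is at the right
        ctx = classify_insertion(_te(50, 150), _gene(100, 500, "-"))
        assert ctx.category == "overlap_3prime"
        ctx = classify_insertion(_te(450, 600), _gene(100, 500, "-"))
        assert ctx.category == "overlap_5prime"

    def test_abutting_boundaries(self):
        ctx = classify_insertion(_te(50, 100), _gene(100, 500))
        assert ctx.category == "boundary_gene_start_eq_te_end"
        assert ctx.gap_distance == 0
        ctx = classify_insertion(_te(500, 600), _gene(100, 500))
        assert ctx.category == "boundary_gene_end_eq_te_start"

    def test_gene_swallowed_by_te_flagged_excluded(self):
        ctx = classify_insertion(_te(50, 900), _gene(100, 500))
        assert ctx.category == "gene_inside_te" and ctx.excluded

    def test_near_threshold_strict(self):
        assert classify_insertion(_te(0, 100), _gene(2099, 2500)).category == \
            "next_to_gene"  # gap 1999
        assert classify_insertion(_te(0, 100), _gene(2100, 2500)).category == \
            "none"  # gap exactly 2000

    def test_undetermined_strand(self):
        ctx = classify_insertion(_te(0, 100, strand="."), _gene(500, 900))
        assert ctx.orientation == "undetermined"

    def test_every_pair_maps_to_exactly_one_category(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            ts = int(rng.integers(0, 400))
            te = _te(ts, ts + int(rng.integers(1, 300)),
                     strand=str(rng.choice(["+", "-"])))
            gs = int(rng.integers(0, 400))
            half = int(rng.integers(1, 200))
            g = _gene(gs, gs + 2 * half, str(rng.choice(["+", "-"])),
                      exons=[(gs, gs + half)])
            ctx = classify_insertion(te, g)
            assert ctx.category in CATEGORIES

    def test_planted_context_categories_recovered_exactly(self, context_bundle):
        contexts = classify_all(context_bundle.te_copies(),
                                [_gene_from_truth(r)
                                 for r in context_bundle.truth_genes.itertuples()])
        got = {c.te_copy_id: c.category for c in contexts}
        for r in context_bundle.truth_contexts.itertuples():
            assert got[r.copy_id] == r.category, r.copy_id


def _gene_from_truth(r):
    exons = [tuple(map(int, e.split("-"))) for e in r.exons.split(";")]
    return GeneFeature(r.seq_id, r.start, r.end, r.strand, r.gene_id, exons)


def _chi2_sf_independent(x, df):
    """Chi-square survival function from the series/erfc closed forms
    (no scipy): recurrence sf(x, df+2) = sf(x, df) + pdf-term."""
    if df % 2 == 0:
        term = math.exp(-x / 2)
        sf = term
        for k in range(1, df // 2):
            term *= (x / 2) / k
            sf += term
        return sf
    sf = math.erfc(math.sqrt(x / 2))
    term = math.sqrt(2 * x / math.pi) * math.exp(-x / 2)
    for k in range(1, (df - 1) // 2 + 1):
        sf += term
        term *= x / (2 * k + 1)
    return sf


class TestOrientationTest:
    def test_balanced_counts_give_zero_statistic(self):
        res = orientation_chi_square({"a": (25, 25), "b": (40, 40)})
        assert res.per_category["a"] == (0.0, 1.0)
        assert res.omnibus_statistic == pytest.approx(0.0)
        assert res.omnibus_p == pytest.approx(1.0)

    def test_five_prime_bias_matches_hand_pearson(self):
        res = orientation_chi_square({"five": (304, 239)})
        chi2, p = res.per_category["five"]
        assert chi2 == pytest.approx(2 * 32.5**2 / 271.5)
        assert p < 0.01

    def test_zero_total_category_excluded_with_log(self):
        res = orientation_chi_square({"a": (10, 20), "b": (0, 0),
                                      "c": (15, 15)})
        assert res.excluded == ["b"]
        assert res.omnibus_df == 1

    def test_omnibus_p_matches_independent_survival_function(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            k = int(rng.integers(2, 8))
            counts = {f"c{i}": (int(rng.integers(5, 400)),
                                int(rng.integers(5, 400)))
                      for i in range(k)}
            res = orientation_chi_square(counts)
            assert res.omnibus_df == k - 1
            assert res.omnibus_p == pytest.approx(
                _chi2_sf_independent(res.omnibus_statistic, res.omnibus_df),
                abs=1e-8)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            orientation_chi_square({"a": (-1, 5)})


class TestRecentReport:
    def _contexts(self):
        return [
            InsertionContext("c1", "g1", "next_to_gene", "sense", 100),
            InsertionContext("c2", "g2", "te_inside_gene_exonic", "antisense", 0),
            InsertionContext("c3", "g3", "overlap_5prime", "sense", 0),
            InsertionContext("c4", "g4", "overlap_3prime", "sense", 0),
            InsertionContext("c5", "g5", "none", "sense", 5000),
        ]

    def test_strict_divergence_threshold(self):
        div = {"c1": 0.019, "c2": 0.02, "c3": 0.01, "c4": 0.3, "c5": 0.0}
        table, _ = recent_insertion_report(self._contexts(), div,
                                           {"c1": "X", "c2": "X", "c3": "Y"})
        total = table[table.superfamily == "total"].iloc[0]
        # c2 sits exactly at 2% (excluded); c4 too old; c5 not near a gene
        assert total.n_sites == 2
        assert total.next_to_genes == 1 and total.five_prime == 1

    def test_superfamily_rows_sum_to_total(self):
        div = {f"c{i}": 0.0 for i in range(1, 6)}
        table, orient = recent_insertion_report(
            self._contexts(), div,
            {"c1": "hAT", "c2": "hAT", "c3": "MITE", "c4": "MITE"})
        total = table[table.superfamily == "total"].iloc[0]
        body = table[table.superfamily != "total"]
        assert total.n_sites == body.n_sites.sum() == 4
        assert set(orient.columns) == {"site", "sense", "antisense"}

    def test_empty_contexts_all_zero(self):
        table, orient = recent_insertion_report([], {}, {})
        assert table[table.superfamily == "total"].iloc[0].n_sites == 0
        assert len(orient) == 0


class TestGeneGff:
    def test_round_trip_via_bundle(self, tiny_bundle_dir):
        genes = read_gene_gff(tiny_bundle_dir["gene_gff"])
        assert genes, "bundle should contain genes"
        for g in genes:
            assert g.exons, g.gene_id
            g.validate()
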