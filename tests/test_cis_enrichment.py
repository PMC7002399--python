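"""Insertion-site filtering, intersection, class rates and empirical nulls."""

import math

import numpy as np
import pandas as pd
import pytest

from cancerlnc.cis_enrichment import (
    class_rates,
    empirical_p,
    filter_insertions,
    genes_with_insertions,
    insertions_per_mb,
    length_matched_null,
    packaged_insertion_table_path,
    read_insertion_table,
    relocation_null,
    set_enrichment_test,
)
from cancerlnc.genome_model import GenomeLayout, Interval, IntervalSet
from conftest import oracle_fisher_p
from test_genome_model import make_gene


class TestFilter:
    def test_length_boundary(self):
        """Records longer than 1000 bp are discarded; exactly 1000 is kept."""
        ivs = IntervalSet(
            [Interval("chr1", 0, 1000), Interval("chr1", 5000, 6001)]
        )
        kept, counts = filter_insertions(ivs, exclude_pc=False)
        assert [iv.length for iv in kept] == [1000]
        assert counts == {"input": 2, "after_length_filter": 1, "after_pc_filter": 1}

    def test_pc_overlap_removed(self):
        pc = IntervalSet([Interval("chr1", 100, 200)])
        ivs = IntervalSet([Interval("chr1", 150, 160), Interval("chr1", 500, 510)])
        kept, _ = filter_insertions(ivs, pc, exclude_pc=True)
        assert [iv.start for iv in kept] == [500]

    def test_empty_input(self):
        kept, counts = filter_insertions(IntervalSet([]))
        assert len(kept) == 0 and counts["input"] == 0


class TestFixtureTable:
    def test_printed_records_group_to_eight_genes(self):
        """The packaged table holds 10 records over 8 genes, with DLEU2 and
        MONC carrying two records each."""
        sites = read_insertion_table(packaged_insertion_table_path())
        assert len(sites) == 10
        per_gene = pd.Series([s.interval.label for s in sites]).value_counts()
        assert len(per_gene) == 8
        assert per_gene["DLEU2"] == 2
        assert per_gene["MONC"] == 2
        assert set(per_gene[per_gene == 2].index) == {"DLEU2", "MONC"}
        assert all(s.interval.length <= 1000 for s in sites)
        assert all(s.mouse_interval is not None for s in sites)


class TestGenesWithInsertions:
    def test_adjacent_not_counted(self):
        g = make_gene("G", "chr1", "+", [(100, 200)])
        ins = IntervalSet([Interval("chr1", 90, 100)])  # ends exactly at start
        assert genes_with_insertions([g], ins)["G"] == 0
        ins2 = IntervalSet([Interval("chr1", 90, 101)])
        assert genes_with_insertions([g], ins2)["G"] == 1

    def test_masked_span_excludes_pc_overlap(self):
        g = make_gene("G", "chr1", "+", [(0, 1000)])
        pc = IntervalSet([Interval("chr1", 0, 500)])
        ins = IntervalSet([Interval("chr1", 100, 110)])  # inside masked part
        assert genes_with_insertions([g], ins, mask_pc=True, pc_spans=pc)["G"] == 0
        assert genes_with_insertions([g], ins)["G"] == 1

    def test_matches_all_pairs_scan(self):
        rng = np.random.default_rng(7)
        genes = []
        for i in range(30):
            s = int(rng.integers(0, 50_000))
            genes.append(make_gene(f"G{i:02d}", "chr1", "+", [(s, s + int(rng.integers(100, 3000)))]))
        ins = IntervalSet(
            [
                Interval("chr1", int(s), int(s) + int(rng.integers(1, 500)))
                for s in rng.integers(0, 50_000, 40)
            ]
        )
        got = genes_with_insertions(genes, ins)
        for g in genes:
            span = g.span
            want = sum(
                1 for iv in ins if iv.start < span.end and span.start < iv.end
            )
            assert got[g.gene_id] == want


class TestSetEnrichment:
    def test_equal_rates_or_one(self):
        focal = [make_gene(f"f{i}", "chr1", "+", [(i * 1000, i * 1000 + 500)]) for i in range(4)]
        back = [make_gene(f"b{i}", "chr1", "+", [(100_000 + i * 1000, 100_000 + i * 1000 + 500)]) for i in range(4)]
        ins = IntervalSet(
            [Interval("chr1", 100, 110), Interval("chr1", 100_100, 100_110)]
        )
        res = set_enrichment_test(focal, back, ins)
        assert res["odds_ratio"] == 1.0

    def test_planted_table_p_matches_oracle(self):
        # genes arranged so exactly [[8,114],[64,15763]]-shaped rates appear
        # at a reduced size: [[8,12],[4,76]]
        focal, back, ins = [], [], []
        pos = 0
        for i in range(20):
            focal.append(make_gene(f"f{i:02d}", "chr1", "+", [(pos, pos + 500)]))
            if i < 8:
                ins.append(Interval("chr1", pos, pos + 10))
            pos += 1000
        for i in range(80):
            back.append(make_gene(f"b{i:02d}", "chr1", "+", [(pos, pos + 500)]))
            if i < 4:
                ins.append(Interval("chr1", pos, pos + 10))
            pos += 1000
        res = set_enrichment_test(focal, back, IntervalSet(ins))
        assert res["odds_ratio"] > 1
        assert res["fisher_p"] == pytest.approx(
            oracle_fisher_p([[8, 12], [4, 76]]), rel=1e-6
        )

    def test_empty_focal_errors(self):
        with pytest.raises(ValueError):
            set_enrichment_test([], [make_gene("b", "chr1", "+", [(0, 10)])], IntervalSet([]))


class TestClassRates:
    def layout(self):
        return GenomeLayout({"chr1": 1_000_000})

    def test_rate_arithmetic(self):
        gold = [make_gene("G", "chr1", "+", [(0, 500_000)])]
        ins = IntervalSet([Interval("chr1", 10, 20), Interval("chr1", 100, 120)])
        rates = class_rates(self.layout(), gold, [], [], [], ins)
        assert rates.bp["gold_pc"] == 500_000
        assert rates.rates_per_mb["gold_pc"] == pytest.approx(4.0)

    def test_partition_sums_to_genome(self):
        rng = np.random.default_rng(8)
        groups = [[], [], [], []]
        for i in range(40):
            s = int(rng.integers(0, 990_000))
            g = make_gene(f"g{i:02d}", "chr1", "+", [(s, s + int(rng.integers(100, 20_000)))])
            groups[int(rng.integers(0, 4))].append(g)
        rates = class_rates(self.layout(), *groups, IntervalSet([]))
        assert sum(rates.bp.values()) == 1_000_000

    def test_precedence_and_per_base_oracle(self):
        rng = np.random.default_rng(9)
        groups = [[], [], [], []]
        spans = {}
        for i in range(20):
            s = int(rng.integers(0, 9_000))
            e = s + int(rng.integers(50, 800))
            cls = int(rng.integers(0, 4))
            g = make_gene(f"g{i:02d}", "chr1", "+", [(s, e)])
            groups[cls].append(g)
            spans[g.gene_id] = (s, e, cls)
        layout = GenomeLayout({"chr1": 10_000})
        ins = IntervalSet(
            [Interval("chr1", int(s), int(s) + 5) for s in rng.integers(0, 9_990, 15)]
        )
        rates = class_rates(layout, *groups, ins)
        # per-base oracle
        names = ["gold_pc", "other_pc", "focal_lnc", "other_lnc"]
        paint = np.full(10_000, 4)
        for order, name in reversed(list(enumerate(names))):
            for s, e, cls in spans.values():
                if cls == order:
                    paint[s:e] = order
        for order, name in enumerate(names):
            assert rates.bp[name] == int((paint == order).sum())
        assert rates.bp["intergenic"] == int((paint == 4).sum())
        for iv in ins:
            want = int(paint[iv.start:iv.end].min())
        counts = {n: 0 for n in names + ["intergenic"]}
        for iv in ins:
            cls = int(paint[iv.start:iv.end].min())
            counts[(names + ["intergenic"])[cls]] += 1
        assert rates.counts == counts

    def test_missing_chromosome_errors(self):
        g = make_gene("G", "chr9", "+", [(0, 100)])
        with pytest.raises(ValueError, match="chr"):
            class_rates(self.layout(), [g], [], [], [], IntervalSet([]))


class TestEmpiricalP:
    def test_observed_above_all_nulls(self):
        assert empirical_p(10.0, np.zeros(1000)) == 0.0

    def test_observed_equal_to_all_nulls(self):
        assert empirical_p(5.0, np.full(100, 5.0)) == 1.0

    def test_median_counting(self):
        nulls = np.arange(101, dtype=float)
        assert empirical_p(50.0, nulls) == pytest.approx(51 / 101)

    def test_less_direction(self):
        assert empirical_p(0.0, np.arange(10.0), "less") == pytest.approx(1 / 10)

    def test_conservative_mode(self):
        assert empirical_p(10.0, np.zeros(99), conservative=True) == pytest.approx(1 / 100)


class TestLengthMatchedNull:
    def test_empty_insertions_p_one(self, small_bundle):
        b = small_bundle
        focal = [b.genes[g] for g in b.census_ids]
        back = [b.genes[g] for g in b.lnc_ids if g not in set(b.census_ids)]
        res = length_matched_null(focal, back, IntervalSet([]), n_iter=20, seed=0)
        assert res.observed == 0.0
        assert res.p_value == 1.0

    def test_statistic_identity_on_focal(self, small_bundle):
        b = small_bundle
        focal = [b.genes[g] for g in b.census_ids]
        assert insertions_per_mb(focal, b.insertions) == pytest.approx(
            length_matched_null(focal, focal + [], b.insertions, n_iter=1, seed=0).observed
        )

    def test_same_seed_identical_null(self, small_bundle):
        b = small_bundle
        focal = [b.genes[g] for g in b.census_ids]
        back = [b.genes[g] for g in b.lnc_ids if g not in set(b.census_ids)]
        r1 = length_matched_null(focal, back, b.insertions, n_iter=10, seed=4)
        r2 = length_matched_null(focal, back, b.insertions, n_iter=10, seed=4)
        assert np.array_equal(r1.null_values, r2.null_values)


class TestRelocationNull:
    def test_empty_insertions_p_one(self, small_bundle):
        b = small_bundle
        focal = [b.genes[g] for g in b.census_ids]
        res = relocation_null(
            focal, IntervalSet([]), b.layout, excluded=b.pc_spans, n_iter=10, seed=0
        )
        assert res.observed == 0.0
        assert res.p_value == 1.0

    def test_relocations_avoid_exclusions_and_keep_length(self):
        """Every placement falls in an allowed gap and preserves length
        (checked via an instrumented insertion set covering the exclusions)."""
        layout = GenomeLayout({"chr1": 100_000})
        excluded = IntervalSet([Interval("chr1", 20_000, 80_000)])
        genes = [make_gene(f"g{i}", "chr1", "+", [(0, 5_000)]) for i in range(5)]
        # insertions exactly covering the excluded region: a relocated gene
        # overlapping the exclusion would register as a hit
        ins = IntervalSet([Interval("chr1", 20_000, 80_000)])
        res = relocation_null(genes, ins, layout, excluded, n_iter=50, seed=1)
        assert res.null_values.max() == 0  # no relocated gene ever overlaps

    def test_gene_longer_than_gaps_errors(self):
        layout = GenomeLayout({"chr1": 10_000})
        excluded = IntervalSet([Interval("chr1", 4_000, 6_000)])
        g = make_gene("BIG", "chr1", "+", [(0, 9_000)])
        with pytest.raises(ValueError, match="BIG"):
            relocation_null([g], IntervalSet([]), layout, excluded, n_iter=1, seed=0)

    def test_planted_enrichment_recovered(self, small_bundle):
        b = small_bundle
        focal = [b.genes[g] for g in b.census_ids]
        filtered, _ = filter_insertions(b.insertions, b.pc_spans)
        res = relocation_null(
            focal, filtered, b.layout, excluded=b.pc_spans, n_iter=200, seed=2
        )
        assert res.p_value <= 0.01
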