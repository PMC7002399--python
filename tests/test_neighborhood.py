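"""Matched sampling, orientation classification and coexpression nulls."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cancerlnc.genome_model import GeneModel, Interval, IntervalSet, Transcript
from cancerlnc.neighborhood import (
    build_pairs,
    classify_all,
    classify_gene,
    distance_matched_control_pairs,
    divergent_partner_enrichment,
    match_distribution,
    pair_correlation,
    select_pf_subset,
    shuffled_pair_null,
)
from conftest import oracle_fisher_p
from test_genome_model import make_gene


class TestMatchDistribution:
    def test_pool_equals_target_matches_exactly(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 1, 200)
        pool = {f"g{i}": float(v) for i, v in enumerate(vals)}
        sample = match_distribution(pool, vals, n_bins=10, seed=1)
        # binned histogram of the sample equals the target proportions
        assert np.allclose(
            sample.achieved_proportions, sample.target_proportions, atol=1 / len(sample)
        )

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        pool = {f"g{i}": float(v) for i, v in enumerate(rng.uniform(0, 1, 400))}
        target = rng.uniform(0, 1, 200)
        s1 = match_distribution(pool, target, seed=42)
        s2 = match_distribution(pool, target, seed=42)
        assert s1.ids == s2.ids

    def test_improves_ks_distance(self):
        """Exponential target vs uniform pool: the matched sample is closer
        to the target than the pool is."""
        rng = np.random.default_rng(2)
        pool_vals = rng.uniform(0, 8, 2000)
        pool = {f"g{i}": float(v) for i, v in enumerate(pool_vals)}
        target = rng.exponential(1.0, 300)
        sample = match_distribution(pool, target, n_bins=20, seed=3)
        sample_vals = np.array([pool[g] for g in sample.ids])
        d_sample = stats.ks_2samp(sample_vals, target).statistic
        d_pool = stats.ks_2samp(pool_vals, target).statistic
        assert d_sample < d_pool

    def test_empty_bin_dropped_with_warning(self):
        pool = {f"g{i}": 0.0 for i in range(50)}
        target = np.concatenate([np.zeros(50), np.full(50, 10.0)])
        with pytest.warns(UserWarning, match="dropped"):
            sample = match_distribution(pool, target, n_bins=4, seed=0)
        assert len(sample.ids) > 0

    def test_bad_n_bins(self):
        with pytest.raises(ValueError):
            match_distribution({"a": 1.0}, [1.0], n_bins=1)


class TestSelectPfSubset:
    def test_retains_reference_distributions(self):
        rng = np.random.default_rng(4)
        n = 2000
        cons = {f"g{i}": float(v) for i, v in enumerate(rng.beta(2, 5, n))}
        expr = {f"g{i}": float(v) for i, v in enumerate(rng.lognormal(1, 1, n))}
        reference = [f"g{i}" for i in range(0, 200)]
        background = [f"g{i}" for i in range(200, n)]
        subset = select_pf_subset(background, cons, expr, reference, seed=5)
        # background drawn from the same law: matched subset should not
        # differ detectably from the reference in either variable
        for valmap in (cons, expr):
            p = stats.ks_2samp(
                [valmap[g] for g in subset], [valmap[g] for g in reference]
            ).pvalue
            assert p > 0.1

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        cons = {f"g{i}": float(v) for i, v in enumerate(rng.random(500))}
        expr = {f"g{i}": float(v) for i, v in enumerate(rng.random(500))}
        ref = [f"g{i}" for i in range(50)]
        bg = [f"g{i}" for i in range(50, 500)]
        assert select_pf_subset(bg, cons, expr, ref, seed=9) == select_pf_subset(
            bg, cons, expr, ref, seed=9
        )

    def test_too_small_subset_errors(self):
        cons = {"a": 1.0, "b": 1.0, "c": 5.0}
        expr = {"a": 1.0, "b": 1.0, "c": 1.0}
        with pytest.raises(ValueError, match="too small"):
            select_pf_subset(["b"], cons, expr, ["a"], seed=0, min_size=10)


def oracle_classify(lnc_span, lnc_strand, pc_list, genic=10_000):
    """Independent straight-line decision table for a single-transcript
    lncRNA: (start, end, strand) vs [(start, end, strand, id), ...]."""
    ls, le = lnc_span
    ltss = ls if lnc_strand == "+" else le - 1
    overlapping = [
        (min(e, le) - max(s, ls), pid, st)
        for s, e, st, pid in pc_list
        if min(e, le) - max(s, ls) > 0
    ]
    if overlapping:
        ov, pid, st = max(overlapping, key=lambda t: (t[0], [-ord(c) for c in t[1]]))
        return ("overlapping_sense" if st == lnc_strand else "overlapping_antisense")
    dists = []
    for s, e, st, pid in pc_list:
        ptss = s if st == "+" else e - 1
        gap = max(s - le, ls - e, 0)
        dists.append((abs(ptss - ltss), pid, st, ptss, gap))
    if not dists:
        return "intergenic"
    near = min(dists, key=lambda t: (t[0], t[1]))
    if near[0] > genic and min(d[4] for d in dists) > genic:
        return "intergenic"
    _, pid, st, ptss, _ = near
    if st != lnc_strand:
        if lnc_strand == "+":
            return "divergent" if ptss <= ltss else "convergent"
        return "divergent" if ptss >= ltss else "convergent"
    if lnc_strand == "+":
        return "samestrand_pc_up" if ptss < ltss else "samestrand_pc_down"
    return "samestrand_pc_up" if ptss > ltss else "samestrand_pc_down"


class TestClassification:
    def pc(self, pid, s, e, strand):
        return make_gene(pid, "chr1", strand, [(s, e)], biotype="protein_coding")

    def test_far_gene_is_intergenic(self):
        lnc = make_gene("L", "chr1", "+", [(100_000, 105_000)])
        pc = [self.pc("P", 200_000, 210_000, "+")]
        assert classify_gene(lnc, pc).genomic_class == "intergenic"

    def test_head_to_head_is_divergent(self):
        """TSSs 500 bp apart on opposite strands, transcribed apart."""
        lnc = make_gene("L", "chr1", "+", [(10_500, 12_000)])
        pc = [self.pc("P", 5_000, 10_000, "-")]  # pc TSS at 9_999, pointing left
        res = classify_gene(lnc, pc)
        assert res.genomic_class == "divergent"
        assert res.partner == "P"
        assert res.tss_distance == 501

    def test_convergent(self):
        lnc = make_gene("L", "chr1", "+", [(0, 5_000)])  # points right
        pc = [self.pc("P", 6_000, 12_000, "-")]  # TSS 11_999, points left
        assert classify_gene(lnc, pc).genomic_class == "convergent"

    def test_samestrand_pc_up(self):
        lnc = make_gene("L", "chr1", "+", [(20_000, 25_000)])
        pc = [self.pc("P", 12_000, 19_000, "+")]
        assert classify_gene(lnc, pc).genomic_class == "samestrand_pc_up"

    def test_overlap_sense_and_antisense(self):
        lnc = make_gene("L", "chr1", "+", [(1_000, 3_000)])
        assert (
            classify_gene(lnc, [self.pc("P", 2_000, 8_000, "+")]).genomic_class
            == "overlapping_sense"
        )
        assert (
            classify_gene(lnc, [self.pc("P", 2_000, 8_000, "-")]).genomic_class
            == "overlapping_antisense"
        )

    def test_empty_pc_set_errors(self):
        lnc = make_gene("L", "chr1", "+", [(0, 100)])
        with pytest.raises(ValueError):
            classify_gene(lnc, [])

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_independent_decision_table(self, seed):
        rng = np.random.default_rng(100 + seed)
        pcs = []
        pc_list = []
        for i in range(4):
            s = int(rng.integers(0, 150_000))
            e = s + int(rng.integers(2_000, 30_000))
            st = "+" if rng.random() < 0.5 else "-"
            pid = f"P{i}"
            pcs.append(self.pc(pid, s, e, st))
            pc_list.append((s, e, st, pid))
        ls = int(rng.integers(0, 150_000))
        le = ls + int(rng.integers(1_000, 20_000))
        lst = "+" if rng.random() < 0.5 else "-"
        lnc = make_gene("L", "chr1", lst, [(ls, le)])
        got = classify_gene(lnc, pcs).genomic_class
        assert got == oracle_classify((ls, le), lst, pc_list)

    def test_threshold_extremes(self):
        """genic threshold -> infinity makes every non-overlapping gene
        non-intergenic; -> 0 makes every non-overlapping gene intergenic."""
        lnc = make_gene("L", "chr1", "+", [(100_000, 101_000)])
        pc = [self.pc("P", 500_000, 510_000, "+")]
        assert classify_gene(lnc, pc, genic_distance=10**12).genomic_class != "intergenic"
        assert classify_gene(lnc, pc, genic_distance=0).genomic_class == "intergenic"

    def test_majority_vote_over_transcripts(self):
        """Two transcripts vote divergent, one intergenic: gene is divergent."""
        pc = [self.pc("P", 5_000, 10_000, "-")]
        exA = (Interval("chr1", 10_500, 12_000, "+"),)
        exB = (Interval("chr1", 10_600, 12_500, "+"),)
        exC = (Interval("chr1", 80_000, 90_000, "+"),)
        gene = GeneModel(
            "L", "L", "lncRNA",
            (
                Transcript("L.t1", "L", "+", exA),
                Transcript("L.t2", "L", "+", exB),
                Transcript("L.t3", "L", "+", exC),
            ),
        )
        assert classify_gene(gene, pc).genomic_class == "divergent"


class TestDivergentEnrichment:
    def test_all_partners_gold_or_one(self):
        classes = pd.DataFrame(
            {
                "gene_id": ["a", "b", "c", "d"],
                "genomic_class": ["divergent"] * 4,
                "partner": ["P1", "P1", "P2", "P2"],
                "tss_distance": [1.0] * 4,
            }
        )
        res = divergent_partner_enrichment(
            classes, {"P1", "P2"}, ["a", "b"], ["c", "d"]
        )
        assert res["odds_ratio"] == 1.0

    def test_fisher_matches_oracle(self):
        rows = []
        # focal: 4 of 20 divergent-to-gold; background: 5 of 100
        for i in range(20):
            rows.append((f"f{i}", "divergent", "GOLD" if i < 4 else "X", 1.0))
        for i in range(100):
            rows.append((f"b{i}", "divergent", "GOLD" if i < 5 else "X", 1.0))
        classes = pd.DataFrame(
            rows, columns=["gene_id", "genomic_class", "partner", "tss_distance"]
        )
        res = divergent_partner_enrichment(
            classes, {"GOLD"}, [f"f{i}" for i in range(20)],
            [f"b{i}" for i in range(100)],
        )
        assert res["fisher_p"] == pytest.approx(
            oracle_fisher_p([[4, 16], [5, 95]]), rel=1e-6
        )

    def test_planted_enrichment_recovered(self, small_bundle):
        b = small_bundle
        classes = classify_all(b.lnc_genes, b.pc_genes)
        res = divergent_partner_enrichment(
            classes, b.gold_pc_ids, b.census_ids,
            [g for g in b.lnc_ids if g not in set(b.census_ids)],
        )
        assert res["odds_ratio"] > 1
        assert res["fisher_p"] < 0.05


class TestPairCorrelation:
    def expr(self, data, samples=("s1", "s2")):
        return pd.DataFrame(data, columns=list(samples))

    def test_proportional_pairs_r_one(self):
        expr = pd.DataFrame(
            {
                "s1": [1.0, 2.0, 3.0, 2.0, 4.0, 6.0],
            },
            index=["l1", "l2", "l3", "p1", "p2", "p3"],
        )
        pairs = pd.DataFrame(
            {"lnc_id": ["l1", "l2", "l3"], "pc_id": ["p1", "p2", "p3"]}
        )
        r = pair_correlation(pairs, expr, transform="raw")
        assert r["s1"] == pytest.approx(1.0)

    def test_hand_computed_value(self):
        lnc_vals = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        pc_vals = np.array([2.0, 3.0, 1.0, 9.0, 4.0])
        expr = pd.DataFrame(
            {"s1": np.concatenate([lnc_vals, pc_vals])},
            index=[f"l{i}" for i in range(5)] + [f"p{i}" for i in range(5)],
        )
        pairs = pd.DataFrame(
            {"lnc_id": [f"l{i}" for i in range(5)], "pc_id": [f"p{i}" for i in range(5)]}
        )
        r = pair_correlation(pairs, expr, transform="raw")
        # textbook formula by hand
        x, y = lnc_vals - lnc_vals.mean(), pc_vals - pc_vals.mean()
        want = (x * y).sum() / math.sqrt((x**2).sum() * (y**2).sum())
        assert r["s1"] == pytest.approx(want)

    def test_zero_variance_flagged_nan(self):
        expr = pd.DataFrame(
            {"s1": [1.0, 1.0, 1.0, 2.0, 3.0, 4.0]},
            index=["l1", "l2", "l3", "p1", "p2", "p3"],
        )
        pairs = pd.DataFrame(
            {"lnc_id": ["l1", "l2", "l3"], "pc_id": ["p1", "p2", "p3"]}
        )
        assert math.isnan(pair_correlation(pairs, expr, "raw")["s1"])

    def test_permuted_partners_center_on_zero(self):
        rng = np.random.default_rng(8)
        n = 30
        expr = pd.DataFrame(
            rng.lognormal(2, 1, (2 * n, 4)),
            index=[f"l{i}" for i in range(n)] + [f"p{i}" for i in range(n)],
        )
        expr.columns = [f"s{j}" for j in range(4)]
        rs = []
        for _ in range(250):
            perm = rng.permutation(n)
            pairs = pd.DataFrame(
                {
                    "lnc_id": [f"l{i}" for i in range(n)],
                    "pc_id": [f"p{perm[i]}" for i in range(n)],
                }
            )
            rs.extend(pair_correlation(pairs, expr).to_numpy())
        assert abs(np.mean(rs)) < 0.05

    def test_too_few_pairs_error(self):
        expr = pd.DataFrame({"s1": [1.0, 2.0]}, index=["l1", "p1"])
        pairs = pd.DataFrame({"lnc_id": ["l1"], "pc_id": ["p1"]})
        with pytest.raises(ValueError):
            pair_correlation(pairs, expr)


class TestControls:
    def test_distance_matched_controls_match_distance(self, small_bundle):
        b = small_bundle
        census = set(b.census_ids)
        observed = build_pairs([b.genes[g] for g in b.census_ids], b.pc_genes)
        candidates = [b.genes[g] for g in b.lnc_ids if g not in census]
        partners = [b.genes[p] for p in set(observed["pc_id"])]
        control = distance_matched_control_pairs(
            observed, candidates, partners, seed=3
        )
        assert len(control) >= 5
        assert not set(control["lnc_id"]) & set(observed["lnc_id"])
        p = stats.ks_2samp(
            control["tss_distance"], observed["tss_distance"]
        ).pvalue
        assert p > 0.1

    def test_control_pairs_deterministic(self, small_bundle):
        b = small_bundle
        observed = build_pairs([b.genes[g] for g in b.census_ids], b.pc_genes)
        candidates = [b.genes[g] for g in b.lnc_ids if g not in set(b.census_ids)]
        partners = [b.genes[p] for p in set(observed["pc_id"])]
        c1 = distance_matched_control_pairs(observed, candidates, partners, seed=3)
        c2 = distance_matched_control_pairs(observed, candidates, partners, seed=3)
        pd.testing.assert_frame_equal(c1, c2)


class TestShuffledNull:
    def test_planted_correlation_detected(self, small_bundle):
        b = small_bundle
        pairs = b.pairs[b.pairs["lnc_id"].isin(set(b.census_ids))]
        null = shuffled_pair_null(pairs, b.expression, n_iter=100, seed=2)
        assert null.observed.mean() > null.pooled_null.mean() + 0.2
        assert null.ks_p < 0.01

    def test_independent_pairs_not_rejected(self):
        rng = np.random.default_rng(10)
        n = 40
        expr = pd.DataFrame(
            rng.lognormal(2, 1, (2 * n, 8)),
            index=[f"l{i}" for i in range(n)] + [f"p{i}" for i in range(n)],
            columns=[f"s{j}" for j in range(8)],
        )
        pairs = pd.DataFrame(
            {"lnc_id": [f"l{i}" for i in range(n)], "pc_id": [f"p{i}" for i in range(n)]}
        )
        null = shuffled_pair_null(pairs, expr, n_iter=60, seed=4)
        assert null.ks_p > 0.05

    def test_single_iteration_reproducible(self, small_bundle):
        b = small_bundle
        pairs = b.pairs.head(10)
        n1 = shuffled_pair_null(pairs, b.expression, n_iter=1, seed=5)
        n2 = shuffled_pair_null(pairs, b.expression, n_iter=1, seed=5)
        assert np.array_equal(n1.null_values, n2.null_values, equal_nan=True)

    def test_null_mean_approaches_zero_many_pairs(self):
        rng = np.random.default_rng(11)
        n = 500
        expr = pd.DataFrame(
            rng.lognormal(2, 1, (2 * n, 3)),
            index=[f"l{i}" for i in range(n)] + [f"p{i}" for i in range(n)],
            columns=["s1", "s2", "s3"],
        )
        pairs = pd.DataFrame(
            {"lnc_id": [f"l{i}" for i in range(n)], "pc_id": [f"p{i}" for i in range(n)]}
        )
        null = shuffled_pair_null(pairs, expr, n_iter=30, seed=6)
        assert abs(null.pooled_null.mean()) < 0.02
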