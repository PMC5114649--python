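"""Allelic pipeline: IUPAC genome, read simulation, toy mapping,
mapability filtering, phased assignment, imbalance statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import fisher_exact_enum
from xescape.allelic import (
    assign_alleles,
    batch_imbalance_test,
    build_personalized_genome,
    enumerate_simulated_reads,
    imbalance_score,
    mapability_filter,
    merge_replicates,
    replicate_concordance,
    summarize_sites,
    toy_unique_mapper,
    unique_read_counts,
)
from xescape.core import GenomicInterval, HetSite
from xescape.simulate import AllelicSimConfig, simulate_allelic_counts


def _het(site_id, pos, ref="G", alt="A", chrom="chrX", xi="paternal"):
    mat, pat = (alt, ref) if xi == "paternal" else (ref, alt)
    return HetSite(site_id, chrom, pos, ref, alt, maternal=mat, paternal=pat)


class TestPersonalizedGenome:
    def test_ga_becomes_r_and_ct_becomes_y(self):
        genome = {"chrX": "GGGCCC"}
        hets = [_het("h1", 1, "G", "A"),
                HetSite("h2", "chrX", 4, "C", "T", maternal="C", paternal="T")]
        out = build_personalized_genome(genome, hets)
        assert out["chrX"] == "GRGCYC"

    def test_empty_het_list_identity(self):
        genome = {"chrX": "ACGT"}
        assert build_personalized_genome(genome, []) == genome

    def test_reference_mismatch_names_site(self):
        genome = {"chrX": "TTTT"}
        with pytest.raises(ValueError, match="h1"):
            build_personalized_genome(genome, [_het("h1", 0, "G", "A")])


class TestReadEnumeration:
    def test_interior_het_yields_144_reads(self, toy_genome):
        genome = build_personalized_genome(toy_genome.sequences, toy_genome.hets)
        het = toy_genome.hets[2]
        reads = enumerate_simulated_reads(
            genome, [het], toy_genome.peaks.intervals, read_len=36)
        assert len(reads) == 144  # 36 offsets x 2 alleles x 2 strands

    def test_het_near_contig_start_truncated(self):
        genome = {"chrX": "ACGT" * 30}
        het = _het("h", 10, ref="G", alt="T")
        assert genome["chrX"][10] == "G"
        reads = enumerate_simulated_reads(
            genome, [het], [GenomicInterval("chrX", 0, 120)], read_len=36)
        assert len(reads) == 44  # 11 fitting windows x 2 x 2

    def test_het_outside_regions_skipped(self):
        genome = {"chrX": "ACGT" * 100}
        het = _het("h", 200, ref=genome["chrX"][200], alt="C")
        reads = enumerate_simulated_reads(
            genome, [het], [GenomicInterval("chrX", 0, 50)], read_len=36)
        assert reads == []

    def test_regions_widened_by_100bp(self):
        genome = {"chrX": "ACGT" * 200}
        pos = 340  # outside [400, 500) but inside the 100 bp flank
        het = _het("h", pos, ref=genome["chrX"][pos], alt="C")
        reads = enumerate_simulated_reads(
            genome, [het], [GenomicInterval("chrX", 400, 500)], read_len=36)
        assert len(reads) == 144

    def test_reads_carry_the_substituted_allele(self):
        genome = {"chrX": "A" * 100}
        het = _het("h", 50, ref="A", alt="C")
        reads = enumerate_simulated_reads(
            genome, [het], [GenomicInterval("chrX", 0, 100)], read_len=10)
        plus = [(a, off, seq) for _, a, s, off, seq in reads if s == "+"]
        for allele, off, seq in plus:
            assert seq[off] == allele


class TestToyMapper:
    def test_unique_multi_unmapped_statuses(self, toy_genome):
        genome = build_personalized_genome(toy_genome.sequences, toy_genome.hets)
        chrom = "chrX"
        dup = toy_genome.dup_source
        unique_read = genome[chrom][2000:2036]
        dup_read = toy_genome.sequences[chrom][dup.start + 10:dup.start + 46]
        reads = [("u", "A", "+", 0, unique_read),
                 ("m", "A", "+", 0, dup_read),
                 ("n", "A", "+", 0, "N" * 36)]
        statuses = {r[0]: r[4] for r in toy_unique_mapper(reads, genome)}
        assert statuses["u"] == "unique"
        assert statuses["m"] == "multi"
        assert statuses["n"] == "unmapped"

    def test_mapability_filter_arithmetic(self):
        counts = pd.DataFrame({
            "site_id": ["a", "a", "b", "b", "c", "c"],
            "allele": ["A", "G"] * 3,
            "n_unique": [72, 72, 100, 44, 0, 0],
        })
        assert mapability_filter(counts) == ["a"]  # 0.694 dropped; 0-total dropped

    def test_toy_genome_end_to_end(self, toy_genome):
        """The het planted inside the duplication fails the mapability
        filter; balanced unique-region hets survive."""
        genome = build_personalized_genome(toy_genome.sequences, toy_genome.hets)
        reads = enumerate_simulated_reads(genome, toy_genome.hets,
                                          toy_genome.peaks.intervals)
        mapped = toy_unique_mapper(reads, genome)
        kept = mapability_filter(unique_read_counts(mapped))
        dup_het = toy_genome.hets_in_duplication[0]
        assert dup_het not in kept
        assert set(kept) == {h.site_id for h in toy_genome.hets} - {dup_het}


class TestAssignmentAndMerging:
    def test_paternal_xi_assignment(self):
        # canonical strongly Xi-biased pattern: paternal allele 474 reads
        het = HetSite("s1", "chrX", 10, "G", "A", maternal="A", paternal="G")
        raw = pd.DataFrame([{"site_id": "s1", "dataset_id": "d1", "factor": "YY1",
                             "lab": "lab1", "count_allele_a": 474,
                             "count_allele_b": 3}])  # allele_a = G = paternal
        out = assign_alleles(raw, [het], xi_parent="paternal")
        assert out.loc[0, "ra"] == 3 and out.loc[0, "ri"] == 474

    def test_flipping_xi_parent_swaps_counts(self):
        het = HetSite("s1", "chrX", 10, "G", "A", maternal="A", paternal="G")
        raw = pd.DataFrame([{"site_id": "s1", "dataset_id": "d1", "factor": "f",
                             "lab": "l", "count_allele_a": 7, "count_allele_b": 13}])
        a = assign_alleles(raw, [het], xi_parent="paternal")
        b = assign_alleles(raw, [het], xi_parent="maternal")
        assert (a.loc[0, "ra"], a.loc[0, "ri"]) == (b.loc[0, "ri"], b.loc[0, "ra"])

    def test_unknown_site_excluded(self):
        raw = pd.DataFrame([{"site_id": "ghost", "dataset_id": "d", "factor": "f",
                             "lab": "l", "count_allele_a": 1, "count_allele_b": 2}])
        assert len(assign_alleles(raw, [])) == 0

    def test_same_lab_replicates_merge(self):
        counts = pd.DataFrame([
            ("s1", "r1", "YY1", "labA", 10, 5),
            ("s1", "r2", "YY1", "labA", 7, 3),
            ("s1", "r3", "YY1", "labB", 1, 1),
        ], columns=["site_id", "dataset_id", "factor", "lab", "ra", "ri"])
        merged = merge_replicates(counts).set_index("dataset_id")
        assert merged.loc["YY1.labA", ["ra", "ri"]].tolist() == [17, 8]
        assert merged.loc["YY1.labB", ["ra", "ri"]].tolist() == [1, 1]


class TestImbalanceScore:
    @pytest.mark.parametrize("ra,ri,expected", [
        (0, 0, 0.0),
        (3, 474, np.log2(4 / 475)),    # ~ -6.8919
        (140, 0, np.log2(141)),        # ~ +7.1394
    ])
    def test_known_values(self, ra, ri, expected):
        assert imbalance_score(ra, ri) == pytest.approx(expected, abs=1e-9)

    @given(st.integers(0, 10_000), st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_antisymmetry(self, a, b):
        assert imbalance_score(a, b) == pytest.approx(-imbalance_score(b, a),
                                                      abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            imbalance_score(-1, 2)


class TestBatchImbalance:
    def test_matches_enumeration_on_worked_table(self):
        counts = pd.DataFrame([
            ("s1", "d1", "f", "l", 5, 50),
            ("s2", "d1", "f", "l", 995, 950),
        ], columns=["site_id", "dataset_id", "factor", "lab", "ra", "ri"])
        pairs = batch_imbalance_test(counts).set_index("site_id")
        p_oracle = fisher_exact_enum([[5, 50], [995, 950]], "two-sided")
        assert pairs.loc["s1", "raw_p"] == pytest.approx(p_oracle, abs=1e-10)

    def test_fisher_matches_enumeration_on_small_margins(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            ra, ri = int(rng.integers(1, 15)), int(rng.integers(1, 15))
            ta, ti = ra + int(rng.integers(0, 16)), ri + int(rng.integers(0, 16))
            counts = pd.DataFrame(
                [("s1", "d", "f", "l", ra, ri),
                 ("s2", "d", "f", "l", ta - ra, ti - ri)],
                columns=["site_id", "dataset_id", "factor", "lab", "ra", "ri"])
            pairs = batch_imbalance_test(counts)
            for rec in pairs.itertuples(index=False):
                rest_a = counts.ra.sum() - rec.ra
                rest_i = counts.ri.sum() - rec.ri
                p_oracle = fisher_exact_enum([[rec.ra, rec.ri], [rest_a, rest_i]])
                assert rec.raw_p == pytest.approx(p_oracle, abs=1e-10)

    def test_zero_count_pairs_not_tested(self):
        counts = pd.DataFrame([
            ("s1", "d1", "f", "l", 10, 0),
            ("s2", "d1", "f", "l", 10, 10),
            ("s3", "d1", "f", "l", 8, 12),
        ], columns=["site_id", "dataset_id", "factor", "lab", "ra", "ri"])
        pairs = batch_imbalance_test(counts)
        assert set(pairs.site_id) == {"s2", "s3"}

    def test_norm_matching_site_has_odds_near_zero(self):
        counts = pd.DataFrame(
            [(f"s{i}", "d", "f", "l", 80, 20) for i in range(20)],
            columns=["site_id", "dataset_id", "factor", "lab", "ra", "ri"])
        pairs = batch_imbalance_test(counts)
        assert np.abs(pairs["log2_odds"]).max() < 0.1
        assert (pairs["raw_p"] == 1.0).all()

    def test_haldane_odds_sign_convention(self):
        counts = pd.DataFrame([
            ("xa", "d", "f", "l", 90, 10),
            ("xi", "d", "f", "l", 5, 95),
            ("bulk", "d", "f", "l", 500, 500),
        ], columns=["site_id", "dataset_id", "factor", "lab", "ra", "ri"])
        pairs = batch_imbalance_test(counts).set_index("site_id")
        assert pairs.loc["xa", "log2_odds"] > 0 > pairs.loc["xi", "log2_odds"]

    def test_planted_xi_sites_rank_top_and_pass_fdr(self):
        hits = 0
        for seed in range(10):
            cfg = AllelicSimConfig(n_sites=200, frac_xa_biased=1.0,
                                   xi_biased_site_ids=tuple(f"xi{i}" for i in range(5)),
                                   seed=seed)
            counts, truth = simulate_allelic_counts(cfg)
            pairs = batch_imbalance_test(merge_replicates(counts))
            xi = set(truth.index[truth == "xi_biased"])
            top5 = set(pairs.sort_values("raw_p").drop_duplicates("site_id")
                       .head(5).site_id)
            sig_sites = set(pairs[pairs.significant].site_id)
            if top5 == xi and xi <= sig_sites:
                hits += 1
        assert hits >= 9


class TestSummaries:
    def _pairs(self, rows):
        return pd.DataFrame(rows, columns=["site_id", "dataset_id", "ra", "ri",
                                           "raw_p", "log2_odds", "score",
                                           "fdr_p", "significant"])

    def test_consistent_xi_site(self):
        pairs = self._pairs([("s1", f"d{i}", 1, 50, 1e-9, -3.0, -5.0, 1e-8, True)
                             for i in range(3)])
        summary, per_site = summarize_sites(pairs)
        assert per_site.loc["s1", "direction"] == "Xi"
        assert summary["n_consistent_xi"] == 1

    def test_mixed_direction_site(self):
        pairs = self._pairs([("s1", "d1", 1, 50, 1e-9, -3.0, -5.0, 1e-8, True),
                             ("s1", "d2", 50, 1, 1e-9, 3.0, 5.0, 1e-8, True)])
        _, per_site = summarize_sites(pairs)
        assert per_site.loc["s1", "direction"] == "mixed"

    def test_no_significant_pairs_empty_summary(self):
        pairs = self._pairs([("s1", "d1", 5, 5, 0.9, 0.0, 0.0, 0.95, False)])
        summary, per_site = summarize_sites(pairs)
        assert summary["n_significant_pairs"] == 0 and per_site.empty

    def test_peak_restriction_never_adds_sites(self, allelic_default):
        counts, _ = allelic_default
        merged = merge_replicates(counts)
        all_pairs = batch_imbalance_test(merged)
        subset = merged[merged.site_id.isin(sorted(set(merged.site_id))[:50])]
        sub_pairs = batch_imbalance_test(subset)
        assert len(sub_pairs) <= len(all_pairs)
        assert set(sub_pairs.site_id) <= set(all_pairs.site_id) | set(subset.site_id)


class TestReplicateConcordance:
    def test_identical_replicates_r_one(self):
        s = pd.Series([0.5, -2.0, 3.0, 1.0], index=list("abcd"))
        r, _ = replicate_concordance(s, s.copy())
        assert r == pytest.approx(1.0)

    def test_independent_noise_low_r(self):
        rng = np.random.default_rng(0)
        a = pd.Series(rng.normal(size=100))
        b = pd.Series(rng.normal(size=100))
        r, _ = replicate_concordance(a, b)
        assert abs(r) < 0.25

    def test_binomial_replicates_match_reported_consistency(self):
        """Replicates sharing true per-site allele fractions at ~67 sites
        correlate at r >= 0.8 with default read depths."""
        rs = []
        for seed in range(5):
            cfg = AllelicSimConfig(n_sites=65, n_datasets=2, seed=seed)
            counts, _ = simulate_allelic_counts(cfg)
            reps = [g.set_index("site_id") for _, g in counts.groupby("dataset_id")]
            s0 = pd.Series(imbalance_score(reps[0].ra, reps[0].ri), index=reps[0].index)
            s1 = pd.Series(imbalance_score(reps[1].ra, reps[1].ri), index=reps[1].index)
            rs.append(replicate_concordance(s0, s1)[0])
        assert min(rs) >= 0.8

    def test_constant_vector_undefined(self):
        s = pd.Series([1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            replicate_concordance(s, pd.Series([0.1, 0.2, 0.3]))

    def test_too_few_shared_sites(self):
        with pytest.raises(ValueError):
            replicate_concordance(pd.Series([1.0], index=["a"]),
                                  pd.Series([1.0], index=["a"]))
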