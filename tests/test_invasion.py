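"""Strand-invasion detection contracts: upstream-context extraction, 5'
dedup, the consecutive-5'-mismatch matcher (vs a brute-force oracle), the
report's analytic null (vs Monte Carlo), the read filter, and the read-start
nucleotide profile."""

import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import (brute_force_match, monte_carlo_match_probability)
from tsoumi.invasion import (AlignedUmiRead, annotate_upstream,
                             assign_features, dedup_5p, filter_invasion,
                             invasion_report, match_umi_upstream,
                             random_match_probability, readstart_profile)
from tsoumi.io import AlignmentRecord, revcomp
from tsoumi.simulate import SimConfig, simulate_dataset


def make_read(umi="ACGTACGT", upstream="A" * 20, read_id="c0:m0", start=100,
              strand="+", chrom="chr1"):
    return AlignedUmiRead(read_id, umi, chrom, start, start + 50, strand,
                          upstream)


@pytest.fixture(scope="module")
def annotated_umi_reads(umi_only_dataset):
    reads, dropped = annotate_upstream(umi_only_dataset.alignments,
                                       umi_only_dataset.genome)
    assert dropped == 0
    return reads


class TestAnnotateUpstream:
    def test_plus_strand_window_definition(self):
        genome = {"chr1": "".join(random.Random(0).choices("ACGT", k=300))}
        aln = AlignmentRecord("c0:m0", "chr1", 100, 150, "+", umi="ACGTACGT")
        (read,), _ = annotate_upstream([aln], genome)
        assert read.upstream20 == genome["chr1"][80:100]

    def test_minus_strand_window_is_revcomp_after_end(self):
        genome = {"chr1": "".join(random.Random(1).choices("ACGT", k=300))}
        aln = AlignmentRecord("c0:m0", "chr1", 50, 100, "-", umi="ACGTACGT")
        (read,), _ = annotate_upstream([aln], genome)
        assert read.upstream20 == revcomp(genome["chr1"][100:120])

    def test_contig_edge_reads_dropped_and_counted(self):
        genome = {"chr1": "ACGT" * 30}
        near_edge = AlignmentRecord("c0:m0", "chr1", 5, 40, "+", umi="A" * 8)
        missing = AlignmentRecord("c0:m1", "chrX", 50, 90, "+", umi="A" * 8)
        reads, dropped = annotate_upstream([near_edge, missing], genome)
        assert reads == [] and dropped == 2

    def test_invasion_reads_carry_umi_in_window(self, umi_only_dataset,
                                                annotated_umi_reads):
        truth = umi_only_dataset.truth.reads.set_index("read_id")
        n_checked = 0
        for r in annotated_umi_reads:
            row = truth.loc[r.read_id]
            if row.is_invasion and not row.invasion_motif:
                assert r.upstream20[-8:] == r.umi
                n_checked += 1
        assert n_checked > 0


def test_antisense_fraction_counts_opposed_strands():
    from tsoumi.invasion import antisense_fraction
    from tsoumi.io import GeneInterval
    genes = [GeneInterval("chr1", 0, 1000, "gA", "+")]
    reads = [make_read(read_id=f"c0:m{i}", strand=s)
             for i, s in enumerate("++-+")]
    for r in reads:
        r.gene = "gA"
    assert antisense_fraction(reads, genes) == pytest.approx(0.25)


class TestDedup:
    def test_identical_reads_collapse(self):
        a = make_read(read_id="c0:m0")
        b = make_read(read_id="c0:m0:d1")
        assert len(dedup_5p([a, b])) == 1

    def test_same_umi_position_different_upstream_retained(self):
        a = make_read(upstream="A" * 20)
        b = make_read(upstream="C" * 20, read_id="c0:m1")
        assert len(dedup_5p([a, b])) == 2

    def test_opposite_strands_not_collapsed(self):
        a = make_read(strand="+")
        b = make_read(strand="-", read_id="c0:m1")
        assert len(dedup_5p([a, b])) == 2

    def test_idempotent(self, annotated_umi_reads):
        once = dedup_5p(annotated_umi_reads)
        assert len(dedup_5p(once)) == len(once)

    def test_order_insensitive_key_set(self, annotated_umi_reads):
        sample = annotated_umi_reads[:500]
        keys_fwd = {r.dedup_key for r in dedup_5p(sample)}
        keys_rev = {r.dedup_key for r in dedup_5p(sample[::-1])}
        assert keys_fwd == keys_rev

    def test_duplicate_factor_collapses_to_molecules(self):
        ds = simulate_dataset(SimConfig(
            seed=21, n_cells=2, reads_per_cell=800, frac_umi_reads=1.0,
            p_background=0.0, p_invasion=0.0, duplicate_factor=3,
            n_het_snps=0))
        reads, _ = annotate_upstream(ds.alignments, ds.genome)
        assert len(reads) == 3 * ds.truth.reads.molecule_id.nunique()
        assert len(dedup_5p(reads)) == ds.truth.reads.molecule_id.nunique()


class TestMatcher:
    def test_perfect_match_level_zero(self):
        up = "T" * 12 + "ACGTACGT"
        assert match_umi_upstream("ACGTACGT", up) == 0

    def test_consecutive_5p_mismatches_forgiven(self):
        # the 5-suffix TACGT occurs, but no 6/7/8-suffix does -> m=3
        umi = "TTTTACGT"
        up = "GGGGGGGGGGGGGGGTACGT"
        assert match_umi_upstream(umi, up, 3) == 3
        assert brute_force_match(umi, up, 3, "none") == 3
        assert match_umi_upstream(umi, up, 2) is None

    def test_internal_mismatches_never_forgiven(self):
        # one internal mismatch at the 4th base: no suffix of length >= 5 matches
        assert match_umi_upstream("ACGTACGT", "AAAAAAAAAAAAACGAACGT", 3) is None

    def test_spacer_ggg_motif_required_after_umi(self):
        up = "ACGT" + "ACGTACGT" + "CTAACGGG"
        assert match_umi_upstream("ACGTACGT", up, motif="spacer_ggg",
                                  spacer="CTAAC") == 0
        assert match_umi_upstream("ACGTACGT", "ACGTCTAA" + "ACGTACGT" + "CTAA",
                                  motif="spacer_ggg", spacer="CTAAC") is None

    def test_adjacent_only_restricts_to_window_end(self):
        up = "ACGTACGT" + "T" * 12
        assert match_umi_upstream("ACGTACGT", up) == 0
        assert match_umi_upstream("ACGTACGT", up, adjacent_only=True) is None

    def test_parameter_bounds(self):
        with pytest.raises(ValueError):
            match_umi_upstream("ACGTACGT", "A" * 20, 4)
        with pytest.raises(ValueError):
            match_umi_upstream("ACGTACGT", "A" * 20, motif="bogus")

    def test_agrees_with_brute_force_on_random_draws(self):
        """10^4 random (umi, upstream) draws, half with a planted suffix
        match, across all motif modes and mismatch caps."""
        rng = np.random.default_rng(99)
        bases = np.array(list("ACGT"))
        for i in range(10_000):
            umi = "".join(bases[rng.integers(0, 4, 8)])
            up = list(bases[rng.integers(0, 4, 20)])
            motif = ("none", "GGG", "spacer_ggg")[i % 3]
            if i % 2:  # plant the m-suffix (+ motif) at a random offset
                m = int(rng.integers(0, 4))
                tail = {"none": "", "GGG": "GGG",
                        "spacer_ggg": "CTAACGGG"}[motif]
                q = umi[m:] + tail
                if len(q) <= 20:
                    off = int(rng.integers(0, 20 - len(q) + 1))
                    up[off:off + len(q)] = list(q)
            up = "".join(up)
            max_m = int(rng.integers(0, 4))
            assert match_umi_upstream(umi, up, max_m, motif) == \
                brute_force_match(umi, up, max_m, motif)


class TestReportAndNull:
    def test_analytic_null_matches_monte_carlo(self):
        for m, motif_len in [(0, 0), (2, 0), (0, 3)]:
            analytic = random_match_probability(m, motif_len)
            mc = monte_carlo_match_probability(m, motif_len,
                                               n_draws=150_000, seed=m * 7 + motif_len)
            sd = np.sqrt(analytic * (1 - analytic) / 150_000)
            assert abs(mc - analytic) < 3 * sd

    def test_all_invasion_reads_match_at_level_zero(self):
        ds = simulate_dataset(SimConfig(
            seed=22, n_cells=1, reads_per_cell=400, frac_umi_reads=1.0,
            p_background=0.0, p_invasion=1.0, n_het_snps=0))
        reads, _ = annotate_upstream(ds.alignments, ds.genome)
        report = invasion_report(dedup_5p(reads))
        assert report.pct(0, "none") == 100.0

    def test_empty_input_reports_nan_not_zero(self):
        report = invasion_report([])
        assert report.n_dedup_reads == 0
        assert np.isnan(report.table.pct).all()

    def test_match_fraction_monotone_in_mismatch_and_motif(
            self, annotated_umi_reads):
        report = invasion_report(dedup_5p(annotated_umi_reads))
        t = report.table
        for motif in ("none", "GGG", "spacer_ggg"):
            pcts = t[t.motif == motif].sort_values("mismatch").pct.to_numpy()
            assert (np.diff(pcts) >= 0).all()
        for m in range(4):
            none_pct = t[(t.motif == "none") & (t.mismatch == m)].pct.iloc[0]
            for motif in ("GGG", "spacer_ggg"):
                assert t[(t.motif == motif)
                         & (t.mismatch == m)].pct.iloc[0] <= none_pct

    def test_feature_breakdown_partitions_reads(self, umi_only_dataset,
                                                annotated_umi_reads):
        reads = dedup_5p(annotated_umi_reads)
        assign_features(reads, umi_only_dataset.genes)
        report = invasion_report(reads)
        per = report.per_feature
        sub = per[(per.motif == "none") & (per.mismatch == 0)]
        assert sub.n.sum() == report.n_dedup_reads
        assert sub.n_match.sum() == report.table[
            (report.table.motif == "none")
            & (report.table.mismatch == 0)].n_match.iloc[0]


class TestFilter:
    def test_verbatim_match_removed(self):
        r = make_read(umi="ACGTACGT", upstream="T" * 12 + "ACGTACGT")
        retained, removed = filter_invasion([r], max_mismatch=1)
        assert retained == [] and removed == 1

    def test_match_only_at_m2_retained_at_max1(self):
        # 6-suffix GTACGT present, 7- and 8-suffix absent
        umi = "TTGTACGT"
        up = "AAAAAAAAAAAAAAGTACGT"
        assert match_umi_upstream(umi, up, 3) == 2
        retained, removed = filter_invasion([make_read(umi=umi, upstream=up)],
                                            max_mismatch=1)
        assert removed == 0 and len(retained) == 1

    def test_consistent_with_report_counts(self, annotated_umi_reads):
        dedup = dedup_5p(annotated_umi_reads)
        _, removed = filter_invasion(dedup, max_mismatch=1)
        report = invasion_report(dedup)
        assert removed == report.table[
            (report.table.motif == "none")
            & (report.table.mismatch == 1)].n_match.iloc[0]

    def test_high_recall_on_truth_invasions(self, umi_only_dataset,
                                            annotated_umi_reads):
        truth = umi_only_dataset.truth.reads
        invasion_ids = set(truth[truth.is_invasion].read_id)
        retained, _ = filter_invasion(annotated_umi_reads, max_mismatch=1)
        surviving = invasion_ids & {r.read_id for r in retained}
        assert len(surviving) <= 0.01 * len(invasion_ids)


class TestReadstartProfile:
    def test_ggg_preceded_reads_give_unit_g_frequency(self):
        reads = [make_read(upstream="A" * 17 + "GGG", read_id=f"c0:m{i}")
                 for i in range(10)]
        prof = readstart_profile(reads)
        for pos in (-3, -2, -1):
            assert prof.loc[pos, "G"] == 1.0
        assert prof.loc[-4, "A"] == 1.0

    def test_uniform_genome_background_is_flat(self):
        # sparse reads on a large genome so upstream windows rarely overlap
        # (overlapping windows would correlate the per-position tallies)
        ds = simulate_dataset(SimConfig(
            seed=23, n_cells=2, reads_per_cell=1500, frac_umi_reads=1.0,
            p_background=0.0, p_invasion=0.0, n_het_snps=0,
            chrom_len=300_000, gene_len=4000))
        reads, _ = annotate_upstream(ds.alignments, ds.genome)
        prof = readstart_profile(dedup_5p(reads), seed=1)
        n = len(dedup_5p(reads))
        sd = np.sqrt(0.25 * 0.75 / n)
        assert (np.abs(prof[list("ACGT")].to_numpy() - 0.25) < 3 * sd).all()

    def test_invasion_with_ggg_knob_enriches_g_near_start(self):
        ds = simulate_dataset(SimConfig(
            seed=24, n_cells=2, reads_per_cell=3000, frac_umi_reads=1.0,
            p_background=0.0, p_invasion=0.4, p_invasion_ggg=1.0,
            n_het_snps=0))
        reads, _ = annotate_upstream(ds.alignments, ds.genome)
        prof = readstart_profile(dedup_5p(reads), seed=1)
        for pos in (-3, -2, -1):
            assert prof.loc[pos, "G"] > 0.35  # ~0.25 background + planted GGG
        assert prof.loc[-4, "G"] < 0.35

    def test_sampling_is_seeded_and_bounded(self, annotated_umi_reads):
        a = readstart_profile(annotated_umi_reads, n_sample=200, seed=5)
        b = readstart_profile(annotated_umi_reads, n_sample=200, seed=5)
        assert a.equals(b)
        rows = a.sum(axis=1)
        assert np.allclose(rows, 1.0)
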