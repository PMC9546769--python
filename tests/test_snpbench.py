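"""SNP benchmark contracts: exome hard filters, per-cell reference lists,
TP/FP/FN identities, the internal pileup caller, depth curves and cell
aggregation."""

from collections import defaultdict

import numpy as np
import pytest

from tsoumi.io import AlignmentRecord, VariantRecord
from tsoumi.simulate import SimConfig, simulate_dataset
from tsoumi.snpbench import (ExomeReference, aggregate_cells, benchmark_cell,
                             call_snps, classify_cell_snps, depth_curve,
                             hard_filter_exome, reference_list_for_cell)

CAPTURE = [("chr1", 0, 10_000)]
PASS_INFO = {"QD": 25.0, "FS": 0.5, "SOR": 1.0, "MQ": 60.0,
             "MQRankSum": 0.0, "ReadPosRankSum": 0.0}


def variant(pos, ref="A", alt="T", dp=10, qual=50.0, info=None, chrom="chr1"):
    return VariantRecord(chrom, pos, ref, alt, dp=dp, qual=qual,
                         info=dict(PASS_INFO if info is None else info))


def read(read_id, start, end, seq=None, chrom="chr1"):
    return AlignmentRecord(read_id, chrom, start, end, "+", seq=seq)


@pytest.fixture(scope="module")
def snp_dataset():
    return simulate_dataset(SimConfig(
        seed=41, n_cells=4, reads_per_cell=5000, p_invasion=0.0,
        p_tso_tagmentation=0.0, n_het_snps=50, error_rate=0.0))


@pytest.fixture(scope="module")
def snp_bench_inputs(snp_dataset):
    ds = snp_dataset
    exome = hard_filter_exome(ds.exome_variants, ds.capture_intervals)
    by_cell = defaultdict(list)
    for a in ds.alignments:
        by_cell[a.cell].append(a)
    return ds, exome, by_cell


class TestHardFilter:
    def test_low_qd_removed(self):
        v = variant(100, info=dict(PASS_INFO, QD=1.5))
        assert hard_filter_exome([v], CAPTURE).variants == []

    def test_threshold_is_strict(self):
        v = variant(100, info=dict(PASS_INFO, QD=2.0))
        assert hard_filter_exome([v], CAPTURE).variants == []

    def test_passing_variant_kept(self):
        v = variant(100)
        assert hard_filter_exome([v], CAPTURE).variants == [v]

    def test_missing_annotation_passes_by_default(self):
        v = variant(100, info={})
        assert hard_filter_exome([v], CAPTURE).variants == [v]
        assert hard_filter_exome([v], CAPTURE,
                                 missing_passes=False).variants == []

    def test_indels_and_mito_excluded(self):
        indel = VariantRecord("chr1", 100, "A", "AT", dp=10, info=dict(PASS_INFO))
        mito = variant(100, chrom="chrM")
        assert hard_filter_exome([indel, mito], CAPTURE + [("chrM", 0, 1000)]
                                 ).variants == []

    def test_planted_pass_fail_recovered(self, snp_bench_inputs):
        ds, exome, _ = snp_bench_inputs
        truth = ds.truth.variants
        expected = {(r.chrom, r.pos, r.alt)
                    for r in truth[truth.passes_filters].itertuples()}
        assert {v.key for v in exome.variants} == expected


class TestReferenceList:
    def test_coverage_boundary_strictly_more_than_two(self):
        exome = ExomeReference([variant(101)], CAPTURE)
        reads3 = [read(f"c0:m{i}", 90, 120) for i in range(3)]
        assert len(reference_list_for_cell(exome, reads3)) == 1
        assert reference_list_for_cell(exome, reads3[:2]) == []

    def test_simulated_reference_equals_truth_coverage(self, snp_bench_inputs):
        ds, exome, by_cell = snp_bench_inputs
        cell = "cell000"
        ref = reference_list_for_cell(exome, by_cell[cell])
        expected = set()
        for v in exome.variants:
            cov = sum(1 for a in by_cell[cell]
                      if a.chrom == v.chrom and a.start <= v.pos - 1 < a.end)
            if cov > 2:
                expected.add(v.key)
        assert {v.key for v in ref} == expected


class TestClassify:
    def test_empty_cell_vcf(self):
        ref = [variant(101), variant(202)]
        res = classify_cell_snps([], ref, CAPTURE)
        assert (res.n_tp, res.n_fp, res.n_fn) == (0, 0, 2)

    def test_alt_allele_mismatch_is_fp(self):
        ref = [variant(101, alt="T")]
        call = variant(101, alt="G", dp=8)
        res = classify_cell_snps([call], ref, CAPTURE)
        assert (res.n_tp, res.n_fp, res.n_fn) == (0, 1, 1)
        loose = classify_cell_snps([call], ref, CAPTURE, match_alt=False)
        assert (loose.n_tp, loose.n_fp, loose.n_fn) == (1, 0, 0)

    def test_dp_threshold_strict(self):
        ref = [variant(101)]
        res = classify_cell_snps([variant(101, dp=2)], ref, CAPTURE)
        assert res.n_tp == 0 and res.n_fn == 1

    def test_outside_capture_filtered(self):
        res = classify_cell_snps([variant(50_000, dp=9)], [], CAPTURE)
        assert res.n_fp == 0

    def test_unknown_contig_raises(self):
        with pytest.raises(ValueError, match="chr9"):
            classify_cell_snps([variant(101, chrom="chr9")], [variant(101)],
                               CAPTURE)

    def test_qual_thresholded_counts_bounded(self):
        ref = [variant(101)]
        calls = [variant(101, dp=9, qual=10.0), variant(300, dp=9, qual=50.0)]
        res = classify_cell_snps(calls, ref, CAPTURE)
        assert res.n_tp_qual <= res.n_tp
        assert res.n_fp_qual <= res.n_fp
        assert res.n_tp_qual == 0 and res.n_fp_qual == 1


class TestCaller:
    GENOME = {"chr1": "A" * 200}

    def test_two_alt_reads_required(self):
        reads1 = [read("c0:m0", 50, 60, seq="AAAAATAAAA")] + \
                 [read(f"c0:m{i}", 50, 60, seq="A" * 10) for i in range(1, 4)]
        assert call_snps(reads1, self.GENOME) == []
        reads2 = reads1 + [read("c0:m9", 50, 60, seq="AAAAATAAAA")]
        calls = call_snps(reads2, self.GENOME)
        assert [(v.pos, v.ref, v.alt, v.dp) for v in calls] == [(56, "A", "T", 5)]

    def test_alt_fraction_threshold(self):
        reads = [read(f"c0:m{i}", 50, 60, seq="AAAAATAAAA") for i in range(2)]
        reads += [read(f"c0:x{i}", 50, 60, seq="A" * 10) for i in range(10)]
        assert call_snps(reads, self.GENOME) == []  # 2/12 < 0.2


class TestBenchmarkPipeline:
    def test_identity_tp_plus_fn_and_perfect_recovery(self, snp_bench_inputs):
        """Error-free simulation: every covered planted SNP is recovered
        (pct_tp = 100) with zero false positives, for every cell."""
        ds, exome, by_cell = snp_bench_inputs
        assert len(exome.variants) == 50
        any_reference = False
        for cell, alns in by_cell.items():
            res = benchmark_cell(alns, ds.genome, exome, cell_id=cell)
            assert res.n_tp + res.n_fn == res.n_reference
            assert res.n_fp == 0
            if res.n_reference:
                any_reference = True
                assert res.pct_tp == 100.0
        assert any_reference

    def test_injected_miscalls_become_fp(self, snp_bench_inputs):
        ds, exome, by_cell = snp_bench_inputs
        cell = "cell001"
        alns = by_cell[cell]
        ref = reference_list_for_cell(exome, alns)
        calls = call_snps(alns, ds.genome)
        base = classify_cell_snps(calls, ref, exome.capture_intervals)
        taken = {v.key for v in calls} | {v.key for v in exome.variants}
        injected = []
        g = ds.genes[0]
        pos = g.start + 3
        while len(injected) < 7:
            key = (g.chrom, pos + 1, "T")
            ref_base = ds.genome[g.chrom][pos]
            if key not in taken and ref_base != "T":
                injected.append(VariantRecord(g.chrom, pos + 1, ref_base, "T",
                                              dp=9, qual=60.0))
                taken.add(key)
            pos += 1
        res = classify_cell_snps(calls + injected, ref,
                                 exome.capture_intervals)
        assert res.n_fp == base.n_fp + 7
        assert res.n_tp == base.n_tp

    def test_depth_curve_monotone_and_consistent(self, snp_bench_inputs):
        ds, exome, by_cell = snp_bench_inputs
        cell = "cell002"
        alns = by_cell[cell]
        curve = depth_curve(alns, [0, len(alns) // 4, len(alns)], seed=3,
                            genome=ds.genome, exome=exome, cell_id=cell)
        assert curve[0].n_tp == 0 and curve[0].n_fp == 0
        full = benchmark_cell(alns, ds.genome, exome, cell_id=cell)
        assert curve[-1].n_tp == full.n_tp
        assert curve[-1].n_fp == full.n_fp
        mean_tp_low = np.mean([depth_curve(alns, [len(alns) // 4], seed=s,
                                           genome=ds.genome, exome=exome
                                           )[0].n_tp for s in range(4)])
        assert mean_tp_low <= full.n_tp

    def test_depth_beyond_available_flagged(self, snp_bench_inputs):
        ds, exome, by_cell = snp_bench_inputs
        alns = by_cell["cell000"]
        (res,) = depth_curve(alns, [10 * len(alns)], seed=1,
                             genome=ds.genome, exome=exome)
        assert res.depth_exhausted
        assert res.depth_used == len(alns)

    def test_aggregate_single_cell_equals_cell_result(self, snp_bench_inputs):
        ds, exome, by_cell = snp_bench_inputs
        pooled = aggregate_cells(by_cell, k=1, seed=5, genome=ds.genome,
                                 exome=exome)
        single = benchmark_cell(by_cell[pooled.cell_id], ds.genome, exome,
                                cell_id=pooled.cell_id)
        assert (pooled.n_tp, pooled.n_fp, pooled.n_fn) == \
            (single.n_tp, single.n_fp, single.n_fn)

    def test_aggregate_all_cells_dominates_best_single(self, snp_bench_inputs):
        ds, exome, by_cell = snp_bench_inputs
        pooled = aggregate_cells(by_cell, k=len(by_cell), seed=5,
                                 genome=ds.genome, exome=exome)
        best_single = max(
            benchmark_cell(a, ds.genome, exome).n_tp
            for a in by_cell.values())
        assert pooled.n_tp >= best_single

    def test_aggregate_seeded_cell_choice_is_stable(self, snp_bench_inputs):
        ds, exome, by_cell = snp_bench_inputs
        a = aggregate_cells(by_cell, k=2, seed=9, genome=ds.genome, exome=exome)
        b = aggregate_cells(by_cell, k=2, seed=9, genome=ds.genome, exome=exome)
        assert a.cell_id == b.cell_id
        with pytest.raises(ValueError):
            aggregate_cells(by_cell, k=99, seed=1, genome=ds.genome,
                            exome=exome)
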