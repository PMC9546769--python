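"""Per-cell RNA SNP benchmarking against an exome-derived reference.

The exome call set is hard-filtered (QD > 2, FS < 60, SOR < 3, MQ > 40,
MQRankSum > -12.5, ReadPosRankSum > -8; SNVs only). For each cell, the
reference list is the subset of exome SNPs whose position is covered by more
than 2 of the cell's RNA reads; cell calls outside the exome capture
intervals are discarded; true positives are cell SNPs with DP > 2 matching
the reference list (by chrom, pos and alt allele), false negatives the
remainder of the reference list, false positives the remaining cell SNPs
with DP > 2. TP/FP are additionally reported at QUAL > 20.

The RNA-side caller used for synthetic data is a minimal pileup caller: a
site is called when >= 2 reads carry the same non-reference base and the alt
fraction is >= 0.2; QUAL is the Phred-scaled probability of seeing that many
alt reads from sequencing error alone. Real VCFs from any caller can be
supplied instead.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .io import AlignmentRecord, VariantRecord
from .simulate import downsample

DEFAULT_EXCLUDED_CONTIGS = frozenset({"chrM", "MT"})

# hard filters on the exome side: (operator, threshold), strict inequalities
HARD_FILTERS: dict[str, tuple[str, float]] = {
    "QD": (">", 2.0), "FS": ("<", 60.0), "SOR": ("<", 3.0),
    "MQ": (">", 40.0), "MQRankSum": (">", -12.5),
    "ReadPosRankSum": (">", -8.0),
}


@dataclass
class ExomeReference:
    """Hard-filtered exome SNVs plus the capture intervals they lie in."""

    variants: list[VariantRecord]
    capture_intervals: list[tuple[str, int, int]]  # 0-based half-open


@dataclass
class SnpBenchResult:
    """Per-cell benchmark counts at the stated DP/QUAL thresholds."""

    cell_id: str
    depth_used: int
    n_reference: int
    n_total_cell_snps: int
    n_tp: int
    n_tp_qual: int
    n_fn: int
    n_fp: int
    n_fp_qual: int
    depth_exhausted: bool = False  # requested depth exceeded available reads

    @property
    def pct_tp(self) -> float:
        if self.n_reference == 0:
            return float("nan")
        return 100.0 * self.n_tp / self.n_reference


def _passes_hard_filters(v: VariantRecord, missing_passes: bool = True) -> bool:
    for key, (op, thr) in HARD_FILTERS.items():
        if key not in v.info:
            if missing_passes:
                continue
            return False
        val = v.info[key]
        if op == ">" and not val > thr:
            return False
        if op == "<" and not val < thr:
            return False
    return True


def hard_filter_exome(variants: Iterable[VariantRecord],
                      capture_intervals: Sequence[tuple[str, int, int]],
                      missing_passes: bool = True,
                      excluded_contigs: frozenset = DEFAULT_EXCLUDED_CONTIGS
                      ) -> ExomeReference:
    """Retain SNVs passing every hard filter, inside capture intervals."""
    intervals = sorted(capture_intervals)
    kept = []
    for v in variants:
        if v.chrom in excluded_contigs or not v.is_snv:
            continue
        if not _passes_hard_filters(v, missing_passes):
            continue
        if not _in_intervals(v.chrom, v.pos - 1, intervals):
            continue
        kept.append(v)
    return ExomeReference(kept, list(intervals))


def _in_intervals(chrom: str, pos0: int,
                  intervals: Sequence[tuple[str, int, int]]) -> bool:
    # intervals are few; linear scan per chrom is fine at this scale
    return any(c == chrom and s <= pos0 < e for c, s, e in intervals)


class DepthIndex:
    """Read-depth lookups over primary mapped alignments."""

    def __init__(self, alignments: Iterable[AlignmentRecord]):
        starts: dict[str, list[int]] = defaultdict(list)
        ends: dict[str, list[int]] = defaultdict(list)
        self.n = 0
        for a in alignments:
            starts[a.chrom].append(a.start)
            ends[a.chrom].append(a.end)
            self.n += 1
        self._starts = {c: sorted(v) for c, v in starts.items()}
        self._ends = {c: sorted(v) for c, v in ends.items()}

    def depth(self, chrom: str, pos0: int) -> int:
        """Number of reads whose span covers 0-based position pos0."""
        s = self._starts.get(chrom)
        if s is None:
            return 0
        return bisect_right(s, pos0) - bisect_right(self._ends[chrom], pos0)


def reference_list_for_cell(exome: ExomeReference,
                            cell_alignments: Sequence[AlignmentRecord],
                            min_reads: int = 2) -> list[VariantRecord]:
    """Exome SNPs covered by strictly more than min_reads cell reads."""
    depth = DepthIndex(cell_alignments)
    return [v for v in exome.variants
            if depth.depth(v.chrom, v.pos - 1) > min_reads]


def call_snps(cell_alignments: Sequence[AlignmentRecord],
              genome: Mapping[str, str], min_alt_reads: int = 2,
              min_alt_frac: float = 0.2, base_error: float = 0.01,
              excluded_contigs: frozenset = DEFAULT_EXCLUDED_CONTIGS
              ) -> list[VariantRecord]:
    """Minimal pileup SNV caller over alignment records carrying sequences."""
    alt_counts: dict[tuple[str, int, str], int] = defaultdict(int)
    for a in cell_alignments:
        if a.seq is None or a.chrom in excluded_contigs:
            continue
        ref = genome[a.chrom][a.start:a.end]
        if a.seq == ref:
            continue
        for i, (rb, gb) in enumerate(zip(a.seq, ref)):
            if rb != gb and rb in "ACGT":
                alt_counts[(a.chrom, a.start + i, rb)] += 1
    depth = DepthIndex(a for a in cell_alignments
                       if a.chrom not in excluded_contigs)
    calls: list[VariantRecord] = []
    for (chrom, pos0, alt), k in sorted(alt_counts.items()):
        dp = depth.depth(chrom, pos0)
        if k < min_alt_reads or dp == 0 or k / dp < min_alt_frac:
            continue
        # Phred of the chance that >= k of dp reads are pure sequencing error
        p_err = float(stats.binom.sf(k - 1, dp, base_error))
        qual = 99.0 if p_err <= 0 else min(99.0, -10.0 * np.log10(p_err))
        calls.append(VariantRecord(chrom=chrom, pos=pos0 + 1,
                                   ref=genome[chrom][pos0], alt=alt,
                                   dp=dp, qual=qual))
    return calls


def classify_cell_snps(cell_variants: Sequence[VariantRecord],
                       reference_list: Sequence[VariantRecord],
                       capture_intervals: Sequence[tuple[str, int, int]],
                       min_dp: int = 2, qual_threshold: float = 20.0,
                       match_alt: bool = True, cell_id: str = "",
                       depth_used: int = 0,
                       excluded_contigs: frozenset = DEFAULT_EXCLUDED_CONTIGS
                       ) -> SnpBenchResult:
    """TP/FP/FN classification of one cell's calls against its reference
    list. TP + FN = n_reference holds by construction."""
    known_contigs = ({c for c, _s, _e in capture_intervals}
                     | {v.chrom for v in reference_list} | set(excluded_contigs))
    bad = sorted({v.chrom for v in cell_variants
                  if v.chrom not in known_contigs})
    if bad:
        raise ValueError(f"contigs absent from the exome reference: {bad}")

    def key(v: VariantRecord) -> tuple:
        return v.key if match_alt else (v.chrom, v.pos)

    ref_keys = {key(v) for v in reference_list}
    eligible = [v for v in cell_variants
                if v.is_snv and v.chrom not in excluded_contigs
                and v.dp > min_dp
                and _in_intervals(v.chrom, v.pos - 1, capture_intervals)]
    tp_keys = {key(v) for v in eligible} & ref_keys
    tp = [v for v in eligible if key(v) in ref_keys]
    fp = [v for v in eligible if key(v) not in ref_keys]
    n_tp = len(tp_keys)
    return SnpBenchResult(
        cell_id=cell_id, depth_used=depth_used,
        n_reference=len(ref_keys),
        n_total_cell_snps=len(eligible),
        n_tp=n_tp,
        n_tp_qual=len({key(v) for v in tp if v.qual > qual_threshold}),
        n_fn=len(ref_keys) - n_tp,
        n_fp=len(fp),
        n_fp_qual=sum(1 for v in fp if v.qual > qual_threshold))


def benchmark_cell(cell_alignments: Sequence[AlignmentRecord],
                   genome: Mapping[str, str], exome: ExomeReference,
                   min_dp: int = 2, qual_threshold: float = 20.0,
                   cell_id: str = "", match_alt: bool = True
                   ) -> SnpBenchResult:
    """Reference list + internal caller + classification for one cell."""
    reference = reference_list_for_cell(exome, cell_alignments, min_reads=min_dp)
    calls = call_snps(cell_alignments, genome)
    return classify_cell_snps(calls, reference, exome.capture_intervals,
                              min_dp=min_dp, qual_threshold=qual_threshold,
                              match_alt=match_alt, cell_id=cell_id,
                              depth_used=len(cell_alignments))


def depth_curve(cell_alignments: Sequence[AlignmentRecord],
                depths: Sequence[int], seed: int,
                genome: Mapping[str, str], exome: ExomeReference,
                cell_id: str = "", **kwargs) -> list[SnpBenchResult]:
    """Benchmark one cell at several read depths (sampling without
    replacement). A depth exceeding the available reads is computed on the
    full data and flagged."""
    rng = np.random.default_rng(seed)
    results = []
    for depth in depths:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        exhausted = depth > len(cell_alignments)
        sub = downsample(cell_alignments, depth, sub_seed)
        res = benchmark_cell(sub, genome, exome, cell_id=cell_id, **kwargs)
        res.depth_used = len(sub)
        res.depth_exhausted = exhausted
        results.append(res)
    return results


def aggregate_cells(alignments_by_cell: Mapping[str, Sequence[AlignmentRecord]],
                    k: int, seed: int, genome: Mapping[str, str],
                    exome: ExomeReference, **kwargs) -> SnpBenchResult:
    """Merge the reads of k sampled cells and benchmark the pool (the
    reference list is rebuilt from pooled coverage)."""
    cells = sorted(alignments_by_cell)
    if k > len(cells):
        raise ValueError(f"k={k} exceeds the {len(cells)} available cells")
    rng = np.random.default_rng(seed)
    chosen = [cells[i] for i in sorted(rng.choice(len(cells), size=k,
                                                  replace=False))]
    pooled: list[AlignmentRecord] = []
    for c in chosen:
        pooled.extend(alignments_by_cell[c])
    return benchmark_cell(pooled, genome, exome,
                          cell_id="+".join(chosen), **kwargs)


__all__ = [
    "DEFAULT_EXCLUDED_CONTIGS", "DepthIndex", "ExomeReference",
    "HARD_FILTERS", "SnpBenchResult", "aggregate_cells", "benchmark_cell",
    "call_snps", "classify_cell_snps", "depth_curve", "hard_filter_exome",
    "reference_list_for_cell",
]
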