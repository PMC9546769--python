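"""Strand-invasion artifact detection, quantification and filtering.

A strand-invasion artifact arises when the template-switching oligo anneals
to an internal genomic/cDNA sequence rather than to the non-templated C-tail
at the cDNA 5' end. The diagnostic signature is that the read's UMI
duplicates the genomic sequence upstream of the read start. Detection
therefore compares the UMI against the 20-nt strand-aware upstream window,
forgiving 0-3 *consecutive 5'* mismatches (level m drops the UMI's first m
bases; internal mismatches are never forgiven), optionally requiring the
riboguanosine footprint (GGG) or spacer+GGG immediately 3' of the UMI match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .extract import DEFAULT_SPACER
from .io import AlignmentRecord, GeneInterval, revcomp

MOTIF_MODES = ("none", "GGG", "spacer_ggg")


@dataclass
class AlignedUmiRead:
    """One mapped 5' UMI read with its strand-aware upstream context."""

    read_id: str
    umi: str
    chrom: str
    read_start: int           # 0-based leftmost aligned base (genome orientation)
    read_end: int             # 0-based exclusive
    strand: str
    upstream20: str           # adjacent sequence read in the read's orientation
    gene: Optional[str] = None
    feature: Optional[str] = None  # exonic | intronic | intergenic

    @property
    def cell(self) -> str:
        return self.read_id.split(":", 1)[0]

    @property
    def dedup_key(self) -> tuple:
        # strand is included: opposite-strand reads at one coordinate have
        # different adjacent sequences, so the published key implies it
        return (self.umi, self.chrom, self.read_start, self.strand,
                self.upstream20)


def annotate_upstream(alignments: Iterable[AlignmentRecord],
                      genome: Mapping[str, str], window: int = 20
                      ) -> tuple[list[AlignedUmiRead], int]:
    """Attach the strand-aware upstream window to each UMI-bearing alignment.

    For a + read the window is genome[start-window .. start); for a - read it
    is the reverse complement of genome[end .. end+window). Reads whose
    window would run off the contig (or whose contig is absent from the
    genome) are dropped and counted.
    """
    out: list[AlignedUmiRead] = []
    n_dropped = 0
    for aln in alignments:
        if aln.umi is None:
            continue
        seq = genome.get(aln.chrom)
        if seq is None:
            n_dropped += 1
            continue
        if aln.strand == "+":
            if aln.start < window:
                n_dropped += 1
                continue
            upstream = seq[aln.start - window:aln.start]
        else:
            if aln.end + window > len(seq):
                n_dropped += 1
                continue
            upstream = revcomp(seq[aln.end:aln.end + window])
        out.append(AlignedUmiRead(aln.read_id, aln.umi, aln.chrom, aln.start,
                                  aln.end, aln.strand, upstream,
                                  gene=aln.gene))
    return out, n_dropped


def assign_features(reads: Sequence[AlignedUmiRead],
                    genes: Sequence[GeneInterval]) -> None:
    """Assign each read to the gene with the largest overlap (unstranded);
    reads with no overlapping gene are intergenic. Mutates in place."""
    by_chrom: dict[str, list[GeneInterval]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for r in reads:
        best, best_ov = None, 0
        for g in by_chrom.get(r.chrom, ()):
            ov = min(r.read_end, g.end) - max(r.read_start, g.start)
            if ov > best_ov:
                best, best_ov = g, ov
        if best is None:
            r.gene, r.feature = None, "intergenic"
        else:
            r.gene, r.feature = best.gene, "exonic"


def antisense_fraction(reads: Sequence[AlignedUmiRead],
                       genes: Sequence[GeneInterval]) -> float:
    """Fraction of gene-assigned reads whose strand opposes their gene's
    annotated strand (a strand-invasion-sensitive diagnostic)."""
    strand_of = {g.gene: g.strand for g in genes}
    n_assigned = n_anti = 0
    for r in reads:
        if r.gene in strand_of:
            n_assigned += 1
            if r.strand != strand_of[r.gene]:
                n_anti += 1
    return n_anti / n_assigned if n_assigned else float("nan")


def dedup_5p(reads: Iterable[AlignedUmiRead]) -> list[AlignedUmiRead]:
    """Collapse reads sharing (UMI, position, strand, adjacent sequence);
    the first-encountered record per key is the survivor."""
    seen: dict[tuple, AlignedUmiRead] = {}
    for r in reads:
        seen.setdefault(r.dedup_key, r)
    return list(seen.values())


def _motif_string(motif: str, spacer: str) -> str:
    if motif == "none":
        return ""
    if motif == "GGG":
        return "GGG"
    if motif == "spacer_ggg":
        return spacer + "GGG"
    raise ValueError(f"unknown motif mode {motif!r}; choose from {MOTIF_MODES}")


def match_umi_upstream(umi: str, upstream20: str,
                       max_consecutive_5p_mismatches: int = 3,
                       motif: str = "none", spacer: str = DEFAULT_SPACER,
                       adjacent_only: bool = False) -> Optional[int]:
    """Smallest mismatch level m at which the UMI matches the upstream
    window, or None.

    At level m the query is the 3' (len(umi)-m)-suffix of the UMI followed by
    the motif string; a match is an exact occurrence of the query anywhere
    within the window (or, with adjacent_only, ending exactly at the read
    start).
    """
    if not 0 <= max_consecutive_5p_mismatches <= 3:
        raise ValueError("max_consecutive_5p_mismatches must be in 0..3")
    tail = _motif_string(motif, spacer)
    for m in range(max_consecutive_5p_mismatches + 1):
        query = umi[m:] + tail
        if not query:
            continue
        if adjacent_only:
            if upstream20.endswith(query):
                return m
        elif query in upstream20:
            return m
    return None


def random_match_probability(m: int, motif_len: int = 0, window: int = 20,
                             umi_len: int = 8) -> float:
    """Closed-form probability that a uniform random query of length
    (umi_len - m + motif_len) occurs in a uniform random window, under an
    i.i.d. uniform-base null: 1 - (1 - 4^-L)^(window - L + 1)."""
    L = umi_len - m + motif_len
    if L <= 0 or L > window:
        return float("nan")
    return 1.0 - (1.0 - 4.0 ** -L) ** (window - L + 1)


@dataclass
class InvasionReport:
    """Match fractions at mismatch levels x motif modes over dedup reads."""

    n_dedup_reads: int
    table: pd.DataFrame            # motif, mismatch, n_match, pct, null_pct
    per_feature: pd.DataFrame      # feature, motif, mismatch, n, n_match, pct
    n_window_dropped: int = 0

    def pct(self, mismatch: int, motif: str = "none") -> float:
        row = self.table[(self.table.mismatch == mismatch)
                         & (self.table.motif == motif)]
        return float(row.pct.iloc[0])


def invasion_report(dedup_reads: Sequence[AlignedUmiRead],
                    spacer: str = DEFAULT_SPACER, max_mismatch: int = 3,
                    window: int = 20, adjacent_only: bool = False
                    ) -> InvasionReport:
    """Cumulative match counts/percentages per mismatch level and motif mode,
    with the analytic random-match expectation alongside.

    Input must already be deduplicated (dedup_5p). Percentages are NaN when
    the input is empty, never zero.
    """
    n = len(dedup_reads)
    min_levels: dict[str, list[Optional[int]]] = {mm: [] for mm in MOTIF_MODES}
    for r in dedup_reads:
        for mm in MOTIF_MODES:
            min_levels[mm].append(match_umi_upstream(
                r.umi, r.upstream20, max_mismatch, mm, spacer,
                adjacent_only=adjacent_only))
    rows = []
    for mm in MOTIF_MODES:
        motif_len = len(_motif_string(mm, spacer))
        levels = min_levels[mm]
        for m in range(max_mismatch + 1):
            n_match = sum(1 for lv in levels if lv is not None and lv <= m)
            rows.append({
                "motif": mm, "mismatch": m, "n_match": n_match,
                "pct": 100.0 * n_match / n if n else float("nan"),
                "null_pct": 100.0 * random_match_probability(
                    m, motif_len, window=window),
            })
    table = pd.DataFrame(rows)

    feat_rows = []
    features = sorted({r.feature or "unassigned" for r in dedup_reads})
    for feat in features:
        idx = [i for i, r in enumerate(dedup_reads)
               if (r.feature or "unassigned") == feat]
        for mm in MOTIF_MODES:
            for m in range(max_mismatch + 1):
                n_match = sum(1 for i in idx
                              if min_levels[mm][i] is not None
                              and min_levels[mm][i] <= m)
                feat_rows.append({
                    "feature": feat, "motif": mm, "mismatch": m,
                    "n": len(idx), "n_match": n_match,
                    "pct": 100.0 * n_match / len(idx) if idx else float("nan")})
    per_feature = pd.DataFrame(
        feat_rows, columns=["feature", "motif", "mismatch", "n", "n_match", "pct"])
    return InvasionReport(n, table, per_feature)


def filter_invasion(reads: Iterable[AlignedUmiRead], max_mismatch: int = 1,
                    motif: str = "none", spacer: str = DEFAULT_SPACER
                    ) -> tuple[list[AlignedUmiRead], int]:
    """Discard reads whose UMI invades the adjacent sequence at <= max_mismatch
    consecutive 5' mismatches (motif-free matching by default). Applied
    per read, before deduplication/counting."""
    retained: list[AlignedUmiRead] = []
    removed = 0
    for r in reads:
        if match_umi_upstream(r.umi, r.upstream20, max_mismatch, motif,
                              spacer) is not None:
            removed += 1
        else:
            retained.append(r)
    return retained, removed


def readstart_profile(dedup_reads: Sequence[AlignedUmiRead], window: int = 6,
                      n_sample: int = 500_000, seed: int = 0) -> pd.DataFrame:
    """Base composition at the `window` positions immediately 5' of the read
    start, over up to n_sample randomly selected dedup reads.

    Returns a (position x base) frequency table with rows -window..-1; each
    row sums to 1.
    """
    reads = list(dedup_reads)
    if len(reads) > n_sample:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(reads), size=n_sample, replace=False)
        reads = [reads[i] for i in idx]
    bases = "ACGTN"
    counts = np.zeros((window, len(bases)), dtype=float)
    lookup = {b: i for i, b in enumerate(bases)}
    for r in reads:
        tail = r.upstream20[-window:]
        for j, b in enumerate(tail):
            counts[j, lookup.get(b, 4)] += 1
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(totals > 0, counts / totals, np.nan)
    return pd.DataFrame(freqs, index=range(-window, 0), columns=list(bases))


__all__ = [
    "AlignedUmiRead", "InvasionReport", "MOTIF_MODES", "annotate_upstream",
    "antisense_fraction", "assign_features", "dedup_5p", "filter_invasion",
    "invasion_report", "match_umi_upstream", "random_match_probability",
    "readstart_profile",
]
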