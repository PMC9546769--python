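"""Record types and readers/writers for the formats the pipeline touches.

All coordinates are 0-based half-open internally; the 1-based convention is
restored at the VCF and SAM boundaries. Only primary, mapped alignments are
yielded by :func:`read_alignments` — secondary, supplementary and unmapped
records never enter downstream stages.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pandas as pd
import pysam

_VALID_BASES = frozenset("ACGTN")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N self-complementary)."""
    return seq.translate(COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Domain record types
# ---------------------------------------------------------------------------

@dataclass
class ReadPair:
    """One synchronized pair of FASTQ records."""

    read_id: str
    seq1: str
    seq2: str
    qual1: str
    qual2: str

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise FormatError(f"{self.read_id}: sequence/quality length mismatch")
        for s in (self.seq1, self.seq2):
            if not _VALID_BASES.issuperset(s):
                raise FormatError(f"{self.read_id}: non-ACGTN base in sequence")


@dataclass
class AlignmentRecord:
    """One primary mapped alignment (0-based half-open span)."""

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str  # '+' or '-'
    mate: int = 1
    mapq: int = 255
    umi: Optional[str] = None
    gene: Optional[str] = None
    seq: Optional[str] = None  # aligned bases in genome (forward) orientation

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(f"{self.read_id}: invalid span {self.start}..{self.end}")
        if self.strand not in "+-":
            raise FormatError(f"{self.read_id}: strand must be + or -")

    @property
    def cell(self) -> str:
        """Cell id by the read-name convention '<cell>:<rest>'."""
        return self.read_id.split(":", 1)[0]


@dataclass
class VariantRecord:
    """One biallelic variant call (pos is 1-based as printed in VCF)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    dp: int = 0
    qual: float = 0.0
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"variant position must be >= 1, got {self.pos}")
        if self.dp < 0:
            raise FormatError("DP must be nonnegative")
        if self.ref == self.alt:
            raise FormatError(f"{self.chrom}:{self.pos} ref == alt ({self.ref})")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.alt)


@dataclass
class GeneCountMatrix:
    """Genes x cells count table with its read-type provenance."""

    counts: pd.DataFrame  # index = gene ids, columns = cell ids, ints >= 0
    read_type: str = "umi"  # umi | internal | both

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise FormatError("duplicate gene or cell ids in count matrix")
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("negative counts")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def cells(self) -> list[str]:
        return list(self.counts.columns)

    def __add__(self, other: "GeneCountMatrix") -> "GeneCountMatrix":
        summed = self.counts.add(other.counts, fill_value=0).astype(int)
        return GeneCountMatrix(summed, read_type="both")


@dataclass
class GeneInterval:
    """One gene feature (single exon) from a BED6 annotation."""

    chrom: str
    start: int
    end: int
    gene: str
    strand: str


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def read_fastq_pairs(path1: str | Path, path2: str | Path) -> Iterator[ReadPair]:
    """Stream synchronized read pairs from two FASTQ files.

    Raises FormatError if the files have different record counts or a
    malformed record is encountered (the record index is reported).
    """
    with pysam.FastxFile(str(path1)) as fq1, pysam.FastxFile(str(path2)) as fq2:
        idx = 0
        it1, it2 = iter(fq1), iter(fq2)
        while True:
            r1 = next(it1, None)
            r2 = next(it2, None)
            if r1 is None and r2 is None:
                return
            if r1 is None or r2 is None:
                raise FormatError(f"mismatched record counts at record {idx}")
            if r1.quality is None or r2.quality is None:
                raise FormatError(f"record {idx}: missing quality line")
            try:
                yield ReadPair(r1.name, r1.sequence.upper(), r2.sequence.upper(),
                               r1.quality, r2.quality)
            except FormatError as exc:
                raise FormatError(f"record {idx}: {exc}") from exc
            idx += 1


def write_fastq_pairs(pairs: Iterable[ReadPair], path1: str | Path,
                      path2: str | Path) -> int:
    n = 0
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.read_id}\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.read_id}\n{p.seq2}\n+\n{p.qual2}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# SAM/BAM
# ---------------------------------------------------------------------------

_UMI_NAME_RE = re.compile(r"_([ACGTN]+)$")


def read_alignments(path: str | Path, region: Optional[str] = None
                    ) -> Iterator[AlignmentRecord]:
    """Stream primary mapped alignments from SAM/BAM.

    UMIs are taken from the RX tag or, failing that, from a trailing
    ``_<UMI>`` suffix on the read name (the umi_tools convention). Genes are
    taken from the GX tag when present.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode) as af:
        if region is not None:
            if not af.has_index():
                raise FormatError("region query requires an index")
            it = af.fetch(region=region)
        else:
            it = af
        for rec in it:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            umi = rec.get_tag("RX") if rec.has_tag("RX") else None
            if umi is None:
                m = _UMI_NAME_RE.search(rec.query_name)
                umi = m.group(1) if m else None
            gene = rec.get_tag("GX") if rec.has_tag("GX") else None
            seq = rec.query_alignment_sequence
            yield AlignmentRecord(
                read_id=rec.query_name,
                chrom=rec.reference_name,
                start=rec.reference_start,
                end=rec.reference_end,
                strand="-" if rec.is_reverse else "+",
                mate=2 if rec.is_read2 else 1,
                mapq=rec.mapping_quality,
                umi=umi,
                gene=gene,
                seq=seq.upper() if seq else None,
            )


def write_alignments(records: Iterable[AlignmentRecord], path: str | Path,
                     chrom_sizes: Mapping[str, int]) -> int:
    """Write alignments as SAM. Sequences are stored forward-stranded with a
    fully-matching CIGAR; UMI goes to RX, gene to GX."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in chrom_sizes.items()],
    }
    n = 0
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.read_id
            a.reference_name = rec.chrom
            a.reference_start = rec.start
            a.mapping_quality = rec.mapq
            length = rec.end - rec.start
            a.cigarstring = f"{length}M"
            a.flag = (16 if rec.strand == "-" else 0) | (128 if rec.mate == 2 else 0)
            seq = rec.seq if rec.seq is not None else "N" * length
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            if rec.umi is not None:
                a.set_tag("RX", rec.umi)
            if rec.gene is not None:
                a.set_tag("GX", rec.gene)
            out.write(a)
            n += 1
    return n


# ---------------------------------------------------------------------------
# FASTA / annotation
# ---------------------------------------------------------------------------

def read_genome(path: str | Path) -> dict[str, str]:
    """Load a (small) genome FASTA into a chrom -> sequence dict."""
    genome: dict[str, str] = {}
    with pysam.FastxFile(str(path)) as fa:
        for rec in fa:
            genome[rec.name] = rec.sequence.upper()
    return genome


def write_genome(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as out:
        for chrom, seq in genome.items():
            out.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i:i + width] + "\n")


def read_annotation(path: str | Path) -> list[GeneInterval]:
    """Read a BED6 gene annotation (0-based half-open, as BED is)."""
    out: list[GeneInterval] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"annotation line {i}: expected BED6")
            chrom, start, end, name, _score, strand = fields[:6]
            out.append(GeneInterval(chrom, int(start), int(end), name, strand))
    return out


def write_annotation(genes: Sequence[GeneInterval], path: str | Path) -> None:
    with open(path, "w") as out:
        for g in genes:
            out.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene}\t0\t{g.strand}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_INFO_FLOAT_KEYS = ("QD", "FS", "SOR", "MQ", "MQRankSum", "ReadPosRankSum")


def _vcf_header(contigs: Mapping[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for c, l in contigs.items():
        header.contigs.add(c, length=int(l))
    header.info.add("DP", 1, "Integer", "Read depth")
    for key in _INFO_FLOAT_KEYS:
        header.info.add(key, 1, "Float", f"{key} annotation")
    return header


def write_vcf(variants: Iterable[VariantRecord], path: str | Path,
              contigs: Mapping[str, int]) -> int:
    header = _vcf_header(contigs)
    n = 0
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in variants:
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt), qual=v.qual)
            rec.info["DP"] = v.dp
            for key, val in v.info.items():
                rec.info[key] = float(val)
            out.write(rec)
            n += 1
    return n


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read a VCF into VariantRecords, decomposing multi-allelic sites."""
    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            dp = int(rec.info.get("DP", 0)) if "DP" in rec.info else 0
            info = {}
            for key in _INFO_FLOAT_KEYS:
                if key in rec.info:
                    val = rec.info[key]
                    info[key] = float(val[0] if isinstance(val, tuple) else val)
            for alt in rec.alts or ():
                out.append(VariantRecord(
                    chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                    dp=dp, qual=float(rec.qual or 0.0), info=info))
    return out


# ---------------------------------------------------------------------------
# Count matrices and generic TSV
# ---------------------------------------------------------------------------

def write_count_matrix(matrix: GeneCountMatrix, path: str | Path) -> None:
    matrix.counts.rename_axis("gene").to_csv(path, sep="\t")


def read_count_matrix(path: str | Path, read_type: str = "umi") -> GeneCountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GeneCountMatrix(df.astype(int), read_type=read_type)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


__all__ = [
    "AlignmentRecord", "FormatError", "GeneCountMatrix", "GeneInterval",
    "ReadPair", "VariantRecord", "read_alignments", "read_annotation",
    "read_count_matrix", "read_fastq_pairs", "read_genome", "read_table",
    "read_vcf", "revcomp", "write_alignments", "write_annotation",
    "write_count_matrix", "write_fastq_pairs", "write_genome", "write_table",
    "write_vcf", "replace",
]
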