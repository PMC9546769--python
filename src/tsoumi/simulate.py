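"""Synthetic 5' UMI scRNA-seq dataset generator with full ground truth.

The generator emulates the read structure of spacer-bearing template-switching
oligo (TSO) libraries: 5' UMI reads carrying adapter+UMI+spacer+GGG at the
read-1 start, intra-TSO tagmentation events that flip the motif onto read 2
behind a 2-4 nt adapter remnant, internal (non-UMI) cDNA reads, genomic
background reads, strand-invasion artifacts whose UMI duplicates the genomic
sequence upstream of the read start, and planted heterozygous SNPs with
deterministic ~50% allele support in carrier cells.

The simulator is its own aligner: it emits the true mapping position of the
trimmed UMI-bearing mate (or mate 1 for non-UMI pairs), so every downstream
stage can be validated against the truth tables without running an external
aligner.

Strand-invasion geometry
------------------------
A plain invasion read copies its UMI from the 8 genomic nt immediately
upstream of the read start (strand-aware). With probability ``p_invasion_ggg``
the invasion site additionally carries the riboguanosine footprint: GGG is
planted in the genome at the 3 nt adjacent to the read start and the UMI is
copied from the 8 nt immediately 5' of that GGG, mirroring the annealing
layout UMI-spacer-rGrGrG of the oligo. Both layouts place the UMI inside the
20-nt upstream window that the invasion detector scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .extract import OligoConfig
from .io import (AlignmentRecord, GeneInterval, ReadPair, VariantRecord,
                 revcomp, write_alignments, write_annotation,
                 write_fastq_pairs, write_genome, write_table, write_vcf)

_BASES = np.array(list("ACGT"))

# INFO annotations given to planted (filter-passing) exome variants
_PASS_INFO = {"QD": 25.0, "FS": 0.5, "SOR": 1.0, "MQ": 60.0,
              "MQRankSum": 0.0, "ReadPosRankSum": 0.0}
# one failing annotation per decoy variant, cycled
_FAIL_INFO = [("QD", 1.0), ("FS", 80.0), ("SOR", 4.5), ("MQ", 20.0),
              ("MQRankSum", -20.0), ("ReadPosRankSum", -10.0)]


class SimConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Generative knobs for one synthetic dataset."""

    seed: int = 0
    n_chroms: int = 2
    chrom_len: int = 100_000
    n_genes: int = 40
    n_cells: int = 8
    reads_per_cell: int = 2000          # molecules per cell (pre-duplication)
    frac_umi_reads: float = 0.5
    p_invasion: float = 0.02
    p_tso_tagmentation: float = 0.05
    p_invasion_ggg: float = 0.5
    adapter_truncation_weights: dict[int, float] = field(
        default_factory=lambda: {2: 1.0, 3: 1.0, 4: 1.0})
    p_background: float = 0.05
    n_het_snps: int = 50
    n_filterfail_snps: int = 5
    carrier_frac: float = 1.0
    error_rate: float = 0.0
    read_len: int = 75
    fragment_len: int = 150
    gene_len: int = 1500
    duplicate_factor: int = 1
    dialect: str = "spacer"
    # Dirichlet concentration for per-gene expression weights; None keeps
    # gene choice uniform. Small values concentrate expression in few genes.
    gene_weight_alpha: Optional[float] = None
    oligo: OligoConfig = field(default_factory=OligoConfig)

    def __post_init__(self) -> None:
        for name in ("frac_umi_reads", "p_invasion", "p_tso_tagmentation",
                     "p_invasion_ggg", "p_background", "carrier_frac",
                     "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must be in [0,1], got {v}")
        if self.frac_umi_reads + self.p_background > 1.0 + 1e-12:
            raise SimConfigError("frac_umi_reads + p_background must be <= 1")
        if self.read_len < 25:
            raise SimConfigError("read_len must be >= 25")
        if self.duplicate_factor < 1:
            raise SimConfigError("duplicate_factor must be >= 1")
        margin = self._margin
        if self.chrom_len < 2 * margin + 400:
            raise SimConfigError(
                f"chrom_len {self.chrom_len} too small for read_len, fragment "
                f"and the 20-bp upstream context (need > {2 * margin + 400})")
        if not self.adapter_truncation_weights:
            raise SimConfigError("adapter_truncation_weights must be non-empty")

    @property
    def _margin(self) -> int:
        # clearance from contig edges: fragment + upstream window + slack
        return max(self.fragment_len, self.read_len) + 20 + 30


@dataclass
class SimTruth:
    """Per-read and per-variant ground truth."""

    reads: pd.DataFrame      # one row per emitted read (incl. duplicates)
    variants: pd.DataFrame   # one row per exome variant (planted + decoys)
    support: pd.DataFrame    # per (variant, cell) alt-read support counts


@dataclass
class SimDataset:
    """In-memory simulated dataset plus its truth tables."""

    config: SimConfig
    genome: dict[str, str]
    genes: list[GeneInterval]
    pairs: list[ReadPair]
    alignments: list[AlignmentRecord]
    exome_variants: list[VariantRecord]
    capture_intervals: list[tuple[str, int, int]]
    truth: SimTruth

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the dataset to standard formats under out_dir."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": out / "genome.fa",
            "annotation": out / "genes.bed",
            "fastq1": out / "reads_R1.fastq",
            "fastq2": out / "reads_R2.fastq",
            "alignments": out / "alignments.sam",
            "exome_vcf": out / "exome.vcf",
            "capture": out / "capture.bed",
            "truth_reads": out / "truth_reads.tsv",
            "truth_variants": out / "truth_variants.tsv",
            "truth_support": out / "truth_support.tsv",
        }
        write_genome(self.genome, paths["genome"])
        write_annotation(self.genes, paths["annotation"])
        write_fastq_pairs(self.pairs, paths["fastq1"], paths["fastq2"])
        write_alignments(self.alignments, paths["alignments"], self.chrom_sizes)
        write_vcf(self.exome_variants, paths["exome_vcf"], self.chrom_sizes)
        with open(paths["capture"], "w") as fh:
            for chrom, start, end in self.capture_intervals:
                fh.write(f"{chrom}\t{start}\t{end}\tcapture\t0\t+\n")
        write_table(self.truth.reads, paths["truth_reads"])
        write_table(self.truth.variants, paths["truth_variants"])
        write_table(self.truth.support, paths["truth_support"])
        return paths


def _place_genes(cfg: SimConfig, rng: np.random.Generator
                 ) -> list[GeneInterval]:
    """Non-overlapping single-exon genes, well separated so no read can
    reach two genes at the assignment overlap threshold."""
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    per_chrom = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_genes % cfg.n_chroms):
        per_chrom[i] += 1
    margin = cfg._margin
    genes: list[GeneInterval] = []
    gidx = 0
    for chrom, k in zip(chroms, per_chrom):
        if k == 0:
            continue
        usable = cfg.chrom_len - 2 * margin
        slot = usable // k
        gene_len = min(cfg.gene_len, slot - 2 * cfg.fragment_len - 50)
        if gene_len < 100:
            raise SimConfigError(
                f"cannot fit {k} genes of useful length on a chromosome of "
                f"{cfg.chrom_len} bp; increase chrom_len or reduce n_genes")
        for j in range(k):
            start = margin + j * slot + int(rng.integers(0, 30))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneInterval(chrom, start, start + gene_len,
                                      f"gene{gidx:04d}", strand))
            gidx += 1
    return genes


def _random_base_except(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(0, 3))]


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0.0 or not seq:
        return seq
    mask = rng.random(len(seq)) < rate
    if not mask.any():
        return seq
    out = list(seq)
    for i in np.flatnonzero(mask):
        out[i] = _random_base_except(rng, out[i])
    return "".join(out)


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Generate one dataset: genome, annotation, reads, alignments, exome
    truth VCF and truth tables. Deterministic given config.seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    oligo = cfg.oligo
    spacer = oligo.spacer if cfg.dialect == "spacer" else ""
    adapter = oligo.adapter

    # --- genome as mutable per-chrom base lists -------------------------
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    genome_mut: dict[str, list[str]] = {
        c: list(_BASES[rng.integers(0, 4, cfg.chrom_len)]) for c in chroms}
    genes = _place_genes(cfg, rng)
    genes_by_chrom: dict[str, list[GeneInterval]] = {c: [] for c in chroms}
    for g in genes:
        genes_by_chrom[g.chrom].append(g)

    margin = cfg._margin
    cells = [f"cell{i:03d}" for i in range(cfg.n_cells)]

    trunc_lens = np.array(sorted(cfg.adapter_truncation_weights), dtype=int)
    trunc_w = np.array([cfg.adapter_truncation_weights[int(l)] for l in trunc_lens],
                       dtype=float)
    trunc_w /= trunc_w.sum()

    min_span = 30  # minimum in-gene aligned bases for a UMI/internal read

    if cfg.gene_weight_alpha is not None:
        gene_weights = rng.dirichlet(
            np.full(len(genes), cfg.gene_weight_alpha))
    else:
        gene_weights = None

    def _sample_intergenic(chrom: str) -> int:
        gs = genes_by_chrom[chrom]
        while True:
            pos = int(rng.integers(margin, cfg.chrom_len - margin))
            if all(not (g.start - cfg.read_len < pos < g.end + cfg.read_len)
                   for g in gs):
                return pos

    # --- phase A: plan molecules ---------------------------------------
    plans: list[dict] = []
    for cell in cells:
        for m in range(cfg.reads_per_cell):
            u = rng.random()
            if u < cfg.frac_umi_reads:
                cls = "umi"
            elif u < cfg.frac_umi_reads + cfg.p_background:
                cls = "background"
            else:
                cls = "internal"
            if cls == "background":
                chrom = chroms[int(rng.integers(0, cfg.n_chroms))]
                strand = "+" if rng.random() < 0.5 else "-"
                anchor5 = _sample_intergenic(chrom)
                gene_name = "background"
            else:
                if gene_weights is not None:
                    g = genes[int(rng.choice(len(genes), p=gene_weights))]
                else:
                    g = genes[int(rng.integers(0, len(genes)))]
                chrom, gene_name = g.chrom, g.gene
                strand = g.strand if cls == "umi" else (
                    "+" if rng.random() < 0.5 else "-")
                if strand == "+":
                    anchor5 = int(rng.integers(g.start, g.end - min_span))
                else:
                    anchor5 = int(rng.integers(g.start + min_span, g.end))
            plan = {"cell": cell, "mol": m, "cls": cls, "chrom": chrom,
                    "gene": gene_name, "strand": strand, "anchor5": anchor5,
                    "invasion": False, "motif": False, "r2": False,
                    "suffix_len": 0, "umi": ""}
            if cls == "umi":
                plan["invasion"] = rng.random() < cfg.p_invasion
                if plan["invasion"]:
                    plan["motif"] = rng.random() < cfg.p_invasion_ggg
                plan["r2"] = rng.random() < cfg.p_tso_tagmentation
                if plan["r2"]:
                    plan["suffix_len"] = int(
                        rng.choice(trunc_lens, p=trunc_w))
                else:
                    plan["suffix_len"] = int(
                        rng.integers(oligo.min_suffix_for(cfg.dialect),
                                     len(adapter) + 1))
                if not plan["invasion"]:
                    plan["umi"] = "".join(_BASES[rng.integers(0, 4, 8)])
            plans.append(plan)

    # --- phase B: plant GGG at motif-bearing invasion sites -------------
    for p in plans:
        if not p["motif"]:
            continue
        seq = genome_mut[p["chrom"]]
        a = p["anchor5"]
        if p["strand"] == "+":
            seq[a - 3:a] = list("GGG")
        else:
            seq[a:a + 3] = list("CCC")  # reads GGG in read orientation

    # --- SNPs (planted + filter-fail decoys), positions inside genes ----
    used_pos: set[tuple[str, int]] = set()
    variant_rows: list[dict] = []
    n_total_vars = cfg.n_het_snps + cfg.n_filterfail_snps
    for v in range(n_total_vars):
        while True:
            g = genes[int(rng.integers(0, len(genes)))]
            pos0 = int(rng.integers(g.start + 5, g.end - 5))
            if (g.chrom, pos0) not in used_pos:
                used_pos.add((g.chrom, pos0))
                break
        ref = genome_mut[g.chrom][pos0]
        alt = _random_base_except(rng, ref)
        planted = v < cfg.n_het_snps
        if planted:
            carriers = [c for c in cells if rng.random() < cfg.carrier_frac]
            if not carriers:
                carriers = [cells[int(rng.integers(0, cfg.n_cells))]]
        else:
            carriers = []
        variant_rows.append({
            "chrom": g.chrom, "pos": pos0 + 1, "ref": ref, "alt": alt,
            "planted": planted, "passes_filters": planted,
            "carriers": ",".join(carriers)})
    # per-chrom sorted positions of planted variants for fast lookup
    planted_rows = [r for r in variant_rows if r["planted"]]
    var_pos_by_chrom: dict[str, np.ndarray] = {}
    var_idx_by_chrom: dict[str, list[int]] = {}
    for c in chroms:
        entries = [(r["pos"] - 1, i) for i, r in enumerate(planted_rows)
                   if r["chrom"] == c]
        entries.sort()
        var_pos_by_chrom[c] = np.array([e[0] for e in entries], dtype=int)
        var_idx_by_chrom[c] = [e[1] for e in entries]
    carrier_sets = [set(r["carriers"].split(",")) if r["carriers"] else set()
                    for r in planted_rows]

    genome = {c: "".join(genome_mut[c]) for c in chroms}

    # --- phase C: emit reads -------------------------------------------
    pairs: list[ReadPair] = []
    alignments: list[AlignmentRecord] = []
    read_rows: list[dict] = []
    alt_counter: dict[tuple[int, str], int] = {}
    support: dict[tuple[int, str], int] = {}

    def _aligned_with_snps(chrom: str, start: int, end: int, cell: str) -> str:
        """Genome slice with the deterministic het-SNP alternation applied
        (forward genome orientation)."""
        seq = genome[chrom][start:end]
        positions = var_pos_by_chrom[chrom]
        if positions.size:
            lo = int(np.searchsorted(positions, start, side="left"))
            hi = int(np.searchsorted(positions, end, side="left"))
            if hi > lo:
                seq_l = list(seq)
                for k in range(lo, hi):
                    vi = var_idx_by_chrom[chrom][k]
                    if cell not in carrier_sets[vi]:
                        continue
                    key = (vi, cell)
                    n = alt_counter.get(key, 0) + 1
                    alt_counter[key] = n
                    if n % 2 == 1:  # 1st, 3rd, ... covering read carries alt
                        seq_l[positions[k] - start] = planted_rows[vi]["alt"]
                        support[key] = support.get(key, 0) + 1
                seq = "".join(seq_l)
        return seq

    spacer_anchor = spacer + "GG" + "G"  # spacer + anchor + templated third G
    tech_fixed = 8 + len(spacer_anchor)

    for p in plans:
        cell, cls, chrom, strand, a = (p["cell"], p["cls"], p["chrom"],
                                       p["strand"], p["anchor5"])
        if cls == "umi":
            if p["invasion"]:
                # UMI copied from the genomic sequence upstream of the
                # read start, strand-aware; motif layout shifts it 3 nt.
                if strand == "+":
                    window = genome[chrom][a - 20:a]
                else:
                    window = revcomp(genome[chrom][a:a + 20])
                p["umi"] = window[-11:-3] if p["motif"] else window[-8:]
            umi = p["umi"]
            suffix_len = p["suffix_len"]
            tech = adapter[len(adapter) - suffix_len:] + umi + spacer_anchor
            cdna_len = cfg.read_len - len(tech)
            if strand == "+":
                aln_start, aln_end = a, a + cdna_len
                frag_end = a + cfg.fragment_len
                mate_span = (frag_end - cfg.read_len, frag_end)
                mate_strand = "-"
            else:
                aln_start, aln_end = a - cdna_len, a
                frag_start = a - cfg.fragment_len
                mate_span = (frag_start, frag_start + cfg.read_len)
                mate_strand = "+"
        else:
            umi, tech, suffix_len = "", "", 0
            if strand == "+":
                aln_start, aln_end = a, a + cfg.read_len
                frag_end = a + cfg.fragment_len
                mate_span = (frag_end - cfg.read_len, frag_end)
                mate_strand = "-"
            else:
                aln_start, aln_end = a - cfg.read_len, a
                frag_start = a - cfg.fragment_len
                mate_span = (frag_start, frag_start + cfg.read_len)
                mate_strand = "+"

        for dup in range(cfg.duplicate_factor):
            read_id = f"{cell}:m{p['mol']:06d}" + (f":d{dup}" if dup else "")
            fwd = _aligned_with_snps(chrom, aln_start, aln_end, cell)
            read_seq = fwd if strand == "+" else revcomp(fwd)
            umi_read = tech + read_seq  # mate carrying the motif (or mate 1)
            mate_fwd = genome[chrom][mate_span[0]:mate_span[1]]
            mate_seq = mate_fwd if mate_strand == "+" else revcomp(mate_fwd)
            umi_read = _apply_errors(umi_read, rng, cfg.error_rate)
            mate_seq = _apply_errors(mate_seq, rng, cfg.error_rate)
            umi_obs = umi_read[suffix_len:suffix_len + 8] if cls == "umi" else None
            aligned_obs = umi_read[len(tech):]
            aligned_fwd = aligned_obs if strand == "+" else revcomp(aligned_obs)
            if p["r2"]:
                seq1, seq2 = mate_seq, umi_read
            else:
                seq1, seq2 = umi_read, mate_seq
            pairs.append(ReadPair(read_id, seq1, seq2,
                                  "I" * len(seq1), "I" * len(seq2)))
            alignments.append(AlignmentRecord(
                read_id=read_id, chrom=chrom, start=aln_start, end=aln_end,
                strand=strand, mate=1, mapq=255,
                umi=umi_obs, gene=None, seq=aligned_fwd))
            read_rows.append({
                "read_id": read_id, "cell_id": cell, "gene": p["gene"],
                "chrom": chrom, "start": aln_start, "end": aln_end,
                "strand": strand,
                "read_class": ("umi_r2" if p["r2"] else "umi_r1")
                              if cls == "umi" else cls,
                "true_umi": umi, "is_invasion": p["invasion"],
                "invasion_motif": p["motif"],
                "adapter_suffix_len": suffix_len,
                "molecule_id": f"{cell}:m{p['mol']:06d}"})

    # --- truth tables and exome VCF ------------------------------------
    truth_reads = pd.DataFrame(read_rows)
    truth_variants = pd.DataFrame(variant_rows)
    support_rows = [{"chrom": planted_rows[vi]["chrom"],
                     "pos": planted_rows[vi]["pos"],
                     "alt": planted_rows[vi]["alt"], "cell_id": cell,
                     "n_support": n}
                    for (vi, cell), n in sorted(support.items())]
    truth_support = pd.DataFrame(
        support_rows, columns=["chrom", "pos", "alt", "cell_id", "n_support"])

    exome_variants: list[VariantRecord] = []
    fail_cycle = 0
    for r in variant_rows:
        info = dict(_PASS_INFO)
        if not r["planted"]:
            key, val = _FAIL_INFO[fail_cycle % len(_FAIL_INFO)]
            info[key] = val
            fail_cycle += 1
        exome_variants.append(VariantRecord(
            chrom=r["chrom"], pos=r["pos"], ref=r["ref"], alt=r["alt"],
            dp=100, qual=1000.0, info=info))
    exome_variants.sort(key=lambda v: (v.chrom, v.pos))
    capture = [(g.chrom, g.start, g.end) for g in genes]

    return SimDataset(cfg, genome, genes, pairs, alignments, exome_variants,
                      capture, SimTruth(truth_reads, truth_variants,
                                        truth_support))


def downsample(records: Sequence, n: int, seed: int) -> list:
    """Sample n records without replacement, preserving input order.

    Mirrors seeded FASTQ downsampling: deterministic given seed, identity
    when n >= len(records), empty when n <= 0.
    """
    records = list(records)
    if n >= len(records):
        return records
    if n <= 0:
        return []
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(records), size=n, replace=False))
    return [records[i] for i in idx]


def downsample_fastq(pairs: Iterable[ReadPair], n_reads: int,
                     seed: int) -> list[ReadPair]:
    """Downsample a pair stream to n_reads pairs without replacement."""
    return downsample(list(pairs), n_reads, seed)


PRESETS: dict[str, dict] = {
    "invasion-bench": dict(frac_umi_reads=1.0, p_background=0.0,
                           p_tso_tagmentation=0.0, n_het_snps=0,
                           n_filterfail_snps=0, p_invasion=0.05,
                           n_cells=5, reads_per_cell=10_000),
    "snp-bench": dict(p_invasion=0.0, p_tso_tagmentation=0.0,
                      frac_umi_reads=0.5, p_background=0.02,
                      n_het_snps=50, n_cells=6, reads_per_cell=6000),
    "saturation": dict(p_invasion=0.01, n_genes=60, n_cells=12,
                       reads_per_cell=3000),
}


def preset_config(name: str, seed: int = 0, **overrides) -> SimConfig:
    if name not in PRESETS:
        raise SimConfigError(f"unknown preset {name!r}; "
                             f"choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return SimConfig(seed=seed, **kwargs)


__all__ = ["PRESETS", "SimConfig", "SimConfigError", "SimDataset", "SimTruth",
           "downsample", "downsample_fastq", "preset_config",
           "simulate_dataset"]
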