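"""Per-gene molecule counting and the UMI edit-distance diagnostic.

UMI reads are assigned to genes strand-aware and deduplicated into molecule
counts either by distinct UMI sequence (``unique``) or by the directional
network collapse used by UMI-aware counters: two UMIs at Hamming distance 1
are linked when the more abundant one has count >= 2x the other's count - 1,
and linked components count as one molecule. Internal (non-UMI) reads are
counted per read, unstranded, at a fractional-overlap threshold.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import edlib
import numpy as np
import pandas as pd
from scipy import stats

from .io import AlignmentRecord, GeneCountMatrix, GeneInterval
from .invasion import AlignedUmiRead


class GeneIndex:
    """Overlap queries against single-exon gene intervals."""

    def __init__(self, genes: Sequence[GeneInterval]):
        self.by_chrom: dict[str, list[GeneInterval]] = {}
        for g in genes:
            self.by_chrom.setdefault(g.chrom, []).append(g)
        for lst in self.by_chrom.values():
            lst.sort(key=lambda g: g.start)

    def overlapping(self, chrom: str, start: int, end: int
                    ) -> list[tuple[GeneInterval, int]]:
        """Genes overlapping [start, end) with their overlap lengths."""
        out = []
        for g in self.by_chrom.get(chrom, ()):
            if g.start >= end:
                break
            ov = min(end, g.end) - max(start, g.start)
            if ov > 0:
                out.append((g, ov))
        return out

    def assign(self, chrom: str, start: int, end: int,
               strand: Optional[str] = None, min_overlap_frac: float = 0.25
               ) -> Optional[str]:
        """Gene id when exactly one gene meets the overlap threshold
        (ambiguous multi-gene hits return None). Strand-aware when a strand
        is given."""
        length = end - start
        hits = [g for g, ov in self.overlapping(chrom, start, end)
                if ov >= min_overlap_frac * length
                and (strand is None or g.strand == strand)]
        if len(hits) == 1:
            return hits[0].gene
        return None


def _cell_of(read) -> str:
    return read.read_id.split(":", 1)[0]


def _span_of(read) -> tuple[str, int, int, str]:
    if isinstance(read, AlignedUmiRead):
        return read.chrom, read.read_start, read.read_end, read.strand
    return read.chrom, read.start, read.end, read.strand


def assign_genes(reads: Iterable, index: GeneIndex,
                 min_overlap_frac: float = 0.25, stranded: bool = True
                 ) -> list:
    """Label reads with their gene (mutating), dropping unassignable ones."""
    out = []
    for r in reads:
        chrom, start, end, strand = _span_of(r)
        gene = index.assign(chrom, start, end, strand if stranded else None,
                            min_overlap_frac)
        if gene is not None:
            r.gene = gene
            out.append(r)
    return out


def hamming1_neighbors(umi: str) -> Iterable[str]:
    for i, b in enumerate(umi):
        for alt in "ACGT":
            if alt != b:
                yield umi[:i] + alt + umi[i + 1:]


def count_directional(umi_counts: Mapping[str, int]) -> int:
    """Molecules after directional collapse of a per-(gene, cell) UMI
    multiset.

    Nodes are processed in descending count then lexicographic order; an
    edge a-b (Hamming distance 1) is accepted when count(a) >= 2*count(b)-1
    for the more abundant side, and components of accepted edges count once.
    """
    umis = sorted(umi_counts, key=lambda u: (-umi_counts[u], u))
    if len(umis) <= 1:
        return len(umis)
    parent = {u: u for u in umis}

    def find(u: str) -> str:
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    members = set(umis)
    for a in umis:  # descending count: a is never the smaller side
        ca = umi_counts[a]
        for b in hamming1_neighbors(a):
            if b in members and ca >= 2 * umi_counts[b] - 1:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
    return len({find(u) for u in umis})


def count_molecules(reads: Iterable, method: str = "unique",
                    cells: Optional[Sequence[str]] = None,
                    genes: Optional[Sequence[str]] = None
                    ) -> GeneCountMatrix:
    """Per-(gene, cell) molecule counts from gene-labelled UMI reads.

    ``unique`` counts distinct UMI sequences; ``directional`` counts
    components of the directional collapse.
    """
    if method not in ("unique", "directional"):
        raise ValueError(f"unknown method {method!r}")
    sets: dict[tuple[str, str], Counter] = defaultdict(Counter)
    seen_cells, seen_genes = set(), set()
    for r in reads:
        if r.gene is None or r.umi is None:
            continue
        cell = _cell_of(r)
        sets[(r.gene, cell)][r.umi] += 1
        seen_cells.add(cell)
        seen_genes.add(r.gene)
    all_cells = list(cells) if cells is not None else sorted(seen_cells)
    all_genes = list(genes) if genes is not None else sorted(seen_genes)
    mat = pd.DataFrame(0, index=all_genes, columns=all_cells, dtype=int)
    for (gene, cell), counter in sets.items():
        if gene not in mat.index or cell not in mat.columns:
            continue
        if method == "unique":
            mat.loc[gene, cell] = len(counter)
        else:
            mat.loc[gene, cell] = count_directional(counter)
    return GeneCountMatrix(mat, read_type="umi")


def count_internal(alignments: Iterable[AlignmentRecord],
                   annotation: Sequence[GeneInterval],
                   min_overlap_frac: float = 0.25,
                   cells: Optional[Sequence[str]] = None,
                   genes: Optional[Sequence[str]] = None
                   ) -> GeneCountMatrix:
    """Per-(gene, cell) read counts for internal (non-UMI) reads.

    A read contributes when >= min_overlap_frac of its aligned length
    overlaps a gene's exonic span; reads reaching the threshold in multiple
    genes are discarded as ambiguous. Counting is unstranded.
    """
    index = annotation if isinstance(annotation, GeneIndex) else GeneIndex(annotation)
    counts: dict[tuple[str, str], int] = defaultdict(int)
    seen_cells, seen_genes = set(), set()
    for a in alignments:
        gene = index.assign(a.chrom, a.start, a.end, None, min_overlap_frac)
        if gene is None:
            continue
        cell = _cell_of(a)
        counts[(gene, cell)] += 1
        seen_cells.add(cell)
        seen_genes.add(gene)
    all_cells = list(cells) if cells is not None else sorted(seen_cells)
    all_genes = list(genes) if genes is not None else sorted(seen_genes)
    mat = pd.DataFrame(0, index=all_genes, columns=all_cells, dtype=int)
    for (gene, cell), n in counts.items():
        if gene in mat.index and cell in mat.columns:
            mat.loc[gene, cell] = n
    return GeneCountMatrix(mat, read_type="internal")


# ---------------------------------------------------------------------------
# Edit-distance diagnostic
# ---------------------------------------------------------------------------

def umi_distance(a: str, b: str, metric: str = "levenshtein") -> int:
    if metric == "levenshtein":
        return edlib.align(a, b)["editDistance"]
    if metric == "hamming":
        if len(a) != len(b):
            raise ValueError("hamming distance requires equal lengths")
        return sum(x != y for x, y in zip(a, b))
    raise ValueError(f"unknown metric {metric!r}")


@dataclass
class EditDistanceDiagnostic:
    """Within-gene UMI pairwise distances vs a pooled-resampling null."""

    observed: np.ndarray        # raw pairwise distances, within genes
    null: np.ndarray            # matched-size draws from the pooled UMI set
    observed_hist: np.ndarray   # normalized over distances 0..8
    null_hist: np.ndarray
    statistic: float
    pvalue: float
    n_pairs_observed: int
    n_pairs_null: int
    computable: bool = True


def _pairwise(umis: Sequence[str], metric: str) -> list[int]:
    out = []
    for i in range(len(umis)):
        for j in range(i + 1, len(umis)):
            out.append(umi_distance(umis[i], umis[j], metric))
    return out


def edit_distance_diagnostic(umi_sets: Mapping, n_null_draws: int = 1,
                             seed: int = 0, metric: str = "levenshtein",
                             umi_len: int = 8) -> EditDistanceDiagnostic:
    """Compare within-gene UMI pairwise edit distances against random
    resampling from the pooled UMI set.

    umi_sets maps a group key (gene, or (gene, cell)) to its observed UMIs —
    normally the UMIs of position-deduplicated reads, so identical UMI
    sequences captured at different positions are kept. The null draws
    matching set sizes from the pooled UMIs and is compared to the observed
    distances by a two-sided rank-sum test.
    """
    dedup_sets = [list(v) for v in umi_sets.values()]
    pool = [u for s in dedup_sets for u in s]
    sizes = [len(s) for s in dedup_sets if len(s) >= 2]
    observed: list[int] = []
    for s in dedup_sets:
        if len(s) >= 2:
            observed.extend(_pairwise(s, metric))
    if not observed or len(pool) < 2:
        empty = np.zeros(umi_len + 1)
        return EditDistanceDiagnostic(np.array([]), np.array([]), empty,
                                      empty, float("nan"), float("nan"),
                                      0, 0, computable=False)
    rng = np.random.default_rng(seed)
    null: list[int] = []
    for _ in range(max(1, n_null_draws)):
        for k in sizes:
            k_eff = min(k, len(pool))
            idx = rng.choice(len(pool), size=k_eff, replace=False)
            null.extend(_pairwise([pool[i] for i in idx], metric))
    stat, pval = stats.mannwhitneyu(observed, null, alternative="two-sided")
    bins = np.arange(umi_len + 2)
    obs_hist = np.histogram(observed, bins=bins)[0].astype(float)
    null_hist = np.histogram(null, bins=bins)[0].astype(float)
    obs_hist /= obs_hist.sum()
    null_hist /= null_hist.sum()
    return EditDistanceDiagnostic(
        np.asarray(observed), np.asarray(null), obs_hist, null_hist,
        float(stat), float(pval), len(observed), len(null))


__all__ = [
    "EditDistanceDiagnostic", "GeneIndex", "assign_genes",
    "count_directional", "count_internal", "count_molecules",
    "edit_distance_diagnostic", "hamming1_neighbors", "umi_distance",
]
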