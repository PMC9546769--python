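"""Gene-detection sensitivity and diversity statistics.

Detection is counted at strict read thresholds (>0 and >5 reads by default);
saturation curves recompute detection on reads downsampled without
replacement; gene diversity resamples a fixed number of cells per cell type
and counts genes seen in strictly more than ``min_cells`` of them; cell-cell
similarity uses Kendall's tau-b (rank correlation with tie handling) on the
genes expressed in all compared cells.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import AlignmentRecord, GeneCountMatrix
from .counts import GeneIndex, assign_genes, count_internal, count_molecules
from .simulate import downsample


def genes_detected(matrix: GeneCountMatrix,
                   thresholds: Sequence[int] = (0, 5)) -> pd.DataFrame:
    """Per-cell number of genes with count strictly above each threshold."""
    rows = []
    for cell in matrix.cells:
        col = matrix.counts[cell]
        row = {"cell": cell, "read_type": matrix.read_type}
        for t in thresholds:
            row[f"n_genes_gt{t}"] = int((col > t).sum())
        rows.append(row)
    cols = ["cell", "read_type"] + [f"n_genes_gt{t}" for t in thresholds]
    return pd.DataFrame(rows, columns=cols)


def saturation_curve(alignments: Sequence[AlignmentRecord],
                     annotation, depths: Sequence[int], seed: int,
                     read_type: str = "umi",
                     thresholds: Sequence[int] = (0, 5),
                     min_overlap_frac: float = 0.25) -> pd.DataFrame:
    """Per-cell detection at each downsampled per-cell read depth.

    UMI reads are gene-assigned strand-aware and counted as unique
    molecules; internal reads are counted per read, unstranded. Depths must
    be sorted ascending.
    """
    if list(depths) != sorted(depths):
        raise ValueError("depths must be sorted ascending")
    index = annotation if isinstance(annotation, GeneIndex) else GeneIndex(annotation)
    by_cell: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for a in alignments:
        by_cell[a.cell].append(a)
    rng = np.random.default_rng(seed)
    rows = []
    for cell in sorted(by_cell):
        reads = by_cell[cell]
        for depth in depths:
            sub_seed = int(rng.integers(0, 2**31 - 1))
            sub = downsample(reads, depth, sub_seed)
            if read_type == "umi":
                labelled = assign_genes([r for r in sub if r.umi is not None],
                                        index, min_overlap_frac, stranded=True)
                mat = count_molecules(labelled, method="unique", cells=[cell])
            else:
                mat = count_internal(sub, index, min_overlap_frac, cells=[cell])
            row = {"cell": cell, "depth": depth, "n_reads": len(sub)}
            if cell in mat.cells:
                col = mat.counts[cell]
                for t in thresholds:
                    row[f"n_genes_gt{t}"] = int((col > t).sum())
            else:
                for t in thresholds:
                    row[f"n_genes_gt{t}"] = 0
            rows.append(row)
    cols = (["cell", "depth", "n_reads"]
            + [f"n_genes_gt{t}" for t in thresholds])
    return pd.DataFrame(rows, columns=cols)


@dataclass
class DiversityResult:
    """Resampled gene-diversity values for one cell type."""

    cell_type: str
    values: np.ndarray  # one gene count per resampling iteration
    median: float
    iqr: float


def gene_diversity(matrix: GeneCountMatrix, cell_types: Mapping[str, str],
                   n_cells: int = 10, n_iter: int = 100, min_cells: int = 2,
                   seed: int = 0) -> dict[str, DiversityResult]:
    """Per cell type: resample n_cells cells n_iter times and count genes
    expressed (>0) in strictly more than min_cells of the sampled cells.

    Cell types with fewer than n_cells member cells are excluded.
    """
    by_type: dict[str, list[str]] = defaultdict(list)
    for cell in matrix.cells:
        if cell in cell_types:
            by_type[cell_types[cell]].append(cell)
    rng = np.random.default_rng(seed)
    results: dict[str, DiversityResult] = {}
    for label in sorted(by_type):
        members = by_type[label]
        if len(members) < n_cells:
            continue
        expressed = (matrix.counts[members] > 0)
        values = np.empty(n_iter, dtype=int)
        for it in range(n_iter):
            idx = rng.choice(len(members), size=n_cells, replace=False)
            sampled = [members[i] for i in idx]
            n_expressing = expressed[sampled].sum(axis=1)
            values[it] = int((n_expressing > min_cells).sum())
        q1, med, q3 = np.percentile(values, [25, 50, 75])
        results[label] = DiversityResult(label, values, float(med),
                                         float(q3 - q1))
    return results


def cell_correlation(matrix: GeneCountMatrix,
                     cells: Optional[Sequence[str]] = None,
                     shared: str = "pair") -> pd.DataFrame:
    """Pairwise Kendall tau-b between cells on shared expressed genes.

    shared="pair" restricts each pair to genes with count > 0 in both cells;
    shared="all" uses genes with count > 0 in every cell of the subset.
    Pairs with an empty shared gene set are NaN. The matrix is symmetric
    with a unit diagonal.
    """
    use = list(cells) if cells is not None else matrix.cells
    if len(use) < 2:
        raise ValueError("need at least 2 cells")
    if shared not in ("pair", "all"):
        raise ValueError("shared must be 'pair' or 'all'")
    counts = matrix.counts[use]
    tau = pd.DataFrame(np.eye(len(use)), index=use, columns=use)
    if shared == "all":
        mask_all = (counts > 0).all(axis=1)
    for i, a in enumerate(use):
        for b in use[i + 1:]:
            mask = mask_all if shared == "all" else (
                (counts[a] > 0) & (counts[b] > 0))
            if not mask.any():
                tau.loc[a, b] = tau.loc[b, a] = float("nan")
                continue
            t = stats.kendalltau(counts.loc[mask, a], counts.loc[mask, b],
                                 variant="b").statistic
            tau.loc[a, b] = tau.loc[b, a] = float(t)
    return tau


def apply_gene_blacklist(matrix: GeneCountMatrix,
                         blacklist: Sequence[str]) -> GeneCountMatrix:
    """Drop excluded genes (e.g. mitochondrial/ribosomal) before statistics."""
    keep = [g for g in matrix.genes if g not in set(blacklist)]
    return GeneCountMatrix(matrix.counts.loc[keep], read_type=matrix.read_type)


__all__ = [
    "DiversityResult", "apply_gene_blacklist", "cell_correlation",
    "gene_diversity", "genes_detected", "saturation_curve",
]
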