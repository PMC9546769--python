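"""Molecule counting on the demo dataset and the UMI edit-distance check.

Counts UMI molecules per gene and cell (unique and directional) after the
invasion filter, counts internal reads at the 25 % overlap threshold, and
runs the within-gene UMI edit-distance diagnostic against the pooled
resampling null. Writes results/04_counts_umi.tsv,
results/04_counts_internal.tsv and results/04_edit_distance.tsv.
"""

from collections import defaultdict

import pandas as pd

from common import RESULTS, SEED, demo_config, ensure_dirs
from tsoumi.counts import (GeneIndex, assign_genes, count_internal,
                           count_molecules, edit_distance_diagnostic)
from tsoumi.invasion import annotate_upstream, dedup_5p, filter_invasion
from tsoumi.io import write_count_matrix, write_table
from tsoumi.simulate import simulate_dataset


def main() -> None:
    ensure_dirs()
    ds = simulate_dataset(demo_config())
    index = GeneIndex(ds.genes)

    umi_alns = [a for a in ds.alignments if a.umi]
    reads, _ = annotate_upstream(umi_alns, ds.genome)
    filtered, n_removed = filter_invasion(reads, max_mismatch=1)
    labelled = assign_genes(filtered, index, stranded=True)
    unique = count_molecules(labelled, "unique")
    directional = count_molecules(labelled, "directional")
    write_count_matrix(directional, RESULTS / "04_counts_umi.tsv")

    internal_ids = set(
        ds.truth.reads[ds.truth.reads.read_class == "internal"].read_id)
    internal = [a for a in ds.alignments if a.read_id in internal_ids]
    int_mat = count_internal(internal, index)
    write_count_matrix(int_mat, RESULTS / "04_counts_internal.tsv")

    # edit-distance diagnostic over position-deduplicated reads, one UMI
    # set per (gene, cell) to keep pair counts moderate
    sets = defaultdict(list)
    for r in dedup_5p(labelled):
        sets[(r.gene, r.cell)].append(r.umi)
    diag = edit_distance_diagnostic(sets, n_null_draws=1, seed=SEED)
    write_table(pd.DataFrame({
        "distance": range(9),
        "observed_frac": diag.observed_hist,
        "null_frac": diag.null_hist}), RESULTS / "04_edit_distance.tsv")

    truth_m = ds.truth.reads[
        ds.truth.reads.read_class.isin(["umi_r1", "umi_r2"])
        & ~ds.truth.reads.is_invasion].groupby(
        ["gene", "cell_id"]).molecule_id.nunique().sum()
    print(f"invasion filter removed {n_removed} of {len(reads)} UMI reads")
    print(f"UMI molecules: unique={unique.counts.to_numpy().sum()} "
          f"directional={directional.counts.to_numpy().sum()} "
          f"(truth non-invasion molecules: {truth_m})")
    print(f"internal reads assigned: {int_mat.counts.to_numpy().sum()} "
          f"of {len(internal)}")
    print(f"edit-distance diagnostic: observed mean "
          f"{diag.observed.mean():.3f} vs pooled-null mean "
          f"{diag.null.mean():.3f} over {diag.n_pairs_observed} within-gene "
          f"pairs (rank-sum p={diag.pvalue:.3f}); matching distributions "
          "indicate no UMI-inflation signal")


if __name__ == "__main__":
    main()
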