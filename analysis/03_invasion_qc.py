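"""Strand-invasion detection and filtering across simulated invasion rates.

For invasion rates of 0/2/5/10 % (20,000 error-free UMI reads each) this
driver measures the level-0..3 match fractions with and without the
GGG / spacer+GGG motif requirement, compares the level-0 motif-free
fraction against the simulated rate plus the analytic random-match null,
profiles the 6 bp adjacent to the read start, and applies the
max-1-mismatch read filter. Writes results/03_invasion_sweep.tsv,
results/03_invasion_report.tsv and results/03_readstart_profile.tsv.
"""

import numpy as np
import pandas as pd

from common import RESULTS, SEED, ensure_dirs
from tsoumi.invasion import (annotate_upstream, dedup_5p, filter_invasion,
                             invasion_report, random_match_probability,
                             readstart_profile)
from tsoumi.io import write_table
from tsoumi.simulate import SimConfig, simulate_dataset


def main() -> None:
    ensure_dirs()
    sweep_rows, reports = [], []
    null0 = random_match_probability(0)
    for i, p in enumerate((0.0, 0.02, 0.05, 0.10)):
        ds = simulate_dataset(SimConfig(
            seed=SEED + i, n_cells=2, reads_per_cell=10_000,
            frac_umi_reads=1.0, p_background=0.0, p_invasion=p,
            p_tso_tagmentation=0.0, n_het_snps=0, n_filterfail_snps=0,
            error_rate=0.0))
        reads, _ = annotate_upstream(ds.alignments, ds.genome)
        report = invasion_report(dedup_5p(reads))
        table = report.table.assign(p_invasion=p)
        reports.append(table)
        truth_inv = set(ds.truth.reads[ds.truth.reads.is_invasion].read_id)
        retained, removed = filter_invasion(reads, max_mismatch=1)
        kept_ids = {r.read_id for r in retained}
        recall = (sum(1 for r in truth_inv if r not in kept_ids)
                  / len(truth_inv)) if truth_inv else float("nan")
        expected = 100 * (p + (1 - p) * null0)
        sweep_rows.append({
            "p_invasion": p, "n_reads": len(reads),
            "match_pct_level0": report.pct(0, "none"),
            "expected_pct": expected,
            "filter_removed": removed,
            "filter_recall_pct": 100 * recall,
        })
        if p == 0.10:
            profile = readstart_profile(dedup_5p(reads), seed=SEED)
            profile.rename_axis("position").to_csv(
                RESULTS / "03_readstart_profile.tsv", sep="\t")
    sweep = pd.DataFrame(sweep_rows)
    write_table(sweep, RESULTS / "03_invasion_sweep.tsv")
    write_table(pd.concat(reports), RESULTS / "03_invasion_report.tsv")
    print("level-0 motif-free match fraction vs simulated invasion rate:")
    print(sweep.to_string(index=False,
                          float_format=lambda v: f"{v:.3f}"))
    print(f"analytic random-match null: {100 * null0:.4f}% per read; "
          "the filter removes matching reads at <=1 consecutive 5' mismatch")


if __name__ == "__main__":
    main()
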