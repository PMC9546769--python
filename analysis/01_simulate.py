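"""Generate the demo dataset all later drivers analyse.

Writes the full dataset (genome, annotation, paired FASTQ, alignments,
exome VCF, truth tables) to scratch/sim_demo/ and a class-composition
summary to results/01_sim_summary.tsv.
"""

import pandas as pd

from common import RESULTS, SCRATCH, ensure_dirs, demo_config
from tsoumi.io import write_table
from tsoumi.simulate import simulate_dataset


def main() -> None:
    ensure_dirs()
    ds = simulate_dataset(demo_config())
    paths = ds.write(SCRATCH / "sim_demo")
    t = ds.truth.reads
    summary = (t.read_class.value_counts().rename_axis("read_class")
               .reset_index(name="n_reads"))
    summary["fraction"] = summary.n_reads / len(t)
    write_table(summary, RESULTS / "01_sim_summary.tsv")
    print(f"simulated {len(ds.pairs)} read pairs over {ds.config.n_cells} "
          f"cells -> {paths['fastq1'].parent}")
    print(summary.to_string(index=False))
    print(f"{t.is_invasion.sum()} strand-invasion reads "
          f"({100 * t.is_invasion.mean():.2f}% of all reads); "
          f"{len(ds.exome_variants)} exome variants "
          f"({ds.truth.variants.passes_filters.sum()} pass hard filters)")


if __name__ == "__main__":
    main()
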