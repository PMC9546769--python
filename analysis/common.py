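"""Shared configuration for the numbered analysis drivers.

Generated datasets (FASTQ/SAM/FASTA, potentially large) go to scratch/;
small summary tables go to results/.
"""

from pathlib import Path

from tsoumi.simulate import SimConfig

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"

SEED = 42

# Mixed-condition demo dataset used by drivers 01-02 and 04-06: eight cells,
# half 5' UMI reads, 5 % background, 2 % strand invasion, 5 % intra-TSO
# tagmentation, 50 planted het SNPs, error-free reads.
DEMO = dict(seed=SEED, n_cells=8, reads_per_cell=4000,
            frac_umi_reads=0.5, p_background=0.05, p_invasion=0.02,
            p_tso_tagmentation=0.05, n_het_snps=50, error_rate=0.0)


def demo_config(**overrides) -> SimConfig:
    kwargs = dict(DEMO)
    kwargs.update(overrides)
    return SimConfig(**kwargs)


def ensure_dirs() -> None:
    SCRATCH.mkdir(exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
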