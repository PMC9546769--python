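import pytest

from tsoumi.extract import OligoConfig
from tsoumi.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def oligo() -> OligoConfig:
    return OligoConfig()


@pytest.fixture(scope="session")
def small_dataset():
    """Mixed-class dataset shared across unit tests (deterministic)."""
    cfg = SimConfig(seed=11, n_cells=4, reads_per_cell=1500,
                    p_invasion=0.05, p_tso_tagmentation=0.05,
                    error_rate=0.0)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def umi_only_dataset():
    """All-UMI dataset without SNPs, for invasion/extraction statistics."""
    cfg = SimConfig(seed=5, n_cells=3, reads_per_cell=4000,
                    frac_umi_reads=1.0, p_background=0.0,
                    p_tso_tagmentation=0.05, p_invasion=0.05,
                    n_het_snps=0, n_filterfail_snps=0, error_rate=0.0)
    return simulate_dataset(cfg)
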