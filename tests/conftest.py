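import pytest

from twobrad.pipeline import run_simulated_screen
from twobrad.simulate import SimConfig


@pytest.fixture(scope="session")
def zw_clean():
    """Small error-free ZW population screened end to end."""
    cfg = SimConfig(
        seed=3, genome_length=25_000, n_autosomal_tags=50,
        n_gametolog_snps=5, n_autosomal_snps=10,
        coverage_mean=30.0, error_rate=0.0,
    )
    return run_simulated_screen(cfg)


@pytest.fixture(scope="session")
def zw_noisy():
    """Full-scale ZW study design: 10 F + 10 M, 100 kb, 3 W tags,
    10 gametolog SNPs, 200 autosomal tag loci, 30x coverage, 1% error."""
    cfg = SimConfig(seed=42, coverage_mean=30.0, error_rate=0.01)
    return run_simulated_screen(cfg)
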