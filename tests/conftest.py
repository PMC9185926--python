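import pytest

from epmap.pipeline import RunConfig
from epmap.simulate import SimConfig, simulate


def mini_config(seed: int = 3) -> SimConfig:
    """Small bundle for fast unit tests; same generative model as the default."""
    return SimConfig(seed=seed, chrom_length=3_000_000, n_genes=120,
                     n_enhancers=140, n_tads=12, n_loops=400, n_snps=1000,
                     n_samples_per_pop=30, n_contact_pairs=3000,
                     n_grid_reads=600, n_causal=4, n_decoys=10,
                     n_sweep_windows=2, n_atac_peaks=80)


@pytest.fixture(scope="session")
def mini_bundle():
    return simulate(mini_config())


@pytest.fixture(scope="session")
def bundle():
    """Default-scale bundle: 2 chromosomes x 10 Mb, ~500 genes, ~5000 SNPs,
    10 planted causal variants and 50 single-step decoys."""
    return simulate(SimConfig(seed=11))


@pytest.fixture(scope="session")
def run_config():
    return RunConfig(seed=11)
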