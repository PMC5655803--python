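import pytest

from subfrac.simulate import SimulationConfig, simulate_system


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=11, n_chroms=2, chrom_length=400_000, n_genes=60,
        n_deletions_L=15, n_deletions_S=30,
        n_specific_peaks_per_subgenome=6, n_p300_per_chrom=12)


@pytest.fixture(scope="session")
def small_system(small_config, tmp_path_factory):
    """A small simulated triplet-genome system shared across tests."""
    outdir = tmp_path_factory.mktemp("system")
    truth = simulate_system(small_config, str(outdir))
    return small_config, truth, str(outdir)
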