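"""Shared fixtures: one small simulated two-condition dataset per session."""

import pytest

from srnakit.pipeline import analyze
from srnakit.simulate import (
    SimulationConfig,
    generate_genome,
    known_mature_db,
    simulate_libraries,
    write_dataset,
)

SMALL = dict(
    seed=11,
    genome_length=60_000,
    n_known_mirna=6,
    n_novel_mirna=5,
    n_decoy_loci=3,
    library_depths=(12_000, 12_000),
    n_background_loci=80,
    n_genes=4,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(**SMALL)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    genome = generate_genome(small_config)
    reads_c, reads_t = simulate_libraries(genome, small_config)
    return genome, reads_c, reads_t


@pytest.fixture(scope="session")
def small_results(small_config, small_dataset):
    genome, reads_c, reads_t = small_dataset
    return analyze(
        genome.sequence, genome.features, known_mature_db(genome.truth), reads_c, reads_t
    )


@pytest.fixture(scope="session")
def small_dataset_dir(tmp_path_factory, small_dataset):
    genome, reads_c, reads_t = small_dataset
    outdir = tmp_path_factory.mktemp("dataset")
    return write_dataset(outdir, genome, reads_c, reads_t), genome
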