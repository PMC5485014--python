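import pytest

from supergene.synthetic import SimParams, simulate_dataset, simulate_tables

# A scaled-down study: two scaffolds, 150 kb supergene region, 8v8 samples.
SMALL_PARAMS = SimParams(
    seed=11,
    scaffold_lengths=(500_000, 400_000),
    region_span=("scf_1", 100_000, 250_000),
    gene_count=60,
    str_locus_count=80,
)


@pytest.fixture(scope="session")
def small_sim():
    return simulate_tables(SMALL_PARAMS)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("simdata")
    return simulate_dataset(SMALL_PARAMS, str(outdir))
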