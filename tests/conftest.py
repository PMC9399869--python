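import numpy as np
import pytest

from slsplice import GeneratorConfig, generate_bundle, generate_sl_system


@pytest.fixture(scope="session")
def psinerae():
    return generate_sl_system("psinerae")


@pytest.fixture(scope="session")
def maranthos():
    return generate_sl_system("maranthos")


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(n_transcripts=300, n_contigs=3, contig_length=6000,
                           n_gene_loci=2, n_cis_decoys=1)


@pytest.fixture(scope="session")
def small_bundle(psinerae, small_config):
    return generate_bundle(psinerae, small_config, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
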