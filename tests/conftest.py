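import numpy as np
import pytest

from ventmag import synth


@pytest.fixture(scope="session")
def two_communities():
    """The default active-vs-inactive chimney contrast (fixed seed)."""
    return synth.default_community(seed=11)


@pytest.fixture(scope="session")
def gene_tables(two_communities):
    comm_a, comm_b = two_communities
    return (synth.generate_gene_table(comm_a, "A"),
            synth.generate_gene_table(comm_b, "B"))


@pytest.fixture(scope="session")
def bin_metadata(two_communities):
    """Bin fixtures with 15% injected contaminant contigs, 2 candidate
    bins per taxon."""
    comm_a, _ = two_communities
    return synth.generate_bin_metadata(comm_a, contamination_fraction=0.15,
                                       bins_per_taxon=2, seed=17)


@pytest.fixture
def rng():
    return np.random.default_rng(5)
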