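"""Shared fixtures: a small bound microbiome + universe + error-free reads.

Everything is generated at test time from fixed seeds; no data files.
"""

import numpy as np
import pytest

from vmbench.classify import build_kmer_index, classify_readset
from vmbench.ecology import EcologyParams, generate_ecology
from vmbench.readsim import ReadSimConfig, simulate_reads
from vmbench.universe import UniverseSpec, bind_ecology_to_universe, generate_universe

SMALL = dict(n_species=40, n_genera=12, n_families=4, n_communities=10)


@pytest.fixture(scope="session")
def small_vm():
    return generate_ecology(EcologyParams(**SMALL, seed=11))


@pytest.fixture(scope="session")
def small_universe(small_vm):
    spec = UniverseSpec.matching(small_vm, genome_length=5_000,
                                 primer_fail_prob=0.1, seed=12)
    db_16s, db_genome, taxonomy = generate_universe(spec)
    return spec, db_16s, db_genome, taxonomy


@pytest.fixture(scope="session")
def bound_vm(small_vm, small_universe):
    _, _, _, taxonomy = small_universe
    return bind_ecology_to_universe(small_vm, taxonomy)


@pytest.fixture(scope="session")
def clean_reads(bound_vm, small_universe):
    """2000 error-free amplicon pairs from the complete 16S database."""
    _, db_16s, _, _ = small_universe
    config = ReadSimConfig.amplicon(total_reads=2000, error_a=0.0,
                                    error_b=0.0, seed=13)
    return simulate_reads(bound_vm, 0, db_16s, config)


@pytest.fixture(scope="session")
def clean_classification(clean_reads, small_universe):
    _, db_16s, _, _ = small_universe
    index = build_kmer_index(db_16s, k=31)
    return index, classify_readset(clean_reads, index, min_hits=10)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
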