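"""Shared fixtures: tiny hand-built communities plus a 5-genome simulated one.

Everything is generated in-process; nothing is read from disk except where a
test exercises the file round trip itself.
"""

from __future__ import annotations

import pytest

from smartmeta import (
    CommunityParams,
    IndexParams,
    TaxonAssignment,
    TaxonomyTable,
    build_index,
    simulate_community,
    simulate_reads,
)


@pytest.fixture(scope="session")
def two_species_taxonomy() -> TaxonomyTable:
    return TaxonomyTable(
        {
            "refA": TaxonAssignment.from_lineage(
                "E. coli", "Escherichia", "Gammaproteobacteria"
            ),
            "refB": TaxonAssignment.from_lineage(
                "H. sapiens", "Homo", "Mammalia"
            ),
        }
    )


@pytest.fixture(scope="session")
def community5():
    """5 disjoint random 3 kb genomes, seed 1 — the standard fixture."""
    return simulate_community(
        CommunityParams(n_species=5, genome_length=3000, seed=1)
    )


@pytest.fixture(scope="session")
def index5(community5):
    return build_index(
        community5.records, community5.taxonomy, IndexParams()
    )


@pytest.fixture(scope="session")
def reads_clean(community5):
    """1,000 error-free 100 bp reads from the 5-genome community."""
    return simulate_reads(
        community5, 1000, read_length=100, substitution_rate=0.0, seed=11
    )


@pytest.fixture(scope="session")
def reads_noisy(community5):
    """1,000 reads at 1% substitution rate (most carry 1-3 errors)."""
    return simulate_reads(
        community5, 1000, read_length=100, substitution_rate=0.01, seed=12
    )


@pytest.fixture(scope="session")
def host_community():
    """5 microbes plus a mammalian host genome; host draws half the reads."""
    return simulate_community(
        CommunityParams(
            n_species=5, genome_length=3000, host_fraction=0.5, seed=3
        )
    )


@pytest.fixture(scope="session")
def host_index(host_community):
    return build_index(
        host_community.records, host_community.taxonomy, IndexParams()
    )
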