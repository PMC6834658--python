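import logging

import numpy as np
import pytest

from n2kprior.datatypes import Dataset, OccurrenceMatrix, Site, SpeciesRecord
from n2kprior.synthetic import SyntheticConfig, generate_dataset

# keep the solver/scenario warning chatter out of test output
logging.getLogger("n2kprior").setLevel(logging.ERROR)


SMALL_TAXA = {"amphibian": 5, "bird": 10, "fish": 10, "mammal": 5, "reptile": 5}


@pytest.fixture(scope="session")
def small_dataset() -> Dataset:
    """60-site, 35-species synthetic dataset for fast pipeline tests."""
    config = SyntheticConfig(
        n_sites=60,
        n_species_per_taxon=SMALL_TAXA,
        range_size_distribution=(np.log(15), 0.8),
        seed=3,
    )
    return generate_dataset(config)


@pytest.fixture(scope="session")
def medium_dataset() -> Dataset:
    """150-site dataset with enough eligible species for threshold effects."""
    config = SyntheticConfig(
        n_sites=150,
        n_species_per_taxon={"amphibian": 20, "bird": 40, "fish": 40,
                             "mammal": 20, "reptile": 20},
        range_size_distribution=(np.log(30), 1.0),
        seed=42,
    )
    return generate_dataset(config)


def make_tiny_dataset() -> Dataset:
    """Hand-built 5-site, 4-species dataset with known structure."""
    species = [
        SpeciesRecord("sp1", "bird", "EN", True,
                      habitats_preferred=frozenset({"h1"})),
        SpeciesRecord("sp2", "fish", "VU", True,
                      habitats_preferred=frozenset({"h1"}),
                      habitats_suitable=frozenset({"h2"})),
        SpeciesRecord("sp3", "mammal", "CR", False,
                      habitats_preferred=frozenset({"h2"})),
        SpeciesRecord("sp4", "reptile", "LC", True,
                      habitats_preferred=frozenset({"h3"})),
    ]
    matrix = np.array(
        [
            [1, 1, 0, 1],
            [1, 0, 1, 0],
            [0, 1, 1, 0],
            [1, 1, 1, 1],
            [0, 0, 1, 1],
        ],
        dtype=bool,
    )
    site_ids = [f"s{i}" for i in range(5)]
    sites = [
        Site("s0", frozenset({"sp1"}), latitude=40.0),
        Site("s1", frozenset(), latitude=45.0),
        Site("s2", frozenset({"sp2"}), latitude=50.0),
        Site("s3", frozenset({"sp1", "sp4"}), latitude=55.0),
        Site("s4", frozenset(), latitude=60.0),
    ]
    return Dataset(
        species=species,
        sites=sites,
        occurrence=OccurrenceMatrix(
            site_ids=site_ids, species_ids=[s.species_id for s in species],
            matrix=matrix,
        ),
    )


@pytest.fixture()
def tiny_dataset() -> Dataset:
    return make_tiny_dataset()
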