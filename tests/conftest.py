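import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gutindices import (
    AbundanceProfile,
    CohortTable,
    SampleMetadata,
    TaxonLineage,
    load_default_classification,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def genus_lineage(genus: str, kingdom: str = "Bacteria") -> TaxonLineage:
    return TaxonLineage(ranks=(("k", kingdom), ("g", genus)), genus=genus)


def species_lineage(binomial: str, kingdom: str = "Bacteria") -> TaxonLineage:
    genus = binomial.split()[0]
    return TaxonLineage(
        ranks=(("k", kingdom), ("g", genus), ("s", binomial)),
        genus=genus,
        species=binomial,
    )


@pytest.fixture(scope="session")
def aero_table():
    return load_default_classification()


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_101)


@pytest.fixture()
def tiny_cohort():
    """Three samples over two classified genera plus one unclassified taxon."""
    esch = genus_lineage("Escherichia")
    bact = genus_lineage("Bacteroides")
    mystery = genus_lineage("Zymopluto")  # not in any classification
    profiles = [
        AbundanceProfile("s1", {esch: 0.3, bact: 0.3, mystery: 0.4}),
        AbundanceProfile("s2", {esch: 0.2, bact: 0.4, mystery: 0.4}),
        AbundanceProfile("s3", {esch: 10.0, bact: 990.0}),
    ]
    metadata = {
        "s1": SampleMetadata(age=30, gender="female", conditions=[]),
        "s2": SampleMetadata(age=40, gender="male", conditions=["IBS"]),
        "s3": SampleMetadata(age=50, gender="male", conditions=["ulcerative colitis"]),
    }
    return CohortTable(profiles=profiles, metadata=metadata)
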