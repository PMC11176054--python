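import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from polyhap.core import GenomeLayout
from polyhap.sim import SimulationConfig, rng_from, simulate_founders

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_layout():
    return GenomeLayout((("chr01", 8_000_000), ("chr02", 6_000_000)))


@pytest.fixture(scope="session")
def small_config(small_layout):
    return SimulationConfig(layout=small_layout, founder_ids=("A", "B", "C", "D"),
                            snp_density=60.0, reference_private_density=60.0,
                            introgressions={}, seed=11)


@pytest.fixture(scope="session")
def small_panel(small_config):
    return simulate_founders(small_config, rng=rng_from(small_config.seed, 0))


@pytest.fixture(scope="session")
def two_founder_layout():
    return GenomeLayout((("chr01", 40_000_000), ("chr02", 30_000_000)))


@pytest.fixture(scope="session")
def two_founder_config(two_founder_layout):
    return SimulationConfig(layout=two_founder_layout, founder_ids=("A", "B"),
                            snp_density=100.0, reference_private_density=100.0,
                            introgressions={}, seed=5)


@pytest.fixture(scope="session")
def two_founder_panel(two_founder_config):
    return simulate_founders(two_founder_config, rng=rng_from(two_founder_config.seed, 0))


def toy_variants(records, layout=None):
    """(chrom, pos, ref, alt, genotype_class[, evidence]) tuples -> VariantSet."""
    from polyhap.core import VariantSet
    return VariantSet.from_records(records, layout=layout)
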