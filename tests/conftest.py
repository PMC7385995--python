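"""Shared fixtures: small synthetic genomes with planted MITE families.

Everything is generated programmatically with fixed seeds; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from mitescout.config import PipelineConfig
from mitescout import simulate as sim

# ages spanning the recent-amplification burst, with a slice of undiverged
# copies so exact-structure assertions have substrate
BURST_AGES = [(0.0, 0.1), (1.0e6, 0.2), (2.0e6, 0.4), (3.0e6, 0.3)]


def family_specs(n_copies: int = 10):
    return [
        sim.PlantSpec(
            family_id="famA", element_len=673, tir_len=25, tsd_len=8,
            at_fraction=0.70, n_copies=n_copies, age_distribution=list(BURST_AGES),
        ),
        sim.PlantSpec(
            family_id="famB", element_len=666, tir_len=12, tsd_len=8,
            at_fraction=0.75, n_copies=n_copies, age_distribution=list(BURST_AGES),
        ),
    ]


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_fixture(config):
    """150 kb genome, 15 genes, 2 families x 10 copies."""
    genome, genes = sim.simulate_genome(150_000, 0.36, 15, seed=3)
    planted, shifted_genes, truth = sim.plant_mites(
        genome, genes, family_specs(10), config, seed=4
    )
    return {
        "pristine": genome,
        "genome": planted,
        "genes": shifted_genes,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def discovered_families(small_fixture, config):
    from mitescout.discovery import discover_elements

    return discover_elements(small_fixture["genome"], config)
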