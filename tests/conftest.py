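"""Shared fixtures: synthetic clades at two scales.

The *default* clade (5 strains x ~300 kb, seed 42) is the standard scenario
for end-to-end checks; the *small* clade (3 strains x ~80 kb) keeps unit
tests fast.  Both are session-scoped — generation and the all-vs-all
analysis are the expensive steps.
"""

from __future__ import annotations

import numpy as np
import pytest

from fgikit.island_detect import DetectParams
from fgikit.pipeline import analyze_islands
from fgikit.synthetic_clade import (CladeConfig, IslandSpec,
                                    default_clade_config, generate_clade,
                                    three_species_config)


@pytest.fixture(scope="session")
def default_clade():
    return generate_clade(default_clade_config())


@pytest.fixture(scope="session")
def default_analysis(default_clade):
    genomes, _ = default_clade
    return analyze_islands(genomes)


def small_clade_config(seed: int = 11) -> CladeConfig:
    return CladeConfig(
        seed=seed,
        n_species=1,
        strains_per_species=3,
        ancestor_length=80_000,
        island_specs=[
            IslandSpec("replacement", 0.25, (9_000, 12_000), "strain_unique"),
            IslandSpec("additive", 0.55, (3_000, 5_000), "subset",
                       carrier_count=2, n_cassettes=2),
            IslandSpec("tycheposon", 0.80, (8_000, 10_000), "subset",
                       carrier_count=2, variable_tail_bp=3_000),
        ],
    )


@pytest.fixture(scope="session")
def small_clade():
    return generate_clade(small_clade_config())


@pytest.fixture(scope="session")
def small_params():
    return DetectParams(gap_min_span=2000)


@pytest.fixture(scope="session")
def small_analysis(small_clade, small_params):
    genomes, _ = small_clade
    return analyze_islands(genomes, params=small_params)


@pytest.fixture(scope="session")
def three_species_clade():
    return generate_clade(three_species_config(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
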