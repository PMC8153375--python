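"""Shared fixtures: small seeded simulation bundles used across test modules."""
from __future__ import annotations

import pytest

from mircms.synthetic_data import SimConfig, make_catalog


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        seed=11, n_families=8, n_novel_loci=4, n_decoy_loci=4,
        libraries=(("A", 3000), ("B", 3000)), n_genes=120, n_targets=12,
        planted_family_targets=6,
    )


@pytest.fixture(scope="session")
def small_catalog(small_config):
    return make_catalog(small_config)
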