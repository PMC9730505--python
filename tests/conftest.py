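"""Shared fixtures: small synthetic registries, pools and cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from tcemm.cohort import build_haplotype_pool, sample_genotypes
from tcemm.presentation import DefaultPresentationModel
from tcemm.registry import synthesize_registry


@pytest.fixture(scope="session")
def small_registry():
    """Compact registry (short proteins) for exhaustive oracle checks."""
    return synthesize_registry(
        4, 8, seed=11, version_tag="test-small", length_range=(30, 60)
    )


@pytest.fixture(scope="session")
def small_pool(small_registry):
    return build_haplotype_pool(small_registry, 8, seed=11)


@pytest.fixture(scope="session")
def small_model(small_registry):
    return DefaultPresentationModel(small_registry, q_bind=0.25, seed=11)


@pytest.fixture(scope="session")
def small_pairs(small_pool):
    return sample_genotypes(small_pool, 30, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
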