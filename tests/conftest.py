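"""Shared fixtures: a small synthetic cohort run through the full pipeline."""

from __future__ import annotations

import numpy as np
import pytest

from rxmine import simulate as sim
from rxmine.config import AppConfig
from rxmine.pipeline import PipelineResult, prepare
from rxmine.transactions import TransactionSet

UNIT_N = 3000
UNIT_SEED = 11


@pytest.fixture(scope="session")
def unit_spec() -> sim.CohortSpec:
    return sim.CohortSpec(n_patients=UNIT_N, seed=UNIT_SEED)


@pytest.fixture(scope="session")
def unit_cohort(unit_spec):
    return sim.generate_cohort(unit_spec)


@pytest.fixture(scope="session")
def app_config() -> AppConfig:
    return AppConfig(phenotype=sim.default_phenotype_config())


@pytest.fixture(scope="session")
def drug_map():
    return sim.drug_mapping_frame()


@pytest.fixture(scope="session")
def specialty_map():
    return sim.specialty_mapping_frame()


@pytest.fixture(scope="session")
def pipeline_result(unit_cohort, drug_map, specialty_map, app_config) -> PipelineResult:
    claims, _ = unit_cohort
    return prepare(claims, drug_map, specialty_map, app_config)


def random_transaction_set(
    rng: np.random.Generator,
    max_transactions: int = 200,
    max_items: int = 12,
) -> TransactionSet:
    """A random small basket instance for oracle-equivalence checks."""
    n_items = int(rng.integers(1, max_items + 1))
    alphabet = [f"i{k:02d}" for k in range(n_items)]
    n_trans = int(rng.integers(1, max_transactions + 1))
    items = []
    for _ in range(n_trans):
        size = int(rng.integers(0, n_items + 1))
        items.append(frozenset(rng.choice(alphabet, size=size, replace=False)))
    return TransactionSet(
        level=5,
        patient_ids=[str(i) for i in range(n_trans)],
        items=items,
        n_diabetic=0,
    )


def itemset_key(itemsets):
    """Canonical comparable form of a FrequentItemset collection."""
    return sorted((tuple(sorted(fi.items)), fi.support_count) for fi in itemsets)
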