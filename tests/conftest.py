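"""Shared fixtures: synthetic datasets and fitting targets.

Expensive session-scoped fixtures are generated once; everything is
seeded so the suite is deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from grnkit import data_core, sparse_abc, synthetic_data
from grnkit.data_core import GENES, MUTANT_OF, WILD_TYPE, genotype_activities

SINGLE_GENOTYPES = [WILD_TYPE] + [MUTANT_OF[g] for g in GENES]


@pytest.fixture(scope="session")
def final_l1_gt():
    return synthetic_data.preset_ground_truth("final-L1", n_animals=200, seed=1)


@pytest.fixture(scope="session")
def final_l1_dataset(final_l1_gt):
    return synthetic_data.generate_dataset(final_l1_gt)


@pytest.fixture(scope="session")
def final_l1_target(final_l1_dataset):
    stats = data_core.summarize_expression(
        final_l1_dataset, "late-L1", n_boot=500, seed=1, boot_unit="animal"
    )
    return sparse_abc.target_from_summary(stats, GENES, SINGLE_GENOTYPES)


@pytest.fixture(scope="session")
def single_genotype_specs():
    return [genotype_activities(n, stage="ode") for n in SINGLE_GENOTYPES]


@pytest.fixture(scope="session")
def small_dataset():
    gt = synthetic_data.preset_ground_truth("final-L1", n_animals=30, seed=5)
    return synthetic_data.generate_dataset(gt)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
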