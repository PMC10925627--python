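"""Shared fixtures: a small lesion bank, phantom cohort and dataset.

Everything is generated programmatically with fixed seeds so the suite is
fully reproducible and ships no data files.
"""

import pytest

import lesionbench as lb


@pytest.fixture(scope="session")
def forge_config() -> lb.ForgeConfig:
    # capped extent so stamps fit the 64x64 test phantoms
    return lb.ForgeConfig(max_extent=16)


@pytest.fixture(scope="session")
def bank(forge_config) -> lb.LesionBank:
    return lb.build_lesion_bank(10, 10, seed=0, w=0.5, config=forge_config)


@pytest.fixture(scope="session")
def cohort():
    return lb.phantom_cohort(12, seed=0, size=64)


@pytest.fixture(scope="session")
def dataset(cohort, bank) -> lb.BenchmarkDataset:
    ds = lb.build_dataset(cohort, bank, 60, seed=0)
    return lb.split_by_subject(ds, seed=0)
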