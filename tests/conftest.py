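"""Shared fixtures: hand-built datasets and fast small-scale simulations."""

import numpy as np
import pytest

from snpascert.demography import DemographySpec, IslandModelSpec, SimulationParams, build_island
from snpascert.replicates import DISCOVERY, TYPING, HaplotypeDataset, SamplingDesign


@pytest.fixture
def small_params():
    """Cheap locus for unit-level simulation tests."""
    return SimulationParams(theta=5.0, rho=5.0, length=5_000, N0=1_000)


@pytest.fixture
def small_design():
    return SamplingDesign(n_discovery=10, n_typing=10)


@pytest.fixture
def two_island_small(small_params):
    return build_island(IslandModelSpec(2, 0.1), small_params)


@pytest.fixture
def panmictic(small_params):
    return DemographySpec(
        deme_sizes=(float(small_params.N0),),
        migration_matrix=((0.0,),),
        label="panmictic",
    )


def make_dataset(matrix, pop_sizes, n_discovery, positions=None, reuse=False):
    """Hand-built HaplotypeDataset: per population, first rows are discovery."""
    matrix = np.asarray(matrix, dtype=np.int8)
    n_hap = matrix.shape[0]
    assert sum(pop_sizes) == n_hap
    pop_labels = np.repeat(np.arange(len(pop_sizes)), pop_sizes)
    if reuse:
        role_labels = np.full(n_hap, DISCOVERY)
    else:
        role_labels = np.concatenate(
            [
                np.concatenate([np.full(n_discovery, DISCOVERY), np.full(s - n_discovery, TYPING)])
                for s in pop_sizes
            ]
        )
    if positions is None:
        positions = (np.arange(matrix.shape[1]) + 0.5) / max(matrix.shape[1], 1)
    return HaplotypeDataset(
        matrix=matrix,
        positions=positions,
        pop_labels=pop_labels,
        role_labels=role_labels,
    )


@pytest.fixture
def dataset_factory():
    return make_dataset
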