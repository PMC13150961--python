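import numpy as np
import pytest

from idscn.atlas import dk_atlas, edge_enumeration
from idscn.network import cohort_z_by_group
from idscn.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def atlas():
    return dk_atlas()


@pytest.fixture(scope="session")
def edges(atlas):
    return edge_enumeration(atlas, "unique_pairs")


def make_z_by_group(seed: int, atlas, edges, planted: bool = True):
    """Cohort -> per-group IDSCN z arrays; planted=False gives a pure null."""
    if planted:
        cfg = CohortConfig(seed=seed)
    else:
        cfg = CohortConfig(seed=seed, planted_effects=(), hours_models={})
    cohort = generate_cohort(cfg, atlas)
    return cohort_z_by_group(cohort.table, "CONTROL", edges), cohort


@pytest.fixture(scope="session")
def planted_cohort(atlas, edges):
    """One planted-effect cohort with its z arrays, shared across tests."""
    z, cohort = make_z_by_group(7, atlas, edges, planted=True)
    return z, cohort
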