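"""Shared fixtures: small synthetic cohorts and toy BOLD helpers."""

import numpy as np
import pytest

from fcdstrat.cohort import CohortConfig, default_tasks, generate_cohort
from fcdstrat.fcd import BoldSeries


def make_series(data, tr=3.0, subject_id="sub-000", visit=1):
    """Wrap a voxel x frame matrix in a BoldSeries on a line grid."""
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    coords = np.column_stack([np.arange(n), np.zeros(n, int), np.zeros(n, int)])
    return BoldSeries(data=data, tr=tr, coords=coords, shape=(n, 1, 1),
                      subject_id=subject_id, visit=visit)


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(n_controls=20, n_prehd=20, n_sites=4, seed=11,
                        n_voxels=216, n_frames=60, tasks=default_tasks()[:4])


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
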