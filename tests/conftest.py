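import numpy as np
import pytest

from dfcvar.cohort import CohortSpec
from dfcvar.io import SubjectTimeSeries
from dfcvar.partition import NetworkPartition, make_partition
from dfcvar.variability import FCWindowStack


@pytest.fixture
def small_partition() -> NetworkPartition:
    """Four small modules over 14 nodes."""
    return make_partition({"A": 4, "B": 3, "C": 4, "D": 3})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)


@pytest.fixture
def random_stack(rng) -> FCWindowStack:
    """Random valid FC stack, M=6 nodes, N=4 windows."""
    return make_random_stack(rng, n_windows=4, n_nodes=6)


def make_random_stack(rng, n_windows: int, n_nodes: int) -> FCWindowStack:
    blocks = rng.standard_normal((n_windows, 30, n_nodes))
    mats = []
    for b in blocks:
        C = np.corrcoef(b, rowvar=False)
        np.fill_diagonal(C, 1.0)
        mats.append(C)
    return FCWindowStack(subject_id="rand", windows=np.stack(mats), window_length=30)


@pytest.fixture
def small_series(rng, small_partition) -> SubjectTimeSeries:
    data = rng.standard_normal((60, small_partition.n_nodes))
    return SubjectTimeSeries(subject_id="s1", data=data, tr_seconds=2.0)


def micro_spec(**kwargs) -> CohortSpec:
    """A fast, small cohort spec used across tests; study rates kept, geometry shrunk."""
    defaults = dict(
        n_control=4,
        n_patient=4,
        partition=make_partition({"A": 6, "B": 5, "C": 6, "D": 5, "Uncertain": 4}),
        target_modules=("A", "C"),
        n_volumes=120,
        seed=7,
    )
    defaults.update(kwargs)
    return CohortSpec(**defaults)
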