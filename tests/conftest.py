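import numpy as np
import pytest

from splicescape.psi import build_psi_matrix
from splicescape.synthetic import SimConfig, simulate_bulk
from splicescape.types import PsiMatrix


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale config used by most recovery tests."""
    return SimConfig(
        n_samples=120,
        n_events=200,
        n_informative=60,
        reads_per_event=100.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bulk(small_config):
    return simulate_bulk(small_config)


@pytest.fixture(scope="session")
def small_matrix(small_bulk):
    return build_psi_matrix(small_bulk.counts, small_bulk.events)


def random_psi_matrix(rng, n_events=20, n_samples=10, detect_rate=0.8):
    """Random PsiMatrix helper with engineered detection masks."""
    detected = rng.random((n_events, n_samples)) < detect_rate
    psi = np.where(detected, rng.random((n_events, n_samples)), np.nan)
    ciw = np.where(detected, rng.random((n_events, n_samples)), np.nan)
    return PsiMatrix(
        [f"E{i}" for i in range(n_events)],
        [f"S{j}" for j in range(n_samples)],
        psi,
        ciw,
        detected,
    )
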