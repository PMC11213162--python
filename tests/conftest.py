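import numpy as np
import pytest

from gfcband.synthetic import CohortSpec, generate_cohort


def random_signed_fc(m: int, seed: int = 0, density: float = 1.0) -> np.ndarray:
    """Random symmetric signed matrix in (-1, 1), zero diagonal."""
    rng = np.random.default_rng(seed)
    a = rng.uniform(-0.8, 0.9, size=(m, m))
    if density < 1.0:
        a[rng.random((m, m)) > density] = 0.0
    a = np.triu(a, k=1)
    a = a + a.T
    return a


def random_positive_fc(m: int, seed: int = 0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    a = np.triu(rng.uniform(0.05, 0.95, size=(m, m)), k=1)
    return a + a.T


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny deterministic cohort shared across tests (M=8, 4+4 subjects)."""
    spec = CohortSpec(n_group_a=4, n_group_b=4, n_rois=8,
                      effect_edges=[(0, 1)], effect_size=0.3, seed=11)
    return spec, generate_cohort(spec)
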