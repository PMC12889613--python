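import numpy as np
import pytest

import pottsthread as pt
from pottsthread.potts import PottsModel, zero_sum_gauge


def random_model(L: int, q: int, seed: int, density: float = 1.0) -> PottsModel:
    """Dense-ish random Potts model with the required coupling symmetry."""
    rng = np.random.default_rng(seed)
    J = np.zeros((L, L, q, q))
    iu, ju = np.triu_indices(L, k=1)
    for i, j in zip(iu, ju):
        if rng.random() <= density:
            block = rng.normal(0, 1, size=(q, q))
            J[i, j] = block
            J[j, i] = block.T
    h = rng.normal(0, 1, size=(L, q))
    return PottsModel(h=h, J=J, gauge="raw")


def brute_force_energy(model: PottsModel, seq) -> float:
    """Independent double-loop oracle for the Potts energy."""
    e = 0.0
    for i in range(model.L):
        e += model.h[i, seq[i]]
        for j in range(i + 1, model.L):
            e += model.J[i, j, seq[i], seq[j]]
    return e + model.offset


def brute_force_threading(model: PottsModel, seq, delta) -> float:
    """Independent double-loop oracle for the threading score (zero-sum gauge)."""
    m = zero_sum_gauge(model)
    t = 0.0
    for i in range(m.L):
        for j in range(i + 1, m.L):
            t -= m.J[i, j, seq[i], seq[j]] * delta[i, j]
    return t


@pytest.fixture(scope="session")
def small_world():
    """A modest synthetic world shared by read-only tests."""
    return pt.make_world(n_kinases=60, n_inhibitors=20, seed=7)
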