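import numpy as np
import pytest

import thermosig as ts


@pytest.fixture(scope="session")
def small_study() -> ts.SimulatedStudy:
    """A scaled-down three-year study with planted truth (shared, read-only)."""
    params = ts.SimulationParams(
        n_probes=400,
        n_up=25,
        n_down=25,
        samples_per_group=6,
        rng_seed=11,
    )
    return ts.simulate_multiyear_study(params)


@pytest.fixture
def two_group_matrix() -> tuple[ts.ExpressionMatrix, list[str]]:
    """The hand-checkable one-probe fixture: A={1,2,3}, B={3,4,5}."""
    m = ts.ExpressionMatrix(
        ["p1"], ["a", "b", "c", "d", "e", "f"], np.array([[1, 2, 3, 3, 4, 5]], float)
    )
    return m, ["cool"] * 3 + ["warm"] * 3


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Literal step-up definition: q_i = min_{j: p_j >= p_i} p_j * m / rank_j."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranks = np.empty(m, int)
    ranks[order] = np.arange(1, m + 1)
    q = np.empty(m)
    for i in range(m):
        cand = [min(p[j] * m / ranks[j], 1.0) for j in range(m) if p[j] >= p[i]]
        q[i] = min(cand)
    return q
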