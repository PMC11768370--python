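import numpy as np
import pytest

from metabopk import simulate as sim


def brute_force_dcor(x, y):
    """Independent double-loop implementation of the V-statistic dCor."""
    n = len(x)
    a = [[abs(x[i] - x[j]) for j in range(n)] for i in range(n)]
    b = [[abs(y[i] - y[j]) for j in range(n)] for i in range(n)]

    def center(m):
        rows = [sum(r) / n for r in m]
        cols = [sum(m[i][j] for i in range(n)) / n for j in range(n)]
        grand = sum(rows) / n
        return [
            [m[i][j] - rows[i] - cols[j] + grand for j in range(n)]
            for i in range(n)
        ]

    A, B = center(a), center(b)
    dcov2 = sum(A[i][j] * B[i][j] for i in range(n) for j in range(n)) / n**2
    dvx = sum(A[i][j] ** 2 for i in range(n) for j in range(n)) / n**2
    dvy = sum(B[i][j] ** 2 for i in range(n) for j in range(n)) / n**2
    if dvx <= 0 or dvy <= 0:
        return 0.0
    return (max(dcov2, 0.0) / (dvx * dvy) ** 0.5) ** 0.5


@pytest.fixture(scope="session")
def small_study() -> sim.SimulatedStudy:
    """A compact synthetic study shared by read-only tests."""
    cfg = sim.SimulationConfig(
        seed=5,
        n_features=300,
        n_differential=30,
        n_planted_edges=6,
        n_pathways=10,
    )
    return sim.simulate_study(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
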