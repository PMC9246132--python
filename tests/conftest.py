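"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from poolgrowth import FeedbackParams, PoolConfig


def birth_death_stationary(alpha: float, beta: float, kappa: float, N: int,
                           V: float = 1.0) -> np.ndarray:
    """Independent oracle: stationary eigenvector of the explicit generator.

    Builds the (N+1)-state birth-death generator with up-rates
    kappa (N - n) (1 + n)^-alpha / V and down-rates n^beta (zero at n = 0),
    and solves Q^T pi = 0 with the normalization sum(pi) = 1 by dense linear
    algebra.  Never calls the closed-form distribution it cross-checks.
    """
    up = np.array([kappa * (N - n) * (1.0 + n) ** (-alpha) / V
                   for n in range(N + 1)])
    down = np.array([0.0] + [float(n) ** beta for n in range(1, N + 1)])
    Q = np.zeros((N + 1, N + 1))
    for n in range(N + 1):
        if n < N:
            Q[n, n + 1] = up[n]
        if n > 0:
            Q[n, n - 1] = down[n]
        Q[n, n] = -(up[n] if n < N else 0.0) - (down[n] if n > 0 else 0.0)
    A = Q.T.copy()
    A[-1, :] = 1.0
    b = np.zeros(N + 1)
    b[-1] = 1.0
    return np.linalg.solve(A, b)


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    n = max(p.size, q.size)
    pp = np.zeros(n)
    qq = np.zeros(n)
    pp[: p.size] = p
    qq[: q.size] = q
    return 0.5 * float(np.abs(pp - qq).sum())


@pytest.fixture
def pool50() -> PoolConfig:
    return PoolConfig(N_total=50, V=1.0, M=1)


@pytest.fixture
def pool50_two() -> PoolConfig:
    return PoolConfig(N_total=50, V=1.0, M=2)


def params(alpha: float, beta: float, kappa: float = 1.0) -> FeedbackParams:
    return FeedbackParams.from_kappa(alpha, beta, kappa)
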