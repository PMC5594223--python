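"""Shared fixtures: small stable MVAR processes and synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from eegspect.mvar import MVARModel


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def bivar_var2() -> MVARModel:
    """Stable bivariate VAR(2) with unidirectional coupling 1 -> 2."""
    A = np.zeros((2, 2, 2))
    A[0] = [[0.5, 0.0], [0.3, 0.4]]
    A[1] = [[-0.2, 0.0], [0.0, 0.1]]
    return MVARModel(A, np.eye(2), sfreq=200.0)


@pytest.fixture(scope="session")
def bivar_sim(bivar_var2):
    """A 20k-sample realization of the bivariate VAR(2)."""
    rng = np.random.default_rng(42)
    return bivar_var2.simulate(20000, rng)


def random_stable_model(
    rng: np.random.Generator, m: int = 3, p: int = 2, radius: float = 0.8
) -> MVARModel:
    """Random MVAR model rescaled to a target spectral radius."""
    A = 0.3 * rng.standard_normal((p, m, m))
    model = MVARModel(A, np.eye(m))
    r = model.spectral_radius()
    if r > 0:
        scales = (radius / r) ** np.arange(1, p + 1)
        A = A * scales[:, None, None]
    B = rng.standard_normal((m, m)) * 0.2 + np.eye(m)
    sigma = B @ B.T
    return MVARModel(A, sigma)


def ols_var_fit(x: np.ndarray, p: int) -> np.ndarray:
    """Least-squares lagged-regression oracle for MVAR coefficients."""
    m, n = x.shape
    x = x - x.mean(axis=1, keepdims=True)
    Y = x[:, p:].T
    X = np.hstack([x[:, p - k: n - k].T for k in range(1, p + 1)])
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return B.T.reshape(m, p, m).transpose(1, 0, 2)
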