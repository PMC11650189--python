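import numpy as np
import pytest

import fcgrad as fg


@pytest.fixture(scope="session")
def small_cohort():
    """Null cohort (no planted effect), small enough for fast tests."""
    return fg.gen_cohort(8, 8, n_nodes=60, n_timepoints=120, compression=1.0, seed=7)


@pytest.fixture(scope="session")
def sphere150():
    return fg.gen_sphere(150, seed=11)


@pytest.fixture(scope="session")
def spins150(sphere150):
    return fg.spin_permutations(sphere150, n_perm=300, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_affinity(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random dense symmetric affinity with positive entries, zero diagonal."""
    a = rng.uniform(0.05, 1.0, size=(n, n))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 0.0)
    return a


def dense_embedding_oracle(a: np.ndarray, k: int, alpha: float = 0.5) -> np.ndarray:
    """Independent diffusion-map oracle: explicit transition operator and a
    full nonsymmetric eigendecomposition, normalized so the trivial
    eigenvector is 1 and each component has unit stationary-weighted mean
    square, scaled by lambda/(1-lambda)."""
    d = a.sum(axis=1)
    w = a * np.outer(d**-alpha, d**-alpha)
    dw = w.sum(axis=1)
    p = w / dw[:, None]
    evals, evecs = np.linalg.eig(p)
    evals = np.real(evals)
    evecs = np.real(evecs)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pi = dw / dw.sum()
    comps = []
    for j in range(1, k + 1):
        v = evecs[:, j]
        v = v / np.sqrt(np.sum(pi * v**2))
        comps.append(v * evals[j] / (1.0 - evals[j]))
    return np.column_stack(comps)


def match_signs(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Flip columns of b to match the signs of a (components are
    sign-indeterminate)."""
    out = b.copy()
    for j in range(b.shape[1]):
        if np.dot(a[:, j], b[:, j]) < 0:
            out[:, j] = -out[:, j]
    return out
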