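"""Connectome gradient construction.

Per-subject functional connectivity matrices are sparsified row-wise,
converted to a normalized-angle affinity, and embedded with diffusion maps.
Subject embeddings are harmonized with iterative Procrustes rotation, and
global summaries (range, explained ratio, variance) of the principal
gradient are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh, orthogonal_procrustes
from scipy.sparse.csgraph import connected_components


@dataclass
class ConnectivityMatrix:
    """Node-by-node Pearson correlation matrix with zeroed diagonal."""

    values: np.ndarray
    node_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if not self.node_ids:
            self.node_ids = [str(i + 1) for i in range(v.shape[0])]
        self.values = v

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class AffinityMatrix:
    """Normalized-angle similarity in [0, 1] built from sparsified rows."""

    values: np.ndarray
    density: float


@dataclass
class GradientSet:
    """Embedding components (columns) with eigenvalues and explained ratios.

    ``components[:, 0]`` is the principal gradient. ``explained_ratio`` is
    each retained eigenvalue's share of the full nontrivial positive
    spectrum, so the retained ratios sum to at most 1.
    """

    components: np.ndarray
    eigenvalues: np.ndarray
    explained_ratio: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.components.shape[0]

    @property
    def k(self) -> int:
        return self.components.shape[1]


@dataclass
class GlobalGradientMetrics:
    """Global summaries of one gradient component."""

    range: float
    explained_ratio: float
    variance: float


def fc_matrix(ts: np.ndarray, node_ids: list[str] | None = None) -> ConnectivityMatrix:
    """Pearson correlation across node time series.

    Parameters
    ----------
    ts : array, shape (n_nodes, n_timepoints)
        One row per node. Rows must be non-constant.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[1] < 3:
        raise ValueError("need a 2-D node x time array with >= 3 timepoints")
    sd = ts.std(axis=1)
    bad = np.where(sd == 0)[0]
    if bad.size:
        raise ValueError(f"constant time series at node index {bad[0]}")
    r = np.corrcoef(ts)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(values=r, node_ids=node_ids or [])


def _sparsify_rows(fc: np.ndarray, density: float) -> np.ndarray:
    """Keep the top ``ceil(density*(n-1))`` off-diagonal values per row.

    Ties at the cutoff are all kept, so realized density may slightly
    exceed the nominal value.
    """
    n = fc.shape[0]
    k = int(np.ceil(density * (n - 1)))
    a = fc.copy()
    np.fill_diagonal(a, -np.inf)
    # value of the k-th largest entry per row; keep everything >= it
    kth = np.partition(a, n - k, axis=1)[:, n - k]
    sparse = np.where(a >= kth[:, None], fc, 0.0)
    np.fill_diagonal(sparse, 0.0)
    return sparse


def affinity(fc: ConnectivityMatrix, density: float = 0.10) -> AffinityMatrix:
    """Row-sparsified cosine similarity mapped to normalized angle.

    Each row retains its strongest ``density`` fraction of connections;
    cosine similarity between sparsified rows is then mapped through
    ``1 - arccos(c)/pi`` so affinities live in [0, 1].
    """
    if not 0 < density < 1:
        raise ValueError("density must be in (0, 1)")
    sparse = _sparsify_rows(fc.values, density)
    norms = np.linalg.norm(sparse, axis=1)
    if np.any(norms == 0):
        idx = int(np.where(norms == 0)[0][0])
        raise ValueError(f"row {idx} is all-zero after sparsification")
    cos = (sparse @ sparse.T) / np.outer(norms, norms)
    cos = np.clip(cos, -1.0, 1.0)
    # snap to +-1 where only rounding separates them: arccos amplifies an
    # O(eps) cosine error to O(sqrt(eps)) in the angle
    snap = np.abs(cos) >= 1.0 - 1e-14
    cos = np.where(snap, np.sign(cos), cos)
    ang = 1.0 - np.arccos(cos) / np.pi
    ang = (ang + ang.T) / 2.0
    np.fill_diagonal(ang, 0.0)
    return AffinityMatrix(values=ang, density=density)


def _check_connected(a: np.ndarray) -> None:
    n_comp, _ = connected_components((a > 0).astype(np.int8), directed=False)
    if n_comp > 1:
        raise ValueError(
            "affinity matrix is disconnected; increase the retained density"
        )


def diffusion_embedding(
    aff: AffinityMatrix | np.ndarray,
    k: int = 10,
    alpha: float = 0.5,
    diffusion_time: float = 0.0,
) -> GradientSet:
    """Diffusion map embedding of an affinity matrix.

    The affinity is anisotropically normalized, ``W = D^-a A D^-a``, and the
    spectrum of the transition operator ``P = D_W^-1 W`` is obtained through
    the conjugate symmetric matrix. Components are the nontrivial
    eigenvectors scaled by ``lambda^t``; ``diffusion_time=0`` selects the
    automatic scaling ``lambda / (1 - lambda)``.
    """
    a = aff.values if isinstance(aff, AffinityMatrix) else np.asarray(aff, dtype=float)
    n = a.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of nodes")
    _check_connected(a)

    d = a.sum(axis=1)
    d_alpha = d**-alpha
    w = a * np.outer(d_alpha, d_alpha)
    dw = w.sum(axis=1)
    # symmetric conjugate of the row-stochastic operator
    inv_sqrt = 1.0 / np.sqrt(dw)
    s = w * np.outer(inv_sqrt, inv_sqrt)
    s = (s + s.T) / 2.0
    evals, evecs = eigh(s)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    # right eigenvectors of P, normalized against the stationary vector
    psi = evecs * inv_sqrt[:, None]
    psi = psi / psi[:, :1]

    lam = evals[1 : k + 1]
    if diffusion_time == 0:
        scale = lam / (1.0 - lam)
    else:
        scale = lam**diffusion_time
    components = psi[:, 1 : k + 1] * scale[None, :]

    nontrivial = evals[1:]
    pos = nontrivial[nontrivial > 0]
    explained = np.where(lam > 0, lam, 0.0) / pos.sum()
    return GradientSet(
        components=components, eigenvalues=lam, explained_ratio=explained
    )


def _disparity(gradients: list[np.ndarray], template: np.ndarray) -> float:
    return float(sum(np.sum((g - template) ** 2) for g in gradients))


def procrustes_align(
    subject_gradients: list[GradientSet],
    n_iter: int = 10,
    reference: np.ndarray | None = None,
    tol: float = 1e-8,
) -> tuple[list[GradientSet], np.ndarray]:
    """Harmonize embeddings across subjects with iterative Procrustes rotation.

    Each subject's component matrix is rotated/reflected (orthogonal
    transform, no scaling) towards the current template; the template is the
    component-wise mean, recomputed after each pass. Iteration stops after
    ``n_iter`` passes or when the total disparity change drops below ``tol``.

    Returns the aligned GradientSets and the final template.
    """
    shapes = {g.components.shape for g in subject_gradients}
    if len(shapes) != 1:
        raise ValueError("all subjects must share node count and k")
    mats = [g.components.copy() for g in subject_gradients]
    template = reference.copy() if reference is not None else np.mean(mats, axis=0)

    prev = _disparity(mats, template)
    for _ in range(n_iter):
        for i, m in enumerate(mats):
            rot, _ = orthogonal_procrustes(m, template)
            mats[i] = m @ rot
        if reference is None:
            template = np.mean(mats, axis=0)
        cur = _disparity(mats, template)
        if abs(prev - cur) < tol:
            prev = cur
            break
        prev = cur

    aligned = [
        GradientSet(
            components=m,
            eigenvalues=g.eigenvalues.copy(),
            explained_ratio=g.explained_ratio.copy(),
        )
        for m, g in zip(mats, subject_gradients)
    ]
    return aligned, template


def orient_principal(
    gradients: list[GradientSet], reference_nodes: np.ndarray
) -> list[GradientSet]:
    """Flip gradient 1 of every subject so its mean over ``reference_nodes``
    (typically the DMN) is positive — the primary-to-transmodal orientation."""
    mean_g1 = np.mean([g.components[:, 0] for g in gradients], axis=0)
    if mean_g1[reference_nodes].mean() < 0:
        for g in gradients:
            g.components[:, 0] = -g.components[:, 0]
    return gradients


def global_metrics(g: GradientSet, component: int = 1) -> GlobalGradientMetrics:
    """Range, explained ratio and population variance of one component (1-based)."""
    if not 1 <= component <= g.k:
        raise ValueError("component out of range")
    scores = g.components[:, component - 1]
    return GlobalGradientMetrics(
        range=float(scores.max() - scores.min()),
        explained_ratio=float(g.explained_ratio[component - 1]),
        variance=float(scores.var()),
    )
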