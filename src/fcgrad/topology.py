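"""Small-world network topology over a sparsity range.

Binarized graphs at each sparsity are compared with degree-preserving
rewired references to produce normalized clustering (gamma), normalized
characteristic path length (lambda) and small-worldness (sigma = gamma /
lambda), summarized as areas under the sparsity curve (aGamma, aLambda,
aSigma). aGamma indexes segregation, aLambda integration, and aSigma their
balance.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .gradients import ConnectivityMatrix, GlobalGradientMetrics
from .groupstats import fdr_bh

DEFAULT_SPARSITIES = tuple(np.round(np.arange(0.05, 0.501, 0.05), 2))


@dataclass
class TopologyCurve:
    sparsities: np.ndarray
    gamma: np.ndarray
    lam: np.ndarray
    sigma: np.ndarray
    a_gamma: float
    a_lambda: float
    a_sigma: float


def binarize_at_sparsity(fc: ConnectivityMatrix | np.ndarray, s: float) -> nx.Graph:
    """Unweighted graph keeping the strongest ``s`` fraction of edges.

    Ties at the cutoff are all kept, so realized density may exceed ``s``.
    """
    if not 0 < s < 1:
        raise ValueError("sparsity must be in (0, 1)")
    v = fc.values if isinstance(fc, ConnectivityMatrix) else np.asarray(fc, dtype=float)
    n = v.shape[0]
    iu = np.triu_indices(n, k=1)
    w = v[iu]
    k = int(round(s * w.size))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    if k > 0:
        cutoff = np.partition(w, w.size - k)[w.size - k]
        keep = w >= cutoff
        g.add_edges_from(zip(iu[0][keep], iu[1][keep]))
    return g


def graph_metrics(g: nx.Graph) -> tuple[float, float]:
    """Mean clustering coefficient and characteristic path length.

    C averages per-node triangle density (0 for degree < 2); L is the mean
    BFS shortest-path length over connected pairs, computed on the largest
    connected component when the graph is disconnected.
    """
    n = g.number_of_nodes()
    if n < 3:
        raise ValueError("need at least 3 nodes")
    a = nx.to_scipy_sparse_array(g, dtype=np.int8, format="csr")
    deg = np.asarray(a.sum(axis=1)).ravel()
    # triangles per node = diag(A^3)/2, via (A @ A) rows
    a2 = (a @ a).toarray()
    tri = (a2 * a.toarray()).sum(axis=1) / 2.0
    pairs = deg * (deg - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = float(np.mean(np.where(pairs > 0, tri / np.where(pairs > 0, pairs, 1), 0.0)))
    if g.number_of_edges() == 0:
        return c, float("nan")

    from scipy.sparse.csgraph import connected_components as cc
    from scipy.sparse.csgraph import shortest_path

    n_comp, labels = cc(a, directed=False)
    if n_comp > 1:
        counts = np.bincount(labels)
        keep = np.where(labels == np.argmax(counts))[0]
        if keep.size < 2:
            return c, float("nan")
        a = a[np.ix_(keep, keep)].tocsr()
    d = shortest_path(a, method="D", directed=False, unweighted=True)
    m = a.shape[0]
    off = ~np.eye(m, dtype=bool)
    l = float(d[off].mean())
    return c, l


def random_reference(g: nx.Graph, n_swaps: int | None = None, seed: int = 0) -> nx.Graph:
    """Degree-preserving Maslov-Sneppen rewiring (double-edge swaps).

    ``n_swaps`` counts swap *attempts* (default 10x the edge count).
    Operates on a flat edge list with a hash-set membership check, so large
    swap budgets stay cheap. Attempts that would create self-loops or
    multi-edges are skipped; the degree sequence is preserved regardless.
    """
    m = g.number_of_edges()
    if n_swaps is None:
        n_swaps = 10 * m
    if n_swaps == 0 or m < 2:
        return g.copy()
    rng = np.random.default_rng(seed)
    edges = [tuple(e) for e in g.edges]
    edge_set = {frozenset(e) for e in edges}
    draws = rng.integers(0, m, size=2 * n_swaps)
    flips = rng.random(size=n_swaps) < 0.5
    for t in range(n_swaps):
        i, j = draws[2 * t], draws[2 * t + 1]
        if i == j:
            continue
        u, v = edges[i]
        x, y = edges[j]
        if flips[t]:
            x, y = y, x
        # propose (u, x) and (v, y)
        if len({u, v, x, y}) < 4:
            continue
        e1, e2 = frozenset((u, x)), frozenset((v, y))
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard(frozenset((u, v)))
        edge_set.discard(frozenset((x, y)))
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i] = (u, x)
        edges[j] = (v, y)
    r = nx.Graph()
    r.add_nodes_from(g.nodes)
    r.add_edges_from(edges)
    return r


def trapezoid_auc(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.trapezoid(y, x))


def small_world_curve(
    fc: ConnectivityMatrix | np.ndarray,
    sparsities: tuple[float, ...] = DEFAULT_SPARSITIES,
    n_rand: int = 20,
    seed: int = 0,
) -> TopologyCurve:
    """gamma/lambda/sigma at each sparsity with AUC summaries.

    Normalization uses ``n_rand`` degree-matched rewired graphs per sparsity.
    """
    rng = np.random.default_rng(seed)
    gammas, lambdas = [], []
    for s in sparsities:
        g = binarize_at_sparsity(fc, s)
        c, l = graph_metrics(g)
        c_rand, l_rand = [], []
        for _ in range(n_rand):
            r = random_reference(g, seed=int(rng.integers(2**31 - 1)))
            cr, lr = graph_metrics(r)
            c_rand.append(cr)
            l_rand.append(lr)
        gammas.append(c / np.mean(c_rand) if np.mean(c_rand) > 0 else np.nan)
        lambdas.append(l / np.nanmean(l_rand))
    sp = np.asarray(sparsities, dtype=float)
    gamma = np.asarray(gammas)
    lam = np.asarray(lambdas)
    sigma = gamma / lam
    return TopologyCurve(
        sparsities=sp, gamma=gamma, lam=lam, sigma=sigma,
        a_gamma=trapezoid_auc(sp, gamma),
        a_lambda=trapezoid_auc(sp, lam),
        a_sigma=trapezoid_auc(sp, sigma),
    )


def gradient_topology_corr(
    metrics: list[GlobalGradientMetrics],
    curves: list[TopologyCurve],
    q: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlations between global gradient metrics and topology AUCs,
    with BH-FDR across the table."""
    from scipy.stats import pearsonr

    if len(metrics) != len(curves) or len(metrics) < 3:
        raise ValueError("need >= 3 paired subjects")
    glob = {
        "range": np.array([m.range for m in metrics]),
        "explained_ratio": np.array([m.explained_ratio for m in metrics]),
        "variance": np.array([m.variance for m in metrics]),
    }
    aucs = {
        "aGamma": np.array([c.a_gamma for c in curves]),
        "aLambda": np.array([c.a_lambda for c in curves]),
        "aSigma": np.array([c.a_sigma for c in curves]),
    }
    rows = []
    for gname, gvals in glob.items():
        for aname, avals in aucs.items():
            if gvals.std() == 0 or avals.std() == 0:
                raise ValueError(f"zero variance in {gname} or {aname}")
            r, p = pearsonr(gvals, avals)
            rows.append({"gradient_metric": gname, "topology_metric": aname,
                         "r": r, "p": p})
    df = pd.DataFrame(rows)
    df["sig_fdr"] = fdr_bh(df["p"].to_numpy(), q=q)
    return df
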