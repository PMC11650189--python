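"""Covariate-adjusted group inference on gradient maps.

Per-node general linear models with age and sex covariates, effect sizes,
Benjamini-Hochberg FDR, permutation-based cluster-extent correction,
clinical correlations, paired tests and network-wise shares of significant
nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthdata import NetworkPartition, SubjectRecord


@dataclass
class GroupStatMap:
    t: np.ndarray
    z: np.ndarray
    p: np.ndarray
    d: np.ndarray
    df: int
    contrast: str = "case-control"


@dataclass
class ClusterResult:
    cluster_id: int
    nodes: np.ndarray
    extent: int
    cluster_p: float


def _design(subjects: list[SubjectRecord], interaction: bool = False) -> np.ndarray:
    group = np.array([1.0 if s.group == "case" else 0.0 for s in subjects])
    age = np.array([s.age for s in subjects])
    sex = np.array([1.0 if s.sex == "M" else 0.0 for s in subjects])
    cols = [np.ones(len(subjects)), group, age - age.mean(), sex]
    if interaction:
        cols.append(group * (sex - sex.mean()))
    return np.column_stack(cols)


def _ols_t(x: np.ndarray, y: np.ndarray, col: int) -> tuple[np.ndarray, np.ndarray, int]:
    """t statistic and two-sided p for one design column, vectorized over
    the columns of y (subjects x nodes)."""
    n, p = x.shape
    if np.linalg.matrix_rank(x) < p:
        raise ValueError("rank-deficient design (collinear covariates)")
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    df = n - p
    sigma2 = np.sum(resid**2, axis=0) / df
    # guard exact fits: rounding noise in an all-zero residual must not
    # manufacture a finite t statistic
    scale = np.mean(y**2, axis=0)
    degenerate = sigma2 <= 1e-24 * np.maximum(scale, 1.0)
    se = np.sqrt(sigma2 * xtx_inv[col, col])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[col] / np.where(se > 0, se, 1.0), 0.0)
    t = np.where(degenerate, 0.0, t)
    pval = 2.0 * stats.t.sf(np.abs(t), df)
    return t, pval, df


def _t_to_z(t: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Signed normal quantile of the two-sided t p-value."""
    z = stats.norm.isf(np.clip(p / 2.0, 1e-300, 1.0))
    return np.sign(t) * z


def glm_compare(
    y: np.ndarray,
    subjects: list[SubjectRecord],
    contrast: str = "case-control",
) -> GroupStatMap:
    """Per-node OLS of y on [intercept, group, age, sex]; group-coefficient t.

    Cohen's d is the covariate-adjusted ``t * sqrt(1/n1 + 1/n2)``.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n1 = sum(1 for s in subjects if s.group == "case")
    n2 = sum(1 for s in subjects if s.group == "control")
    if n1 < 3 or n2 < 3:
        raise ValueError("both groups need at least 3 subjects")
    x = _design(subjects)
    t, p, df = _ols_t(x, y, col=1)
    d = t * np.sqrt(1.0 / n1 + 1.0 / n2)
    return GroupStatMap(t=t, z=_t_to_z(t, p), p=p, d=d, df=df, contrast=contrast)


def interaction_test(y: np.ndarray, subjects: list[SubjectRecord]) -> np.ndarray:
    """Per-node p-value for a sex-by-group interaction term."""
    y = np.atleast_2d(np.asarray(y, dtype=float))
    sexes = {s.sex for s in subjects}
    if len(sexes) < 2:
        raise ValueError("sex-by-group interaction inestimable in a single-sex cohort")
    x = _design(subjects, interaction=True)
    _, p, _ = _ols_t(x, y, col=4)
    return p


def fdr_bh(p: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    mask, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")[:4]
    return mask


def _components(nodes: np.ndarray, adjacency: np.ndarray) -> list[np.ndarray]:
    """Connected components of the subgraph induced by ``nodes``."""
    from scipy.sparse.csgraph import connected_components as cc

    if nodes.size == 0:
        return []
    sub = adjacency[np.ix_(nodes, nodes)]
    n_comp, labels = cc((sub > 0).astype(np.int8), directed=False)
    return [nodes[labels == c] for c in range(n_comp)]


def _max_extent(t: np.ndarray, p: np.ndarray, voxel_p: float, adjacency: np.ndarray) -> int:
    supra = np.where(p < voxel_p)[0]
    comps = _components(supra, adjacency)
    return max((len(c) for c in comps), default=0)


def cluster_correct(
    stat: GroupStatMap,
    y: np.ndarray,
    subjects: list[SubjectRecord],
    adjacency: np.ndarray,
    voxel_p: float = 0.001,
    n_perm: int = 1000,
    seed: int = 0,
    strict: bool = True,
) -> list[ClusterResult]:
    """Cluster-extent inference by group-label permutation.

    Supra-threshold (``p < voxel_p``) connected components are compared to a
    null distribution of maximum cluster extents obtained by permuting group
    labels and refitting the GLM.
    """
    if n_perm < 100 and strict:
        raise ValueError("n_perm < 100 is unreliable; pass strict=False to override")
    adjacency = np.asarray(adjacency)
    if adjacency.shape[0] != stat.p.size:
        raise ValueError("adjacency must cover all nodes")
    y = np.atleast_2d(np.asarray(y, dtype=float))
    supra = np.where(stat.p < voxel_p)[0]
    comps = _components(supra, adjacency)
    if not comps:
        return []

    rng = np.random.default_rng(seed)
    groups = [s.group for s in subjects]
    null_max = np.empty(n_perm)
    perm_subjects = [
        SubjectRecord(id=s.id, group=s.group, age=s.age, sex=s.sex, fd=s.fd)
        for s in subjects
    ]
    for i in range(n_perm):
        perm = rng.permutation(len(groups))
        for s, j in zip(perm_subjects, perm):
            s.group = groups[j]
        pstat = glm_compare(y, perm_subjects)
        null_max[i] = _max_extent(pstat.t, pstat.p, voxel_p, adjacency)

    results = []
    for cid, comp in enumerate(sorted(comps, key=len, reverse=True), start=1):
        cp = (1.0 + np.sum(null_max >= len(comp))) / (1.0 + n_perm)
        results.append(
            ClusterResult(cluster_id=cid, nodes=comp, extent=len(comp), cluster_p=float(cp))
        )
    return results


def clinical_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with two-sided p over pairwise-complete values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 paired non-missing values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def paired_ttest(pre: np.ndarray, post: np.ndarray) -> tuple[float, float, float]:
    """Classical paired t test; d = mean(diff) / sd(diff)."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.size != post.size or pre.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    diff = pre - post
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.allclose(diff, 0):
            return 0.0, 1.0, 0.0
        raise ValueError("zero-variance nonzero differences")
    t, p = stats.ttest_rel(pre, post)
    return float(t), float(p), float(diff.mean() / sd)


def network_share(
    mask: np.ndarray,
    signs: np.ndarray,
    partition: NetworkPartition,
) -> dict[str, dict[str, float]]:
    """Per-network proportion of significant nodes, separately by sign.

    Returns ``{"increase": {net: frac}, "decrease": {net: frac}}``; each
    sign's proportions sum to 1 (all zero, with an ``empty`` flag, when no
    node is significant for that sign).
    """
    mask = np.asarray(mask, dtype=bool)
    signs = np.asarray(signs, dtype=float)
    if len(partition.labels) != mask.size:
        raise ValueError("partition must label every node")
    labels = np.asarray(partition.labels)
    out: dict[str, dict[str, float]] = {}
    for name, sel in (("increase", signs > 0), ("decrease", signs < 0)):
        sig = mask & sel
        total = sig.sum()
        shares = {
            net: (float(np.sum(sig & (labels == net)) / total) if total else 0.0)
            for net in sorted(set(partition.labels))
        }
        shares["_empty"] = 0.0 if total else 1.0
        out[name] = shares
    return out
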