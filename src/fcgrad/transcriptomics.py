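"""PLS regression linking regional gene expression to a case-control z map.

The first PLS component (PLS1) summarizes the expression pattern most
covarying with the spatial map of group differences. Component significance
is assessed against spin-permuted maps; gene weights are ranked by bootstrap
Z (weight / bootstrap SE) and selected by BH-FDR into PLS1+ / PLS1- lists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

from .groupstats import fdr_bh
from .spatial import SpinPermutationSet
from .synthdata import ExpressionMatrix


@dataclass
class PLSModel:
    scores: np.ndarray  # (n_regions, n_components)
    x_weights: np.ndarray  # (n_genes, n_components)
    covar_explained: np.ndarray  # per-component fraction of y variance
    y: np.ndarray
    gene_ids: list[str]


def _as_xy(x: ExpressionMatrix | np.ndarray, zscore: bool = True):
    if isinstance(x, ExpressionMatrix):
        values, gene_ids = x.values, list(x.gene_ids)
    else:
        values = np.asarray(x, dtype=float)
        gene_ids = [f"G{i + 1:05d}" for i in range(values.shape[1])]
    if zscore:
        mu = values.mean(axis=0)
        sd = values.std(axis=0)
        sd[sd == 0] = 1.0
        values = (values - mu) / sd
    return values, gene_ids


def _explained_y_variance(scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-component fraction of y variance carried by each score vector
    (squared correlation with y, components being the PLS ordering)."""
    out = []
    yc = y - y.mean()
    for j in range(scores.shape[1]):
        t = scores[:, j] - scores[:, j].mean()
        denom = np.sqrt((t**2).sum() * (yc**2).sum())
        out.append(float((t @ yc) ** 2 / denom**2) if denom > 0 else 0.0)
    return np.asarray(out)


def pls_fit(
    x: ExpressionMatrix | np.ndarray,
    y: np.ndarray,
    n_components: int = 2,
    zscore: bool = True,
) -> PLSModel:
    """PLS regression of the spatial map ``y`` on gene expression ``x``.

    PLS1 scores are sign-flipped when needed so corr(scores_1, y) >= 0.
    """
    values, gene_ids = _as_xy(x, zscore=zscore)
    y = np.asarray(y, dtype=float)
    if values.shape[0] != y.size:
        raise ValueError("region count of X must match length of y")
    if y.std() == 0:
        raise ValueError("constant y map")
    if n_components > values.shape[0] - 2:
        raise ValueError("too many components for the number of regions")
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(values, (y - y.mean()) / y.std())
    scores = pls.x_scores_.copy()
    weights = pls.x_weights_.copy()
    for j in range(n_components):
        if np.corrcoef(scores[:, j], y)[0, 1] < 0:
            scores[:, j] = -scores[:, j]
            weights[:, j] = -weights[:, j]
    return PLSModel(
        scores=scores,
        x_weights=weights,
        covar_explained=_explained_y_variance(scores, y),
        y=y.copy(),
        gene_ids=gene_ids,
    )


def pls_significance(
    x: ExpressionMatrix | np.ndarray,
    y: np.ndarray,
    spins: SpinPermutationSet,
    n_components: int = 1,
    zscore: bool = True,
) -> np.ndarray:
    """Spin-permutation p per component for the explained y variance."""
    if spins.n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    values, _ = _as_xy(x, zscore=zscore)
    y = np.asarray(y, dtype=float)
    if spins.n_parcels != y.size:
        raise ValueError("spin set does not match region count")
    obs = pls_fit(values, y, n_components=n_components, zscore=False).covar_explained
    counts = np.zeros(n_components)
    for i in range(spins.n_perm):
        y_null = y[spins.assignments[i]]
        if y_null.std() == 0:
            continue
        null = pls_fit(values, y_null, n_components=n_components, zscore=False).covar_explained
        counts += null >= obs
    return (1.0 + counts) / (1.0 + spins.n_perm)


def bootstrap_weights(
    x: ExpressionMatrix | np.ndarray,
    y: np.ndarray,
    n_boot: int = 10000,
    seed: int = 0,
    q: float = 0.05,
    zscore: bool = True,
) -> pd.DataFrame:
    """Bootstrap the PLS1 gene weights and rank genes by Z = weight / SE.

    Regions are resampled with replacement; each refit component is
    sign-aligned to the original weights by dot product (PLS components are
    sign-indeterminate, and unaligned bootstraps inflate the SE). Gene-level
    two-sided normal p-values on Z are BH-FDR corrected and genes partitioned
    into PLS1+ (Z > 0, significant), PLS1- (Z < 0, significant) and none.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    values, gene_ids = _as_xy(x, zscore=zscore)
    y = np.asarray(y, dtype=float)
    model = pls_fit(values, y, n_components=1, zscore=False)
    w0 = model.x_weights[:, 0]
    n_regions = values.shape[0]
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, w0.size))
    kept = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n_regions, size=n_regions)
        if np.unique(idx).size < 3 or y[idx].std() == 0:
            continue  # degenerate draw
        bw = pls_fit(values[idx], y[idx], n_components=1, zscore=False).x_weights[:, 0]
        if bw @ w0 < 0:
            bw = -bw
        boots[kept] = bw
        kept += 1
    se = boots[:kept].std(axis=0, ddof=1)
    se_safe = np.where(se > 0, se, np.inf)
    z = w0 / se_safe
    p = 2.0 * stats.norm.sf(np.abs(z))
    from statsmodels.stats.multitest import multipletests

    sig, fdr_p, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    membership = np.where(
        sig & (z > 0), "PLS1+", np.where(sig & (z < 0), "PLS1-", "none")
    )
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "weight": w0,
            "bootstrap_se": se,
            "Z": z,
            "p": p,
            "fdr_p": fdr_p,
            "fdr_sig": sig,
            "list_membership": membership,
        }
    )


def rank_genes(table: pd.DataFrame) -> list[str]:
    """Gene ids ordered by descending Z, ties broken lexicographically."""
    if table.empty:
        return []
    df = table.sort_values(["Z", "gene_id"], ascending=[False, True], kind="stable")
    return df["gene_id"].tolist()
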