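"""Gene-set enrichment of PLS-weighted gene lists.

Two permutation-based overlap tests (mean PLS-Z of shared genes for disorder
sets; overlap count for cell-type markers) and a preranked, weighted
Kolmogorov-Smirnov GSEA for cortical-layer markers. Gene ids are harmonized
case-insensitively by exact match; no alias resolution is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .groupstats import fdr_bh
from .synthdata import GeneSetCollection


@dataclass
class OverlapTestResult:
    set_name: str
    n_overlap: int
    statistic: float  # mean PLS-Z of shared genes, or overlap count
    p_perm: float
    empty: bool = False


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    p_perm: float


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "") -> None:
    lines = [
        "\t".join([name, description, *members]) for name, members in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def _norm(genes) -> list[str]:
    return [str(g).upper() for g in genes]


def overlap_perm_test(
    pls_genes: list[str],
    target_set: list[str],
    background: list[str],
    pls_z: dict[str, float],
    n_perm: int = 10000,
    seed: int = 0,
    side: str = "greater",
) -> OverlapTestResult:
    """Mean PLS-Z of genes shared between a PLS list and a target set.

    The observed statistic is the mean Z over the shared genes; the null
    draws gene sets of the same size from the background and recomputes the
    mean Z. The one-sided p is add-one smoothed.
    """
    bg = _norm(background)
    target = [g for g in _norm(target_set) if g in set(bg)]
    if len(bg) <= len(target):
        raise ValueError("background barely exceeds the target set (degenerate null)")
    if not target:
        raise ValueError("target set has no genes in the background")
    pls = set(_norm(pls_genes))
    if not pls & set(bg):
        raise ValueError("gene list disjoint from background")
    zmap = {str(k).upper(): v for k, v in pls_z.items()}

    shared = sorted(pls & set(target))
    if not shared:
        return OverlapTestResult(set_name="", n_overlap=0, statistic=float("nan"),
                                 p_perm=1.0, empty=True)
    obs = float(np.mean([zmap[g] for g in shared]))

    rng = np.random.default_rng(seed)
    z_bg = np.array([zmap[g] for g in bg])
    null = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(z_bg.size, size=len(shared), replace=False)
        null[i] = z_bg[idx].mean()
    count = np.sum(null >= obs) if side == "greater" else np.sum(null <= obs)
    p = (1.0 + count) / (1.0 + n_perm)
    return OverlapTestResult(set_name="", n_overlap=len(shared),
                             statistic=obs, p_perm=float(p))


def marker_overlap_test(
    gene_list: list[str],
    marker_sets: GeneSetCollection,
    n_perm: int = 10000,
    seed: int = 0,
    q: float = 0.05,
) -> pd.DataFrame:
    """Overlap counts of a gene list with marker sets, permutation p per set.

    The null resamples gene lists of equal size from the background; FDR is
    applied across the marker sets.
    """
    bg = _norm(marker_sets.background)
    bg_set = set(bg)
    genes = [g for g in _norm(gene_list) if g in bg_set]
    if not genes:
        raise ValueError("gene list disjoint from background")
    rng = np.random.default_rng(seed)
    bg_arr = np.array(bg)

    marker_norm = {name: set(_norm(m)) & bg_set for name, m in marker_sets.sets.items()}
    obs = {name: len(set(genes) & m) for name, m in marker_norm.items()}
    counts = {name: 0 for name in marker_norm}
    for _ in range(n_perm):
        draw = set(rng.choice(bg_arr, size=len(genes), replace=False))
        for name, m in marker_norm.items():
            if len(draw & m) >= obs[name]:
                counts[name] += 1
    rows = []
    for name in sorted(marker_norm):
        p = (1.0 + counts[name]) / (1.0 + n_perm)
        rows.append({"set_name": name, "n_overlap": obs[name], "p_perm": p})
    df = pd.DataFrame(rows)
    df["fdr_sig"] = fdr_bh(df["p_perm"].to_numpy(), q=q)
    return df


def enrichment_score(
    ranked_genes: list[str],
    scores: np.ndarray,
    target_set: set[str],
    weight_p: float = 1.0,
) -> float:
    """Weighted Kolmogorov-Smirnov running-sum enrichment score.

    Hits increment proportionally to |score|^weight_p, misses decrement
    uniformly; the ES is the running-sum extremum of largest magnitude.
    """
    hits = np.array([g in target_set for g in ranked_genes])
    if not hits.any():
        raise ValueError("target set has no genes in the ranking")
    w = np.abs(np.asarray(scores, dtype=float)) ** weight_p
    hit_w = np.where(hits, w, 0.0)
    denom_hit = hit_w.sum()
    if denom_hit == 0:  # all hit scores zero; fall back to uniform increments
        hit_w = hits.astype(float)
        denom_hit = hit_w.sum()
    n_miss = (~hits).sum()
    step = hit_w / denom_hit - (~hits) / n_miss
    running = np.cumsum(step)
    return float(running[np.argmax(np.abs(running))])


def gsea(
    ranked_genes: list[str],
    scores: np.ndarray,
    target_set: list[str],
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
) -> GseaResult:
    """Preranked GSEA with gene-label permutation.

    NES = ES / mean(|null ES| of matching sign); p is the add-one proportion
    of same-sign null ES at least as extreme as the observed.
    """
    genes = _norm(ranked_genes)
    target = set(_norm(target_set)) & set(genes)
    if len(target) < 3:
        raise ValueError("need >= 3 target genes present in the ranking")
    scores = np.asarray(scores, dtype=float)
    es = enrichment_score(genes, scores, target, weight_p)

    rng = np.random.default_rng(seed)
    arr = np.array(genes)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(len(arr))
        null[i] = enrichment_score(list(arr[perm]), scores, target, weight_p)
    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    denom = np.mean(np.abs(same_sign)) if same_sign.size else np.mean(np.abs(null))
    nes = es / denom if denom > 0 else 0.0
    count = np.sum(np.abs(same_sign) >= abs(es)) if same_sign.size else 0
    p = (1.0 + count) / (1.0 + (same_sign.size if same_sign.size else n_perm))
    return GseaResult(set_name="", es=es, nes=float(nes), p_perm=float(p))
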