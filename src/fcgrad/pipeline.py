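"""End-to-end pipeline driver.

Runs the full analysis order — cohort simulation (or loading), per-subject
gradients, group statistics, network topology, term-map decoding, PLS
transcriptomics, enrichment, and treatment-outcome prediction — writing every
artifact plus a manifest (config echo + SHA-256 of every output) to a run
directory. Deterministic given the config seed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .gradients import (
    affinity,
    diffusion_embedding,
    fc_matrix,
    global_metrics,
    orient_principal,
    procrustes_align,
)
from .groupstats import cluster_correct, fdr_bh, glm_compare, network_share, paired_ttest
from .prediction import network_weight_share, permutation_validate, svr_loocv
from .spatial import decode, smooth_sphere_map, spin_corr, spin_permutations
from .synthdata import SyntheticCohort, gen_cohort, gen_expression, gen_outcomes
from .topology import gradient_topology_corr, small_world_curve
from .transcriptomics import bootstrap_weights, pls_fit, pls_significance


def sphere_adjacency(centroids: np.ndarray, n_neighbors: int = 6) -> np.ndarray:
    """Symmetric k-nearest-neighbor adjacency over parcel centroids."""
    from scipy.spatial.distance import cdist

    d = cdist(centroids, centroids)
    np.fill_diagonal(d, np.inf)
    n = centroids.shape[0]
    adj = np.zeros((n, n), dtype=np.int8)
    nearest = np.argsort(d, axis=1)[:, :n_neighbors]
    for i in range(n):
        adj[i, nearest[i]] = 1
    return np.maximum(adj, adj.T)


def subject_gradients(
    cohort: SyntheticCohort, density: float = 0.10, alpha: float = 0.5, k: int = 5
) -> tuple[list[str], np.ndarray, list]:
    """Per-subject aligned gradients: ids, subjects x nodes g1 matrix, GradientSets.

    Subjects are Procrustes-aligned to a group template computed from the
    group-mean connectivity matrix.
    """
    from .gradients import ConnectivityMatrix

    baseline = [s for s in cohort.subjects if s.timepoint == "baseline"]
    ids = [s.id for s in baseline]
    fcs = {sid: fc_matrix(cohort.timeseries[sid]).values for sid in ids}
    mean_fc = np.mean(list(fcs.values()), axis=0)
    np.fill_diagonal(mean_fc, 0.0)
    template = diffusion_embedding(
        affinity(ConnectivityMatrix(mean_fc), density=density), k=k, alpha=alpha
    )
    grads = [
        diffusion_embedding(
            affinity(ConnectivityMatrix(fcs[sid]), density=density), k=k, alpha=alpha
        )
        for sid in ids
    ]
    aligned, _ = procrustes_align(grads, reference=template.components)
    dmn_nodes = cohort.partition.indices("DMN")
    aligned = orient_principal(aligned, dmn_nodes)
    g1 = np.array([g.components[:, 0] for g in aligned])
    return ids, g1, aligned


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: fio.PipelineConfig, out_dir: str | Path) -> Path:
    """Execute the full analysis on a seeded synthetic cohort.

    Returns the run directory; every output is listed in ``manifest.json``
    with its SHA-256, so reruns with the same config are byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- simulate -------------------------------------------------------
    cohort = gen_cohort(
        n_case=config.n_case, n_control=config.n_control, n_nodes=config.n_nodes,
        n_timepoints=config.n_timepoints, compression=config.compression,
        seed=config.seed,
    )
    fio.write_cohort(cohort, out / "cohort")

    # --- gradients ------------------------------------------------------
    ids, g1, aligned = subject_gradients(
        cohort, density=config.density, alpha=config.alpha, k=config.k
    )
    baseline = [s for s in cohort.subjects if s.timepoint == "baseline"]
    (out / "gradients").mkdir(exist_ok=True)
    for sid, g in zip(ids, aligned):
        fio.write_gradients(g, out / "gradients" / f"{sid}.tsv")

    # --- group statistics -----------------------------------------------
    stat = glm_compare(g1, baseline)
    sig = fdr_bh(stat.p, q=config.q)
    adjacency = sphere_adjacency(cohort.sphere.centroids[: config.n_nodes])
    clusters = cluster_correct(
        stat, g1, baseline, adjacency, voxel_p=config.voxel_p,
        n_perm=config.n_perm, seed=config.seed + 1,
    )
    cluster_id = np.zeros(config.n_nodes, dtype=int)
    for c in clusters:
        if c.cluster_p < 0.05:
            cluster_id[c.nodes] = c.cluster_id
    fio.write_statmap(stat, out / "statmap.tsv", sig_fdr=sig, cluster_id=cluster_id)
    shares = network_share(sig, np.sign(stat.t), cohort.partition)

    # global gradient metrics, case vs control
    metrics = [global_metrics(g) for g in aligned]
    glob = pd.DataFrame(
        {
            "id": ids,
            "group": [s.group for s in baseline],
            "range": [m.range for m in metrics],
            "explained_ratio": [m.explained_ratio for m in metrics],
            "variance": [m.variance for m in metrics],
        }
    )
    glob.to_csv(out / "global_metrics.csv", index=False, float_format="%.10g")
    global_stats = {}
    for col in ("range", "explained_ratio", "variance"):
        s = glm_compare(glob[col].to_numpy()[:, None], baseline)
        global_stats[col] = {"t": float(s.t[0]), "p": float(s.p[0]), "d": float(s.d[0])}

    # --- topology ---------------------------------------------------------
    curves = [
        small_world_curve(
            fc_matrix(cohort.timeseries[sid]), sparsities=config.sparsities,
            n_rand=config.n_rand, seed=config.seed + 10 + i,
        )
        for i, sid in enumerate(ids)
    ]
    aucs = pd.DataFrame(
        {
            "id": ids,
            "aGamma": [c.a_gamma for c in curves],
            "aLambda": [c.a_lambda for c in curves],
            "aSigma": [c.a_sigma for c in curves],
        }
    )
    aucs.to_csv(out / "topology_auc.csv", index=False, float_format="%.10g")
    case_idx = [i for i, s in enumerate(baseline) if s.group == "case"]
    corr_table = gradient_topology_corr(
        [metrics[i] for i in case_idx], [curves[i] for i in case_idx], q=config.q
    )
    corr_table.to_csv(out / "gradient_topology_corr.csv", index=False, float_format="%.10g")

    # --- spatial nulls + decoding ----------------------------------------
    sphere = cohort.sphere
    spins = spin_permutations(sphere, n_perm=config.n_perm, seed=config.seed + 2)
    term_rng = np.random.default_rng(config.seed + 3)
    term_maps = pd.DataFrame(
        {f"term{i + 1:02d}": smooth_sphere_map(sphere, term_rng)[: config.n_nodes]
         for i in range(10)}
    ).T
    decoded = decode(stat.z, term_maps, spins, q=config.q)
    decoded.to_csv(out / "decoder.csv", index=False, float_format="%.10g")

    # --- transcriptomics --------------------------------------------------
    expr, assoc = gen_expression(
        stat.z, n_genes=config.n_genes, n_assoc=config.n_assoc,
        coupling=config.coupling, seed=config.seed + 4, noise_sd=config.expr_noise_sd,
    )
    fio.write_expression(expr, out / "expression.tsv")
    model = pls_fit(expr, stat.z, n_components=2)
    p_spin_pls = pls_significance(expr, stat.z, spins, n_components=1)
    r_pls, p_pls_map = spin_corr(model.scores[:, 0], stat.z, spins)
    genes = bootstrap_weights(expr, stat.z, n_boot=config.n_boot, seed=config.seed + 5)
    genes.to_csv(out / "gene_weights.csv", index=False, float_format="%.10g")

    # --- enrichment -------------------------------------------------------
    from .enrichment import gsea, marker_overlap_test
    from .synthdata import gen_gene_sets

    markers = gen_gene_sets(
        assoc, expr.gene_ids, overlap_frac=0.8,
        set_sizes={f"celltype{i + 1}": 25 for i in range(7)}, seed=config.seed + 6,
    )
    pls1_minus = genes.loc[genes.list_membership == "PLS1-", "gene_id"].tolist()
    pls1_plus = genes.loc[genes.list_membership == "PLS1+", "gene_id"].tolist()
    marker_res = marker_overlap_test(
        pls1_plus or genes["gene_id"].tolist()[:20], markers,
        n_perm=config.n_perm, seed=config.seed + 7,
    )
    marker_res.to_csv(out / "marker_overlap.csv", index=False, float_format="%.10g")
    from .transcriptomics import rank_genes

    ranked = rank_genes(genes)
    z_by_gene = dict(zip(genes["gene_id"], genes["Z"]))
    scores = np.array([z_by_gene[g] for g in ranked])
    layer_set = markers.sets["celltype1"]
    gsea_res = gsea(ranked, scores, layer_set, n_perm=config.n_perm, seed=config.seed + 8)

    # --- treatment prediction --------------------------------------------
    dmn = cohort.partition.indices("DMN")
    true_w = np.zeros(config.n_nodes)
    true_w[dmn] = 200.0  # sized so the planted response sd ~ 2x the baseline score spread
    id_to_row = {sid: i for i, sid in enumerate(ids)}
    treated_ids = [s.id for s in baseline if s.group == "case"][: config.n_treated]
    feat = g1[[id_to_row[t] for t in treated_ids]]
    week8 = gen_outcomes(
        cohort, true_w, noise_sd=config.outcome_noise_sd, seed=config.seed + 9,
        features=feat, n_treated=len(treated_ids),
    )
    base_by_id = {s.id: s for s in baseline}
    pre = np.array([base_by_id[w.id].panss_pos for w in week8], dtype=float)
    post = np.array([w.panss_pos for w in week8], dtype=float)
    t_paired, p_paired, d_paired = paired_ttest(pre, post)
    svr = svr_loocv(feat, post, c=config.svr_c, epsilon=config.svr_epsilon)
    p_r, p_mse = permutation_validate(
        feat, post, n_perm=config.n_perm, seed=config.seed + 11,
        c=config.svr_c, epsilon=config.svr_epsilon,
    )
    w_share = network_weight_share(svr.weights, cohort.partition)
    pd.DataFrame({"id": treated_ids, "observed": svr.observed,
                  "predicted": svr.predicted}).to_csv(
        out / "predictions.csv", index=False, float_format="%.10g")

    summary = {
        "global_gradient_stats": global_stats,
        "network_share": shares,
        "n_significant_nodes": int(sig.sum()),
        "n_clusters_p05": int(sum(c.cluster_p < 0.05 for c in clusters)),
        "pls1_explained": float(model.covar_explained[0]),
        "pls1_spin_p": float(p_spin_pls[0]),
        "pls1_score_zmap_r": float(r_pls),
        "pls1_score_zmap_p_spin": float(p_pls_map),
        "n_pls1_plus": int((genes.list_membership == "PLS1+").sum()),
        "n_pls1_minus": int((genes.list_membership == "PLS1-").sum()),
        "gsea_es": gsea_res.es,
        "gsea_nes": gsea_res.nes,
        "paired_t": {"t": t_paired, "p": p_paired, "d": d_paired},
        "svr": {"r": svr.r, "mse": svr.mse, "p_perm_r": p_r, "p_perm_mse": p_mse},
        "svr_network_share": w_share,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))

    manifest = {
        "config": config.to_dict(),
        "outputs": {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


def subgroup_compare(
    y: np.ndarray,
    subjects: list,
    split_mask: np.ndarray,
    spins,
) -> dict:
    """GLM z maps in two subject subsets plus their spin-corrected correlation.

    ``split_mask`` selects the subjects of subset 1 among the *cases*;
    controls are kept in both subsets. Used for onset-age subgroups,
    random-half reproducibility and similar checks.
    """
    subjects = list(subjects)
    y = np.asarray(y, dtype=float)
    is_case = np.array([s.group == "case" for s in subjects])
    split_mask = np.asarray(split_mask, dtype=bool)
    sel1 = ~is_case | split_mask
    sel2 = ~is_case | (is_case & ~split_mask)
    for sel in (sel1, sel2):
        if np.sum(sel & is_case) < 3:
            raise ValueError("subgroup has fewer than 3 cases")
    s1 = glm_compare(y[sel1], [s for s, m in zip(subjects, sel1) if m])
    s2 = glm_compare(y[sel2], [s for s, m in zip(subjects, sel2) if m])
    r, p = spin_corr(s1.z, s2.z, spins)
    return {"zmap1": s1.z, "zmap2": s2.z, "spatial_r": r, "p_spin": p}
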