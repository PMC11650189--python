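# fcgrad

Functional connectome gradient analysis for case–control studies, with
spatial-null inference, imaging transcriptomics and treatment-outcome
prediction — plus a synthetic-data generator that plants known effects so
every stage of the pipeline is testable end to end without any download.

## Who this is for

Researchers analyzing resting-state functional connectivity in clinical
cohorts (e.g. first-episode psychosis) who want to:

1. build per-subject **connectome gradients** — diffusion map embeddings of
   row-sparsified, normalized-angle connectivity affinities — and harmonize
   them across subjects with iterative Procrustes rotation;
2. run **covariate-adjusted group inference** (per-node GLM t/z/Cohen's-d
   maps, BH-FDR, permutation cluster-extent correction, network-wise shares
   of significant nodes);
3. relate gradients to **small-world topology** (aGamma, aLambda, aSigma as
   AUCs over a sparsity range against degree-preserving rewired nulls);
4. test spatial hypotheses against **spin-permutation nulls** (random sphere
   rotations preserving spatial autocorrelation) and decode maps against a
   term-map collection;
5. link a case–control z map to regional gene expression with **PLS
   regression**, rank genes by bootstrap Z = weight/SE, and run permutation
   **overlap/GSEA enrichment** of the resulting PLS1+/PLS1− gene lists;
6. predict post-treatment symptom scores from baseline gradients with
   **leave-one-out linear SVR** and attribute the weight vector to networks.

## The core model

Given a node×node Pearson connectivity matrix **R**, each row keeps its top
10% of connections; cosine similarity between sparsified rows is mapped to a
normalized angle *a* = 1 − arccos(c)/π ∈ [0, 1]. The affinity **A** is
anisotropically normalized, W = D<sup>−α</sup> A D<sup>−α</sup> (α = 0.5),
and the spectrum of the transition operator P = D<sub>W</sub><sup>−1</sup>W
gives the gradients: component *i* is the *i*-th nontrivial right
eigenvector scaled by λ/(1−λ), and its explained ratio is λ<sub>i</sub>'s
share of the nontrivial positive spectrum. Gradient 1 runs from primary
sensory to transmodal cortex; its **range**, **explained ratio** and
**variance** are the global gradient metrics compared between groups.

For transcriptomics, PLS1 of (regions × genes) expression against the
case–control z map yields region scores and gene weights; 10 000-draw
bootstrap SEs give Z ranks and FDR-selected PLS1+/PLS1− lists, which feed
permutation overlap tests (disorder and cell-type marker sets) and a
preranked, weighted-KS GSEA (NES = ES normalized by same-sign null
magnitude).

## Worked example

```python
import numpy as np
import fcgrad as fg
from fcgrad.gradients import ConnectivityMatrix

# a synthetic two-group cohort with gradient compression planted in cases
cohort = fg.gen_cohort(n_case=30, n_control=30, n_nodes=120,
                       n_timepoints=150, compression=0.6, seed=17)

for group in ("case", "control"):
    ids = [s.id for s in cohort.subjects if s.group == group]
    fc = np.mean([fg.fc_matrix(cohort.timeseries[i]).values for i in ids], axis=0)
    np.fill_diagonal(fc, 0.0)
    grads = fg.diffusion_embedding(fg.affinity(ConnectivityMatrix(fc)), k=5)
    m = fg.global_metrics(grads)
    print(f"{group:7s}  range={m.range:.3f}  explained={m.explained_ratio:.3f}  "
          f"variance={m.variance:.5f}")
```

prints (seed 17):

```
case     range=0.185  explained=0.212  variance=0.00371
control  range=0.236  explained=0.176  variance=0.00373
```

The planted compression (0.6 at the axis extremes) contracts the case
group's principal gradient, so the control range (0.236) exceeds the case
range (0.185) — the direction the per-node GLM and global-metric statistics
then quantify.

The full pipeline (simulation → gradients → group stats → topology →
decoding → PLS → enrichment → prediction, with a hashed manifest) runs as

```bash
fcgrad run --seed 17 --out runs/demo
```

and each stage is also available as its own subcommand
(`simulate`, `gradients`, `compare`, `topology`, `spin`, `decode`, `pls`,
`enrich`, `predict`) on delimited-text inputs.

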