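"""Synthetic cohort, expression, gene-set, sphere and outcome generators.

The generators emulate the statistical structure a gradient +
imaging-transcriptomics study assumes, with planted ground truth so every
downstream stage can be validated without real data:

* a case/control cohort whose node time series share a latent 1-D
  functional axis ``g`` in [-1, 1]; in cases the axis is compressed at its
  extremes, producing a narrower recoverable principal gradient;
* a regions x genes expression matrix with a planted gene subset spatially
  coupled to a supplied case-control z map;
* marker / disorder gene sets overlapping the planted genes;
* quasi-uniform spherical parcel centroids for spin-permutation nulls;
* post-treatment symptom scores linearly dependent on baseline gradients.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NETWORK_NAMES = ("VN", "SMN", "DAN", "VAN", "limbic", "FPN", "DMN")

PANSS_POS_MIN = 7  # instrument minimum for the 7-item positive subscale
PANSS_POS_MAX = 49


@dataclass
class SubjectRecord:
    id: str
    group: str  # "case" | "control"
    age: float
    sex: str  # "M" | "F"
    fd: float
    onset_age: float | None = None
    panss_pos: int | None = None
    panss_neg: int | None = None
    panss_total: int | None = None
    timepoint: str = "baseline"


@dataclass
class NetworkPartition:
    """Node index -> canonical 7-network label."""

    labels: list[str]

    def __post_init__(self) -> None:
        unknown = set(self.labels) - set(NETWORK_NAMES)
        if unknown:
            raise ValueError(f"unknown network labels: {sorted(unknown)}")

    def indices(self, network: str) -> np.ndarray:
        return np.array([i for i, l in enumerate(self.labels) if l == network])


@dataclass
class ParcelSphere:
    centroids: np.ndarray  # (n, 3) unit vectors
    hemisphere: list[str]  # per-parcel "L" | "R"

    @property
    def n_parcels(self) -> int:
        return self.centroids.shape[0]


@dataclass
class PlantedTruth:
    gradient_compression: float
    affected_nodes: np.ndarray
    latent_axis: np.ndarray
    assoc_genes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    expr_coupling: float = 0.0
    outcome_weights: np.ndarray | None = None
    noise_sd: dict = field(default_factory=dict)


@dataclass
class SyntheticCohort:
    subjects: list[SubjectRecord]
    timeseries: dict[str, np.ndarray]  # subject id -> (n_nodes, n_timepoints)
    partition: NetworkPartition
    sphere: ParcelSphere
    truth: PlantedTruth

    @property
    def n_nodes(self) -> int:
        return next(iter(self.timeseries.values())).shape[0]


@dataclass
class GeneSetCollection:
    sets: dict[str, list[str]]
    background: list[str]


@dataclass
class ExpressionMatrix:
    values: np.ndarray  # (n_regions, n_genes), z-scored per gene
    gene_ids: list[str]
    region_ids: list[str]


def _latent_axis(n_nodes: int) -> np.ndarray:
    return np.linspace(-1.0, 1.0, n_nodes)


def _partition_from_axis(g: np.ndarray) -> NetworkPartition:
    """Seven contiguous blocks along the axis, primary (VN) to transmodal (DMN)."""
    n = len(g)
    edges = np.linspace(0, n, 8).astype(int)
    labels = [""] * n
    for b, name in enumerate(NETWORK_NAMES):
        for i in range(edges[b], edges[b + 1]):
            labels[i] = name
    return NetworkPartition(labels=labels)


def _subject_timeseries(
    g: np.ndarray,
    blocks: np.ndarray,
    n_timepoints: int,
    rng: np.random.Generator,
    n_sources: int = 6,
    tau: float = 0.3,
    block_weight: float = 0.1,
    noise_sd: float = 0.5,
    subject_block_sd: float = 0.06,
) -> np.ndarray:
    """Mixture-of-latent-sources model: loadings decay along the axis so the
    expected node-node correlation decreases with |g_i - g_j|.

    Each subject carries network-specific individual differences: the axis is
    jittered per block by a factor N(1, subject_block_sd), emulating
    inter-individual variability in gradient organization (without it, all
    subjects would share one axis and subject-level gradient features would
    be pure estimation noise).
    """
    block_scale = 1.0 + subject_block_sd * rng.standard_normal(blocks.max() + 1)
    g = g * block_scale[blocks]
    positions = np.linspace(-1.0, 1.0, n_sources)
    loadings = np.exp(-((g[:, None] - positions[None, :]) ** 2) / (2 * tau**2))
    loadings /= np.linalg.norm(loadings, axis=1, keepdims=True)
    sources = rng.standard_normal((n_sources, n_timepoints))
    block_sig = rng.standard_normal((blocks.max() + 1, n_timepoints))
    noise = rng.standard_normal((len(g), n_timepoints))
    return loadings @ sources + block_weight * block_sig[blocks] + noise_sd * noise


def gen_sphere(n_parcels: int, seed: int) -> ParcelSphere:
    """Quasi-uniform unit centroids (Fibonacci lattice, randomly rotated).

    All parcels are labeled "L": the synthetic parcellation models a single
    (left) cortical hemisphere as its own full sphere, the convention of
    surface-registration spheres. A rotation therefore maps the parcel cloud
    onto itself, keeping the spin-test reassignment near-bijective.
    """
    if n_parcels < 10:
        raise ValueError("need at least 10 parcels")
    rng = np.random.default_rng(seed)
    i = np.arange(n_parcels)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n_parcels
    r = np.sqrt(1.0 - z**2)
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    # random global rotation so the lattice orientation depends on the seed
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    pts = pts @ q.T
    return ParcelSphere(centroids=pts, hemisphere=["L"] * n_parcels)


def gen_cohort(
    n_case: int,
    n_control: int,
    n_nodes: int = 200,
    n_timepoints: int = 200,
    compression: float = 0.6,
    seed: int = 0,
    noise_sd: float = 0.5,
    block_weight: float = 0.1,
) -> SyntheticCohort:
    """Generate a two-group cohort with a planted gradient compression.

    Nodes carry a latent axis ``g`` in [-1, 1] split into 7 contiguous
    network blocks. Control time series follow the mixture model on ``g``;
    for cases the axis is rescaled by ``compression`` on the affected nodes
    (|g| > 0.6, the axis extremes), contracting the recoverable gradient.
    Ages and sexes are drawn from the same distributions in both groups.
    """
    if n_case <= 0 or n_control <= 0:
        raise ValueError("group sizes must be positive")
    if n_nodes < 20:
        raise ValueError("need at least 20 nodes")
    if not 0 < compression <= 1:
        raise ValueError("compression must be in (0, 1]")
    rng = np.random.default_rng(seed)

    g = _latent_axis(n_nodes)
    partition = _partition_from_axis(g)
    blocks = np.array([NETWORK_NAMES.index(l) for l in partition.labels])
    affected = np.where(np.abs(g) > 0.6)[0]
    g_case = g.copy()
    g_case[affected] *= compression

    sphere = gen_sphere(max(n_nodes, 10), seed=seed + 1)

    subjects: list[SubjectRecord] = []
    timeseries: dict[str, np.ndarray] = {}
    for group, n_sub, axis in (("case", n_case, g_case), ("control", n_control, g)):
        for j in range(n_sub):
            sid = f"{group}{j + 1:03d}"
            age = float(np.clip(rng.normal(17.0, 4.0), 7.0, 30.0))
            sex = "M" if rng.random() < 0.5 else "F"
            fd = float(np.exp(rng.normal(-2.0, 0.4)))
            rec = SubjectRecord(id=sid, group=group, age=age, sex=sex, fd=fd)
            if group == "case":
                rec.onset_age = float(max(7.0, age - rng.uniform(0.0, 1.0)))
                base = rec.onset_age / 30.0  # older onset -> more severe
                pos = int(np.clip(round(rng.normal(18 + 14 * base, 4)), 7, 49))
                neg = int(np.clip(round(rng.normal(18 + 14 * base, 4)), 7, 49))
                gen = int(np.clip(round(rng.normal(35 + 20 * base, 6)), 16, 112))
                rec.panss_pos, rec.panss_neg = pos, neg
                rec.panss_total = pos + neg + gen
            subjects.append(rec)
            timeseries[sid] = _subject_timeseries(
                axis, blocks, n_timepoints, rng,
                block_weight=block_weight, noise_sd=noise_sd,
            )

    truth = PlantedTruth(
        gradient_compression=compression,
        affected_nodes=affected,
        latent_axis=g,
        noise_sd={"timeseries": noise_sd},
    )
    return SyntheticCohort(
        subjects=subjects, timeseries=timeseries,
        partition=partition, sphere=sphere, truth=truth,
    )


def gen_expression(
    zmap: np.ndarray,
    n_genes: int,
    n_assoc: int,
    coupling: float,
    seed: int,
    noise_sd: float = 1.0,
    autocorr: float = 0.5,
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Regions x genes expression with ``n_assoc`` genes coupled to ``zmap``.

    Planted genes are ``coupling * standardize(zmap) + noise_sd * noise``;
    the remaining genes are AR(1)-smoothed noise along the region ordering
    (a cheap stand-in for spatial autocorrelation). Columns are z-scored.

    Returns the matrix and the planted gene indices.
    """
    zmap = np.asarray(zmap, dtype=float)
    if zmap.size < 10:
        raise ValueError("need at least 10 regions")
    if zmap.std() == 0:
        raise ValueError("z map is constant")
    if n_assoc > n_genes:
        raise ValueError("n_assoc exceeds n_genes")
    rng = np.random.default_rng(seed)
    n_regions = zmap.size
    z = (zmap - zmap.mean()) / zmap.std()

    raw = rng.standard_normal((n_regions, n_genes))
    expr = np.empty_like(raw)
    expr[0] = raw[0]
    for i in range(1, n_regions):  # AR(1) smoothing across regions
        expr[i] = autocorr * expr[i - 1] + np.sqrt(1 - autocorr**2) * raw[i]

    assoc = rng.choice(n_genes, size=n_assoc, replace=False)
    assoc.sort()
    expr[:, assoc] = coupling * z[:, None] + noise_sd * rng.standard_normal(
        (n_regions, n_assoc)
    )

    mu = expr.mean(axis=0)
    sd = expr.std(axis=0)
    sd[sd == 0] = 1.0
    expr = (expr - mu) / sd
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    region_ids = [f"R{i + 1:04d}" for i in range(n_regions)]
    return ExpressionMatrix(values=expr, gene_ids=gene_ids, region_ids=region_ids), assoc


def gen_gene_sets(
    assoc_genes: np.ndarray,
    background: list[str],
    overlap_frac: float,
    set_sizes: dict[str, int],
    seed: int,
) -> GeneSetCollection:
    """Gene sets drawing ``overlap_frac`` of members from the planted genes.

    ``assoc_genes`` are indices into ``background``.
    """
    if not background:
        raise ValueError("empty background")
    if not 0 <= overlap_frac <= 1:
        raise ValueError("overlap_frac must be in [0, 1]")
    rng = np.random.default_rng(seed)
    assoc_ids = [background[i] for i in np.asarray(assoc_genes, dtype=int)]
    other_ids = [g for g in background if g not in set(assoc_ids)]
    sets: dict[str, list[str]] = {}
    for name, size in set_sizes.items():
        if size > len(background):
            raise ValueError(f"set {name!r} larger than background")
        n_from_assoc = min(int(round(overlap_frac * size)), len(assoc_ids))
        picked = list(rng.choice(assoc_ids, size=n_from_assoc, replace=False))
        n_rest = size - n_from_assoc
        if n_rest > len(other_ids):
            raise ValueError(f"set {name!r} cannot be filled from background")
        picked += list(rng.choice(other_ids, size=n_rest, replace=False))
        sets[name] = sorted(picked)
    return GeneSetCollection(sets=sets, background=list(background))


def gen_outcomes(
    cohort: SyntheticCohort,
    weights: np.ndarray,
    noise_sd: float,
    seed: int,
    features: np.ndarray | None = None,
    n_treated: int | None = None,
    mean_improvement: float = 4.0,
) -> list[SubjectRecord]:
    """Append week-8 records for treated cases.

    Post-treatment PANSS positive = baseline - mean_improvement -
    weights . (centered gradient features) + Gaussian noise, rounded and
    clipped to the instrument range. Baseline gradient-1 features are
    computed from the cohort unless supplied. ``mean_improvement`` is the
    average treatment response; the weighted gradient term spreads the
    response across subjects.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.size != cohort.n_nodes:
        raise ValueError("weights length must equal node count")
    rng = np.random.default_rng(seed)
    cases = [s for s in cohort.subjects if s.group == "case" and s.timepoint == "baseline"]
    if n_treated is None:
        n_treated = min(15, len(cases))
    treated = cases[:n_treated]

    if features is None:
        features = baseline_gradient_features(cohort, [s.id for s in treated])

    # center the linear term across the treated set (intercept choice) so the
    # planted effect moves scores around their baseline rather than shifting
    # everyone to the scale floor
    centered = features - features.mean(axis=0, keepdims=True)

    new_records: list[SubjectRecord] = []
    for i, s in enumerate(treated):
        drop = (mean_improvement + float(weights @ centered[i])
                + noise_sd * rng.standard_normal())
        post = int(np.clip(round((s.panss_pos or PANSS_POS_MIN) - drop),
                           PANSS_POS_MIN, PANSS_POS_MAX))
        new_records.append(
            SubjectRecord(
                id=s.id, group="case", age=s.age, sex=s.sex, fd=s.fd,
                onset_age=s.onset_age, panss_pos=post, timepoint="week8",
            )
        )
    cohort.subjects.extend(new_records)
    cohort.truth.outcome_weights = weights
    cohort.truth.noise_sd["outcome"] = noise_sd
    return new_records


def baseline_gradient_features(
    cohort: SyntheticCohort, subject_ids: list[str]
) -> np.ndarray:
    """Aligned principal-gradient node scores for the given subjects.

    Subjects are aligned to a group template built from the group-mean
    connectivity matrix, the standard anchor for cross-subject gradient
    comparability.
    """
    from .gradients import (
        ConnectivityMatrix,
        affinity,
        diffusion_embedding,
        fc_matrix,
        procrustes_align,
    )

    fcs = {sid: fc_matrix(cohort.timeseries[sid]).values for sid in subject_ids}
    mean_fc = np.mean(list(fcs.values()), axis=0)
    np.fill_diagonal(mean_fc, 0.0)
    template = diffusion_embedding(affinity(ConnectivityMatrix(mean_fc)), k=5)
    grads = [
        diffusion_embedding(affinity(ConnectivityMatrix(fcs[sid])), k=5)
        for sid in subject_ids
    ]
    aligned, _ = procrustes_align(grads, reference=template.components)
    return np.array([g.components[:, 0] for g in aligned])
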