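"""Spin-permutation spatial nulls and map-vs-map decoding.

The spin test preserves spatial autocorrelation by randomly rotating parcel
centroids on a sphere and reassigning each parcel to its nearest original
centroid (within hemisphere, the right hemisphere receiving the mirrored
rotation). The resulting reassignments are shared by all spatial-correlation
inference, including the meta-map decoder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .groupstats import fdr_bh
from .synthdata import ParcelSphere


@dataclass
class SpinPermutationSet:
    assignments: np.ndarray  # (n_perm, n_parcels) int indices
    n_perm: int
    seed: int

    @property
    def n_parcels(self) -> int:
        return self.assignments.shape[1]


@dataclass
class DecoderResult:
    term: str
    r: float
    p_spin: float


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3-D rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


_MIRROR = np.diag([-1.0, 1.0, 1.0])  # reflect across the sagittal plane


def spin_permutations(sphere: ParcelSphere, n_perm: int, seed: int) -> SpinPermutationSet:
    """Random-rotation parcel reassignments.

    For each permutation a uniform rotation is applied to left-hemisphere
    centroids and its sagittal mirror to right-hemisphere centroids; each
    rotated parcel is reassigned to the nearest original centroid in its own
    hemisphere. Reassignment is nearest-neighbor, so two parcels may map to
    the same source.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    pts = sphere.centroids
    d = cdist(pts, pts)
    np.fill_diagonal(d, np.inf)
    if d.min() < 1e-12:
        raise ValueError("duplicate centroids")
    hemi = np.asarray(sphere.hemisphere)
    rng = np.random.default_rng(seed)
    n = pts.shape[0]
    assignments = np.empty((n_perm, n), dtype=np.int64)
    for i in range(n_perm):
        rot = random_rotation(rng)
        for h in np.unique(hemi):
            idx = np.where(hemi == h)[0]
            r = rot if h == "L" else _MIRROR @ rot @ _MIRROR
            rotated = pts[idx] @ r.T
            nearest = np.argmin(cdist(rotated, pts[idx]), axis=1)
            assignments[i, idx] = idx[nearest]
    return SpinPermutationSet(assignments=assignments, n_perm=n_perm, seed=seed)


def _corr(a: np.ndarray, b: np.ndarray, method: str) -> float:
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    return float(stats.pearsonr(a, b).statistic)


def spin_corr(
    a: np.ndarray,
    b: np.ndarray,
    spins: SpinPermutationSet,
    method: str = "pearson",
    two_sided: bool = True,
) -> tuple[float, float]:
    """Spatial correlation with a spin-permutation p-value.

    The null rotates map ``a``; p is the add-one proportion of null
    correlations at least as extreme (|r| by default) as the observed one.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != spins.n_parcels or b.size != spins.n_parcels:
        raise ValueError("map length must match the spin set's parcel count")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance map")
    r_obs = _corr(a, b, method)
    if method == "spearman":
        a_use = stats.rankdata(a)
        b_use = stats.rankdata(b)
    else:
        a_use, b_use = a, b
    null_a = a_use[spins.assignments]  # (n_perm, n_parcels)
    za = (null_a - null_a.mean(axis=1, keepdims=True)) / null_a.std(axis=1, keepdims=True)
    zb = (b_use - b_use.mean()) / b_use.std()
    null_r = za @ zb / b.size
    if two_sided:
        count = np.sum(np.abs(null_r) >= abs(r_obs))
    else:
        count = np.sum(null_r >= r_obs)
    p = (1.0 + count) / (1.0 + spins.n_perm)
    return r_obs, float(p)


def decode(
    target: np.ndarray,
    term_maps: pd.DataFrame,
    spins: SpinPermutationSet,
    method: str = "pearson",
    q: float = 0.05,
    threshold: bool = False,
) -> pd.DataFrame:
    """Correlate a target map against a collection of term maps.

    ``term_maps`` is terms x parcels (index = term labels). With
    ``threshold=True`` the target is split at zero and the positive part
    decoded (callers pass ``-target`` for the negative map). Results are
    ranked by r with BH-FDR across terms; ties are kept in stable term-label
    order.
    """
    if term_maps.shape[0] == 0:
        raise ValueError("empty term collection")
    target = np.asarray(target, dtype=float)
    if threshold:
        target = np.where(target > 0, target, 0.0)
    rows = []
    for term in sorted(term_maps.index):
        r, p = spin_corr(target, term_maps.loc[term].to_numpy(), spins, method=method)
        rows.append({"term": term, "r": r, "p_spin": p})
    df = pd.DataFrame(rows)
    df["sig_fdr"] = fdr_bh(df["p_spin"].to_numpy(), q=q)
    df = df.sort_values(["r", "term"], ascending=[False, True], kind="stable")
    return df.reset_index(drop=True)


def smooth_sphere_map(
    sphere: ParcelSphere, rng: np.random.Generator, lengthscale: float = 0.6
) -> np.ndarray:
    """Spatially smooth Gaussian-process map on the sphere (for nulls/tests)."""
    d = cdist(sphere.centroids, sphere.centroids)
    cov = np.exp(-(d**2) / (2 * lengthscale**2)) + 1e-8 * np.eye(sphere.n_parcels)
    chol = np.linalg.cholesky(cov)
    return chol @ rng.standard_normal(sphere.n_parcels)
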