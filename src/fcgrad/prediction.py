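"""Leave-one-out SVR prediction of treatment outcomes from baseline gradients.

A linear-kernel epsilon-SVR predicts post-treatment symptom scores from
baseline gradient features; validity is assessed by label-permutation, and
the linear weight vector is attributed to networks as absolute-weight shares.
Features are standardized inside each training fold only, so the held-out
subject never leaks into the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr
from sklearn.svm import SVR

from .synthdata import NetworkPartition


@dataclass
class SvrPrediction:
    predicted: np.ndarray
    observed: np.ndarray
    r: float
    mse: float
    weights: np.ndarray
    p_perm_r: float | None = None
    p_perm_mse: float | None = None
    network_share: dict[str, float] = field(default_factory=dict)


def _fit_fold(x_tr, y_tr, x_te, c, epsilon):
    mu = x_tr.mean(axis=0)
    sd = x_tr.std(axis=0)
    sd[sd == 0] = 1.0
    model = SVR(kernel="linear", C=c, epsilon=epsilon)
    model.fit((x_tr - mu) / sd, y_tr)
    return model.predict((x_te - mu) / sd)


def svr_loocv(
    features: np.ndarray,
    y: np.ndarray,
    c: float = 1.0,
    epsilon: float = 0.1,
) -> SvrPrediction:
    """Linear epsilon-SVR with leave-one-out cross-validation.

    Per fold, features are standardized on the training subjects only. The
    attribution weight vector comes from a fit on all subjects.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 2 or x.shape[0] != y.size:
        raise ValueError("features must be subjects x nodes matching y")
    if x.shape[0] < 5:
        raise ValueError("need at least 5 subjects for LOOCV")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite features")
    if y.std() == 0:
        raise ValueError("constant outcome")

    n = x.shape[0]
    pred = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        pred[i] = _fit_fold(x[mask], y[mask], x[i : i + 1], c, epsilon)[0]

    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    full = SVR(kernel="linear", C=c, epsilon=epsilon)
    full.fit((x - mu) / sd, y)
    weights = np.asarray(full.coef_).ravel()

    r = float(pearsonr(pred, y).statistic) if pred.std() > 0 else 0.0
    mse = float(np.mean((pred - y) ** 2))
    return SvrPrediction(predicted=pred, observed=y.copy(), r=r, mse=mse, weights=weights)


def permutation_validate(
    features: np.ndarray,
    y: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    c: float = 1.0,
    epsilon: float = 0.1,
) -> tuple[float, float]:
    """Permutation p-values for the LOOCV r (greater) and MSE (less)."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    obs = svr_loocv(features, y, c=c, epsilon=epsilon)
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    count_r = 0
    count_mse = 0
    for _ in range(n_perm):
        y_perm = rng.permutation(y)
        if y_perm.std() == 0:
            continue
        res = svr_loocv(features, y_perm, c=c, epsilon=epsilon)
        count_r += res.r >= obs.r
        count_mse += res.mse <= obs.mse
    p_r = (1.0 + count_r) / (1.0 + n_perm)
    p_mse = (1.0 + count_mse) / (1.0 + n_perm)
    return float(p_r), float(p_mse)


def network_weight_share(
    weights: np.ndarray, partition: NetworkPartition
) -> dict[str, float]:
    """Per-network fraction of total absolute weight; fractions sum to 1."""
    w = np.abs(np.asarray(weights, dtype=float))
    if len(partition.labels) != w.size:
        raise ValueError("partition must label every feature node")
    total = w.sum()
    if total == 0:
        raise ValueError("all-zero weight vector")
    labels = np.asarray(partition.labels)
    return {
        net: float(w[labels == net].sum() / total)
        for net in sorted(set(partition.labels))
    }
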