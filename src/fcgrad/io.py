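"""Delimited-text readers and writers for all interchange formats.

Everything is plain TSV/CSV/GMT/JSON: per-subject time-series TSVs, a
subject table CSV, expression TSV (regions x genes), sphere and partition
CSVs, gradient TSVs with a JSON eigenvalue sidecar, and stat-map TSVs.
Node indices are 0-based internally and written as 1-based labels.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .gradients import GradientSet
from .groupstats import GroupStatMap
from .synthdata import (
    ExpressionMatrix,
    NetworkPartition,
    ParcelSphere,
    SubjectRecord,
    SyntheticCohort,
)


def write_timeseries(ts: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(ts).to_csv(path, sep="\t", header=False, index=False, float_format="%.10g")


def read_timeseries(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)


def write_subject_table(subjects: list[SubjectRecord], path: str | Path) -> None:
    pd.DataFrame([asdict(s) for s in subjects]).to_csv(path, index=False)


def read_subject_table(path: str | Path) -> list[SubjectRecord]:
    df = pd.read_csv(path)
    recs = []
    valid = {f.name for f in fields(SubjectRecord)}
    int_cols = {"panss_pos", "panss_neg", "panss_total"}
    for row in df.to_dict("records"):
        kwargs = {}
        for k, v in row.items():
            if k not in valid or (isinstance(v, float) and np.isnan(v)):
                continue
            kwargs[k] = int(v) if k in int_cols else v
        recs.append(SubjectRecord(**kwargs))
    return recs


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    pd.DataFrame(expr.values, index=expr.region_ids, columns=expr.gene_ids).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def read_expression(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(
        values=df.to_numpy(dtype=float),
        gene_ids=[str(c) for c in df.columns],
        region_ids=[str(i) for i in df.index],
    )


def write_sphere(sphere: ParcelSphere, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "parcel": np.arange(1, sphere.n_parcels + 1),
            "x": sphere.centroids[:, 0],
            "y": sphere.centroids[:, 1],
            "z": sphere.centroids[:, 2],
            "hemisphere": sphere.hemisphere,
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_sphere(path: str | Path) -> ParcelSphere:
    df = pd.read_csv(path)
    return ParcelSphere(
        centroids=df[["x", "y", "z"]].to_numpy(dtype=float),
        hemisphere=df["hemisphere"].astype(str).tolist(),
    )


def write_partition(partition: NetworkPartition, path: str | Path) -> None:
    pd.DataFrame(
        {"node": np.arange(1, len(partition.labels) + 1), "network": partition.labels}
    ).to_csv(path, index=False)


def read_partition(path: str | Path) -> NetworkPartition:
    df = pd.read_csv(path).sort_values("node")
    return NetworkPartition(labels=df["network"].astype(str).tolist())


def write_gradients(g: GradientSet, path: str | Path) -> None:
    """Gradient TSV (node, g1..gk) plus a JSON sidecar with the spectrum."""
    path = Path(path)
    df = pd.DataFrame(g.components, columns=[f"g{i + 1}" for i in range(g.k)])
    df.insert(0, "node", np.arange(1, g.n_nodes + 1))
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    sidecar = {
        "eigenvalues": [float(v) for v in g.eigenvalues],
        "explained_ratio": [float(v) for v in g.explained_ratio],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_gradients(path: str | Path) -> GradientSet:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    comps = df[[c for c in df.columns if c.startswith("g")]].to_numpy(dtype=float)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return GradientSet(
        components=comps,
        eigenvalues=np.asarray(meta["eigenvalues"]),
        explained_ratio=np.asarray(meta["explained_ratio"]),
    )


def write_statmap(stat: GroupStatMap, path: str | Path, sig_fdr=None, cluster_id=None) -> None:
    n = stat.t.size
    df = pd.DataFrame(
        {
            "node": np.arange(1, n + 1),
            "t": stat.t,
            "z": stat.z,
            "p": stat.p,
            "d": stat.d,
            "sig_fdr": sig_fdr if sig_fdr is not None else [False] * n,
            "cluster_id": cluster_id if cluster_id is not None else [0] * n,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_term_maps(term_maps: pd.DataFrame, path: str | Path) -> None:
    term_maps.to_csv(path, sep="\t", float_format="%.10g")


def read_term_maps(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Serialize a synthetic cohort to a directory of delimited-text files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "timeseries").mkdir(exist_ok=True)
    for sid, ts in cohort.timeseries.items():
        write_timeseries(ts, out / "timeseries" / f"{sid}.tsv")
    write_subject_table(cohort.subjects, out / "subjects.csv")
    write_partition(cohort.partition, out / "partition.csv")
    write_sphere(cohort.sphere, out / "sphere.csv")


@dataclass
class PipelineConfig:
    """Validated parameters for the end-to-end pipeline."""

    seed: int = 0
    n_case: int = 30
    n_control: int = 30
    n_nodes: int = 120
    n_timepoints: int = 150
    compression: float = 0.6
    density: float = 0.10
    alpha: float = 0.5
    k: int = 5
    sparsities: tuple = (0.15, 0.25, 0.35)
    n_rand: int = 3
    n_perm: int = 200
    n_boot: int = 200
    n_genes: int = 300
    n_assoc: int = 20
    coupling: float = 1.0
    expr_noise_sd: float = 0.5
    q: float = 0.05
    voxel_p: float = 0.001
    svr_c: float = 1.0
    svr_epsilon: float = 0.1
    outcome_noise_sd: float = 1.0
    n_treated: int = 15

    def __post_init__(self) -> None:
        if not 0 < self.density < 1:
            raise ValueError("density must be in (0, 1)")
        if not 0 < self.compression <= 1:
            raise ValueError("compression must be in (0, 1]")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.k < 1:
            raise ValueError("k must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        valid = {f.name for f in fields(cls)}
        unknown = set(d) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "sparsities" in d:
            d = {**d, "sparsities": tuple(d["sparsities"])}
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sparsities"] = list(d["sparsities"])
        return d
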