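"""Across-subject IC clustering in a weighted multi-measure feature space.

Each retained IC contributes four measures: equivalent-dipole location
(3 dimensions, weight 10), scalp map (PCA-reduced to 7 dimensions,
weight 3), mean log power spectrum over 3–50 Hz (5 dimensions, weight
2), and the concatenated standard+deviant ERPs over 0–500 ms (jointly
reduced to 5 dimensions, weight 1) — 20 feature dimensions in all.
Dipole locations enter raw (their dimension is already 3 and location
is the most subject-robust measure); every other measure is z-normalised
per raw dimension, PCA-reduced, rescaled to unit total block variance
and multiplied by its weight, so a weight w scales that block's
squared-distance contribution by w².

Clustering is Euclidean k-means (k = 20 by default, best of many
restarts).  Outliers beyond 3 cluster-RMS distances from their centroid
can be marked and removed; a config hook allows re-clustering any single
cluster with k = 2 (the analogue of manually splitting an overlarge
cluster).  Cluster accounting reports per-group IC and subject counts,
centroid dipole positions and their Talairach conversion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .data_io import ValidationError
from .localize import DipoleFit

__all__ = [
    "ICRecord",
    "FeatureSpec",
    "ClusterSet",
    "build_feature_vectors",
    "kmeans_cluster",
    "reject_outliers",
    "split_cluster",
    "cluster_report",
    "flag_artifact_clusters",
    "mni_to_talairach",
    "OUTLIER",
]

OUTLIER = -1


@dataclass
class ICRecord:
    """One IC's clustering measures plus provenance tags."""

    subject_id: str
    group: str
    ic_index: int
    scalp_map: np.ndarray
    dipole: DipoleFit
    log_spectrum: np.ndarray  # 3–50 Hz band
    erp_standard: np.ndarray  # 0–500 ms, source-resolved
    erp_deviant: np.ndarray
    source_name: str | None = None  # ground-truth tag when synthetic

    def __post_init__(self) -> None:
        self.scalp_map = np.asarray(self.scalp_map, dtype=float)
        self.log_spectrum = np.asarray(self.log_spectrum, dtype=float)
        self.erp_standard = np.asarray(self.erp_standard, dtype=float)
        self.erp_deviant = np.asarray(self.erp_deviant, dtype=float)
        if self.erp_standard.shape != self.erp_deviant.shape:
            raise ValidationError("condition ERPs must share a time base")


@dataclass(frozen=True)
class FeatureSpec:
    """Per-measure (dimensions, relative weight)."""

    dipole: tuple[int, float] = (3, 10.0)
    scalp_map: tuple[int, float] = (7, 3.0)
    spectrum: tuple[int, float] = (5, 2.0)
    erp: tuple[int, float] = (5, 1.0)

    def __post_init__(self) -> None:
        for dims, weight in (self.dipole, self.scalp_map, self.spectrum, self.erp):
            if dims < 1 or weight <= 0:
                raise ValidationError("feature dims must be >= 1 and weights > 0")

    @property
    def total_dims(self) -> int:
        return self.dipole[0] + self.scalp_map[0] + self.spectrum[0] + self.erp[0]


@dataclass
class ClusterSet:
    k: int
    records: list[ICRecord]
    assignments: np.ndarray  # cluster id per record, OUTLIER for outliers
    centroids: np.ndarray  # k × n_features
    features: np.ndarray  # n_records × n_features

    def members(self, cid: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == cid)

    def counts(self) -> dict[int, dict[str, dict[str, int]]]:
        """Per cluster, per group: number of ICs and of distinct subjects."""
        out: dict[int, dict[str, dict[str, int]]] = {}
        for cid in range(self.k):
            idx = self.members(cid)
            per_group: dict[str, dict[str, int]] = {}
            for i in idx:
                r = self.records[i]
                g = per_group.setdefault(r.group, {"n_ics": 0, "subjects": set()})  # type: ignore[dict-item]
                g["n_ics"] += 1
                g["subjects"].add(r.subject_id)  # type: ignore[union-attr]
            out[cid] = {
                grp: {"n_ics": v["n_ics"], "n_subjects": len(v["subjects"])}  # type: ignore[arg-type]
                for grp, v in per_group.items()
            }
        return out


def _z_columns(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - x.mean(axis=0)) / sd


def _block(x: np.ndarray, dims: int, weight: float, reduce: bool, seed: int = 0) -> np.ndarray:
    """z-normalise, optionally PCA-reduce, unit total variance, weight."""
    z = _z_columns(x)
    if reduce:
        if z.shape[0] <= dims:
            raise ValidationError(
                f"need more than {dims} records for a {dims}-D reduction"
            )
        z = PCA(n_components=dims, svd_solver="full", random_state=seed).fit_transform(z)
    elif z.shape[1] != dims:
        raise ValidationError(f"expected {dims} raw dimensions, got {z.shape[1]}")
    total_var = z.var(axis=0).sum()
    if total_var > 0:
        z = z / np.sqrt(total_var)
    return weight * z


def build_feature_vectors(
    records: list[ICRecord], spec: FeatureSpec = FeatureSpec()
) -> np.ndarray:
    """Assemble the weighted feature matrix (n_records × spec.total_dims)."""
    if len(records) < max(spec.scalp_map[0], spec.spectrum[0], spec.erp[0]) + 1:
        raise ValidationError("too few records for the requested feature dims")
    dip = np.array([r.dipole.position for r in records])
    maps = np.array([r.scalp_map for r in records])
    spec_m = np.array([r.log_spectrum for r in records])
    erps = np.array(
        [np.concatenate([r.erp_standard, r.erp_deviant]) for r in records]
    )
    blocks = [
        _block(dip, *spec.dipole, reduce=False),
        _block(maps, *spec.scalp_map, reduce=True),
        _block(spec_m, *spec.spectrum, reduce=True),
        _block(erps, *spec.erp, reduce=True),
    ]
    return np.hstack(blocks)


def kmeans_cluster(
    features: np.ndarray,
    records: list[ICRecord],
    k: int = 20,
    restarts: int = 50,
    seed: int = 0,
) -> ClusterSet:
    """Euclidean k-means, best of ``restarts`` by within-cluster SS."""
    n = features.shape[0]
    if k > n:
        raise ValidationError(f"k={k} exceeds the {n} available records")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(features)
    return ClusterSet(
        k=k,
        records=records,
        assignments=labels.astype(int),
        centroids=km.cluster_centers_,
        features=features,
    )


def reject_outliers(clusters: ClusterSet, sd: float = 3.0) -> ClusterSet:
    """Mark ICs farther than sd × cluster-RMS distance from their centroid.

    Centroids are recomputed once after marking.
    """
    assignments = clusters.assignments.copy()
    for cid in range(clusters.k):
        idx = clusters.members(cid)
        if idx.size == 0:
            continue
        d = np.linalg.norm(
            clusters.features[idx] - clusters.centroids[cid], axis=1
        )
        rms = np.sqrt((d**2).mean())
        if rms == 0:
            continue
        assignments[idx[d > sd * rms]] = OUTLIER
    centroids = clusters.centroids.copy()
    for cid in range(clusters.k):
        idx = np.flatnonzero(assignments == cid)
        if idx.size:
            centroids[cid] = clusters.features[idx].mean(axis=0)
    return ClusterSet(
        k=clusters.k,
        records=clusters.records,
        assignments=assignments,
        centroids=centroids,
        features=clusters.features,
    )


def split_cluster(clusters: ClusterSet, cid: int, seed: int = 0) -> ClusterSet:
    """Re-cluster one cluster with k=2 (manual-split hook).

    The second half keeps a fresh id ``clusters.k``; k grows by one.
    """
    idx = clusters.members(cid)
    if idx.size < 2:
        raise ValidationError("cannot split a cluster with fewer than 2 members")
    km = KMeans(n_clusters=2, n_init=10, random_state=seed, algorithm="lloyd")
    sub = km.fit_predict(clusters.features[idx])
    assignments = clusters.assignments.copy()
    assignments[idx[sub == 1]] = clusters.k
    centroids = np.vstack([clusters.centroids, km.cluster_centers_[1]])
    centroids[cid] = km.cluster_centers_[0]
    return ClusterSet(
        k=clusters.k + 1,
        records=clusters.records,
        assignments=assignments,
        centroids=centroids,
        features=clusters.features,
    )


# piecewise-linear template(MNI)->Talairach transform (above/below AC plane)
_TAL_UPPER = np.array(
    [[0.9900, 0.0, 0.0], [0.0, 0.9688, 0.0460], [0.0, -0.0485, 0.9189]]
)
_TAL_LOWER = np.array(
    [[0.9900, 0.0, 0.0], [0.0, 0.9688, 0.0420], [0.0, -0.0485, 0.8390]]
)


def mni_to_talairach(xyz: np.ndarray) -> np.ndarray:
    """Template (MNI-like) mm coordinates → Talairach, piecewise-linear.

    The origin is a fixed point; points with z ≥ 0 (above the AC–PC
    plane) use the upper affine, others the lower one.
    """
    xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
    out = np.empty_like(xyz)
    upper = xyz[:, 2] >= 0
    out[upper] = xyz[upper] @ _TAL_UPPER.T
    out[~upper] = xyz[~upper] @ _TAL_LOWER.T
    return out[0] if out.shape[0] == 1 and np.asarray(xyz).ndim == 1 else out


def flag_artifact_clusters(
    clusters: ClusterSet, rv_max: float = 0.15, brain_radius: float = 80.0
) -> list[int]:
    """Clusters whose median member looks non-brain (high rv or outside).

    With the upstream dipolarity screen this is usually a no-op; it is
    kept so a pipeline run without the screen still drops artifact
    clusters before ERP accounting.
    """
    flagged = []
    for cid in range(clusters.k):
        idx = clusters.members(cid)
        if idx.size == 0:
            continue
        rvs = np.median([clusters.records[i].dipole.rv for i in idx])
        ecc = np.median(
            [np.linalg.norm(clusters.records[i].dipole.position) for i in idx]
        )
        if rvs > rv_max or ecc > brain_radius:
            flagged.append(cid)
    return flagged


def cluster_report(clusters: ClusterSet) -> dict:
    """Per-cluster accounting: centroid dipoles, Talairach, group counts."""
    counts = clusters.counts()
    report: dict = {"k": clusters.k, "clusters": {}}
    for cid in range(clusters.k):
        idx = clusters.members(cid)
        entry: dict = {"n_members": int(idx.size)}
        if idx.size:
            pos = np.array([clusters.records[i].dipole.position for i in idx])
            centroid = pos.mean(axis=0)
            entry["centroid_mm"] = centroid.tolist()
            entry["centroid_talairach"] = np.asarray(
                mni_to_talairach(centroid)
            ).tolist()
        groups = {}
        for grp, v in counts[cid].items():
            n_ics, n_subj = v["n_ics"], v["n_subjects"]
            groups[grp] = {
                "n_ics": n_ics,
                "n_subjects": n_subj,
                "ics_per_contributing_subject": (n_ics / n_subj) if n_subj else 0.0,
            }
        entry["groups"] = groups
        report["clusters"][cid] = entry
    return report
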