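"""Density-based spatial clustering of merged localizations into telomere candidates.

DBSCAN with a 90-nm neighborhood radius and a minimum of eight neighbors
(counting the point itself, closed ball) groups localizations into candidate
telomere clusters; clusters with fewer than 50 localizations are then removed,
since such sparse groups rarely coincide with a wide-field telomere focus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

QcStatus = Literal["unreviewed", "kept", "rejected"]
DdrClass = Literal["none", "partial", "complete", "unlabeled"]


@dataclass
class ClusterParams:
    eps_nm: float = 90.0
    min_samples: int = 8
    min_cluster_size: int = 50

    def __post_init__(self) -> None:
        if self.eps_nm <= 0:
            raise ValueError("eps_nm must be > 0")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")
        if self.min_cluster_size < self.min_samples:
            raise ValueError("min_cluster_size must be >= min_samples")


@dataclass
class Cluster:
    """One candidate telomere: indices into the merged localization table."""

    cluster_id: int
    member_indices: np.ndarray
    fov_id: str | None = None
    qc_status: QcStatus = "unreviewed"
    qc_reason: str | None = None
    ddr_class: DdrClass = "unlabeled"
    ddr_fraction: float | None = None

    @property
    def n_localizations(self) -> int:
        return len(self.member_indices)


def cluster_dbscan(
    table: pd.DataFrame, params: ClusterParams | None = None, fov_id: str | None = None
) -> tuple[list[Cluster], np.ndarray]:
    """Run DBSCAN on (x_nm, y_nm); returns clusters and the noise-point indices.

    Standard DBSCAN semantics: a core point has >= ``min_samples`` points within
    ``eps_nm`` (closed Euclidean ball, counting itself); clusters are maximal
    density-connected sets; remaining points are noise. With the deterministic
    input ordering used here, border-point ties always resolve to the
    first-discovered cluster, so repeated runs agree exactly.
    """
    params = params or ClusterParams()
    if table.empty:
        raise ValueError("localization table is empty")
    xy = table[["x_nm", "y_nm"]].to_numpy()
    labels = DBSCAN(eps=params.eps_nm, min_samples=params.min_samples).fit_predict(xy)
    clusters = [
        Cluster(cluster_id=int(lab), member_indices=np.flatnonzero(labels == lab), fov_id=fov_id)
        for lab in np.unique(labels)
        if lab != -1
    ]
    noise = np.flatnonzero(labels == -1)
    return clusters, noise


def gate_clusters(
    clusters: list[Cluster], min_cluster_size: int = 50
) -> tuple[list[Cluster], int]:
    """Drop clusters with fewer than ``min_cluster_size`` localizations.

    The inequality is strict: a cluster of exactly ``min_cluster_size`` members
    is kept.
    """
    kept = [c for c in clusters if c.n_localizations >= min_cluster_size]
    return kept, len(clusters) - len(kept)


def labels_from_clusters(clusters: list[Cluster], n_points: int) -> np.ndarray:
    """Per-point cluster labels (-1 = noise/ungated) for CSV export."""
    labels = np.full(n_points, -1, dtype=np.int64)
    for c in clusters:
        labels[c.member_indices] = c.cluster_id
    return labels
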