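"""RMSD-based conformational clustering (GROMOS algorithm) and centroid
selection for path refinement.

The GROMOS scheme greedily takes the frame with the most neighbors within
an RMSD cutoff as a cluster centroid, removes the centroid and its
neighbors from the pool, and repeats. Centroids of the most populated
clusters become the waypoints through which the refined transition path is
bridged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import Structure, aligned_msd_many
from .units import NM_TO_ANGSTROM

__all__ = ["Cluster", "ClusterTable", "gromos_cluster", "select_top_centroids"]


@dataclass
class Cluster:
    id: int  # 1-based rank by population
    population: int
    centroid: Structure
    centroid_index: int  # index into the pooled frames
    member_indices: np.ndarray
    centroid_s: Optional[float] = None
    centroid_z: Optional[float] = None


@dataclass
class ClusterTable:
    clusters: list
    n_frames: int
    cutoff: float  # nm
    metric_subset: str = "measure"

    def __post_init__(self):
        pops = [c.population for c in self.clusters]
        if any(a < b for a, b in zip(pops[:-1], pops[1:])):
            raise ValueError("clusters must be sorted by non-increasing population")
        if sum(pops) != self.n_frames:
            raise ValueError("cluster populations must sum to the pool size")

    def __len__(self):
        return len(self.clusters)

    def to_dataframe(self) -> pd.DataFrame:
        """Table mirroring the printed cluster summary (Z in Å²)."""
        rows = []
        for c in self.clusters:
            rows.append(
                {
                    "cluster_id": c.id,
                    "population": c.population,
                    "S": np.nan if c.centroid_s is None else round(c.centroid_s, 1),
                    "Z_A2": np.nan
                    if c.centroid_z is None
                    else round(c.centroid_z * NM_TO_ANGSTROM**2, 1),
                }
            )
        return pd.DataFrame(rows)


def _pool_frames(traj_pool) -> list:
    if hasattr(traj_pool, "frames"):
        return list(traj_pool.frames)
    frames = []
    for item in traj_pool:
        if hasattr(item, "frames"):
            frames.extend(item.frames)
        else:
            frames.append(item)
    return frames


def pairwise_msd_matrix(frames: Sequence[Structure], subset: str = "measure") -> np.ndarray:
    """Symmetric matrix of aligned MSDs (nm²) between all frame pairs."""
    n = len(frames)
    d2 = np.zeros((n, n))
    for i in range(n - 1):
        d2[i, i + 1 :] = aligned_msd_many(frames[i], frames[i + 1 :], measure=subset)
    return d2 + d2.T


def gromos_cluster(
    traj_pool,
    cutoff: float,
    frameset=None,
    metric_subset: str = "measure",
) -> ClusterTable:
    """Cluster pooled frames with the GROMOS neighbor-count algorithm.

    ``cutoff`` is the aligned-RMSD threshold in nm (1.5 Å = 0.15 nm is the
    conventional choice). The RMSD metric uses the measure subset by default
    (``metric_subset='all'`` clusters on every atom). Ties in neighbor count
    break toward the lowest frame index, which makes the partition
    deterministic. If a ``frameset`` is given, centroid S and Z are
    annotated. A cutoff larger than the pool diameter yields one cluster.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    frames = _pool_frames(traj_pool)
    if not frames:
        raise ValueError("empty trajectory pool")

    d2 = pairwise_msd_matrix(frames, subset=metric_subset)
    neighbors = d2 <= cutoff * cutoff  # includes self
    n = len(frames)
    unassigned = np.ones(n, dtype=bool)
    raw = []
    while unassigned.any():
        counts = (neighbors & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(neighbors[center] & unassigned)
        raw.append((center, members))
        unassigned[members] = False

    raw.sort(key=lambda cm: (-len(cm[1]), cm[1][0]))
    clusters = []
    for rank, (center, members) in enumerate(raw, start=1):
        c = Cluster(
            id=rank,
            population=len(members),
            centroid=frames[center],
            centroid_index=center,
            member_indices=members,
        )
        if frameset is not None:
            from .pathcv import path_s_z

            c.centroid_s, c.centroid_z = path_s_z(c.centroid, frameset)
        clusters.append(c)
    return ClusterTable(
        clusters=clusters, n_frames=n, cutoff=cutoff, metric_subset=metric_subset
    )


def select_top_centroids(table: ClusterTable, k: int) -> list:
    """Centroids of the k most populated clusters, ordered along the path.

    Ordering is by centroid S ascending so consecutive centroids can be
    bridged into a connected path; requires the table to carry S annotations.
    """
    if k > len(table):
        raise ValueError(f"requested {k} centroids but only {len(table)} clusters exist")
    top = table.clusters[:k]
    if any(c.centroid_s is None for c in top):
        raise ValueError("cluster table has no S annotations; cluster with a frameset")
    return [c.centroid for c in sorted(top, key=lambda c: c.centroid_s)]
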