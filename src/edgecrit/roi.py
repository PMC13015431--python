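"""Electrode ROI clusters from montage triangulation, and spatial aggregation.

Dense EEG nets carry highly redundant neighboring channels; the pipeline
reduces them to thirteen six-electrode clusters centered on canonical
positions (F3, FCz, F4, C3, C1, C2, C4, P3, Pz, P4, O1, Oz, O2).  Cluster
membership is the centroid plus its five nearest Delaunay-adjacent
electrodes, with the triangulation computed on an azimuthal-equidistant 2D
projection from the vertex.  Per-electrode metric values are averaged within
a cluster; a cluster with any missing member is skipped wholesale (a dropped
channel may already have been interpolated upstream, and interpolating twice
degrades dimensionality).  Scalp-level aggregation averages all clusters for
auditory analyses but only the occipital clusters (O1, Oz, O2) for visual
ones, reflecting the spatial specificity of visual responses.

A skipped cluster or an epoch with every relevant cluster skipped is
represented by ``numpy.nan`` (a value, not an exception).
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass
from collections.abc import Iterable, Mapping

import numpy as np
from scipy.spatial import Delaunay

OCCIPITAL_CLUSTERS = ("O1", "Oz", "O2")


@dataclass(frozen=True)
class Montage:
    """Electrode ids and 3D positions (consistent units, e.g. unit sphere)."""

    ids: tuple[str, ...]
    positions: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("electrode ids must be unique")
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.ids), 3):
            raise ValueError("positions must be (n_electrodes, 3)")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        if len(np.unique(np.round(pos, 9), axis=0)) != len(pos):
            raise ValueError("duplicated electrode positions")

    @classmethod
    def from_csv(cls, path) -> "Montage":
        ids, pos = [], []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                ids.append(row["id"])
                pos.append([float(row["x"]), float(row["y"]), float(row["z"])])
        return cls(ids=tuple(ids), positions=np.array(pos))

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "x", "y", "z"])
            for i, (x, y, z) in zip(self.ids, self.positions):
                w.writerow([i, f"{x:.6f}", f"{y:.6f}", f"{z:.6f}"])

    def index(self, electrode_id: str) -> int:
        return self.ids.index(electrode_id)


@dataclass(frozen=True)
class ClusterMap:
    """Named clusters of exactly six electrode ids, centroid included."""

    clusters: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for name, members in self.clusters.items():
            if len(members) != 6 or len(set(members)) != 6:
                raise ValueError(f"cluster {name} must have 6 distinct members")
            if name not in members:
                raise ValueError(f"centroid {name} must belong to its cluster")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({k: list(v) for k, v in self.clusters.items()}, fh,
                      indent=1)

    @classmethod
    def from_json(cls, path) -> "ClusterMap":
        with open(path) as fh:
            return cls({k: tuple(v) for k, v in json.load(fh).items()})


def _project_azimuthal(positions: np.ndarray) -> np.ndarray:
    """Azimuthal-equidistant projection from the vertex (+z pole)."""
    p = positions / np.linalg.norm(positions, axis=1, keepdims=True)
    theta = np.arccos(np.clip(p[:, 2], -1.0, 1.0))  # polar angle = radius
    phi = np.arctan2(p[:, 1], p[:, 0])
    return np.column_stack([theta * np.cos(phi), theta * np.sin(phi)])


def delaunay_neighbors(montage: Montage) -> dict[str, set[str]]:
    """Adjacency sets of the Delaunay triangulation of the projected montage."""
    pts = _project_azimuthal(np.asarray(montage.positions, dtype=float))
    tri = Delaunay(pts)
    adj: dict[str, set[str]] = {i: set() for i in montage.ids}
    for simplex in tri.simplices:
        for a in simplex:
            for b in simplex:
                if a != b:
                    adj[montage.ids[a]].add(montage.ids[b])
    return adj


def build_clusters(montage: Montage,
                   centroids: Iterable[str] = None) -> ClusterMap:
    """Build six-electrode clusters around each centroid electrode.

    Cluster = centroid + its 5 nearest Delaunay-adjacent electrodes (3D
    Euclidean distance; ties broken by electrode id).  A centroid with fewer
    than 5 triangulation neighbors (e.g. on the hull of a sparse montage)
    falls back to the overall nearest electrodes, with a warning.
    Deterministic and invariant to electrode ordering.
    """
    from .synth import CENTROID_NAMES

    if centroids is None:
        centroids = CENTROID_NAMES
    centroids = list(centroids)
    missing = [c for c in centroids if c not in montage.ids]
    if missing:
        raise ValueError(f"centroids absent from montage: {missing}")

    adj = delaunay_neighbors(montage)
    pos = {i: p for i, p in zip(montage.ids, montage.positions)}
    clusters = {}
    for c in centroids:
        neigh = sorted(adj[c],
                       key=lambda e: (float(np.linalg.norm(pos[e] - pos[c])), e))
        if len(neigh) < 5:
            warnings.warn(
                f"centroid {c} has only {len(neigh)} Delaunay neighbors; "
                "falling back to geodesic-nearest electrodes", stacklevel=2)
            others = sorted(
                (e for e in montage.ids if e != c),
                key=lambda e: (float(np.linalg.norm(pos[e] - pos[c])), e))
            neigh = others
        clusters[c] = tuple([c] + neigh[:5])
    return ClusterMap(clusters=clusters)


def cluster_feature(per_electrode_values: Mapping[str, float],
                    cluster: Iterable[str]) -> float:
    """Arithmetic mean of a metric over a cluster's six electrodes.

    Returns nan (the skip sentinel) when any member electrode is absent or
    non-finite — the whole cluster is skipped rather than partially averaged.
    """
    vals = []
    for e in cluster:
        v = per_electrode_values.get(e)
        if v is None or not np.isfinite(v):
            return float("nan")
        vals.append(float(v))
    return float(np.mean(vals))


def aggregate_scalp(roi_values: Mapping[str, float], modality: str) -> float:
    """Scalp-level aggregate of cluster values for one epoch.

    auditory: mean over all non-skipped clusters; visual: mean over the
    non-skipped occipital clusters.  All relevant clusters skipped -> nan
    (missing-observation sentinel).
    """
    if modality == "visual":
        pool = [roi_values.get(c, float("nan")) for c in OCCIPITAL_CLUSTERS]
    elif modality == "auditory":
        pool = list(roi_values.values())
    else:
        raise ValueError("modality must be 'auditory' or 'visual'")
    pool = [v for v in pool if v is not None and np.isfinite(v)]
    if not pool:
        return float("nan")
    return float(np.mean(pool))
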