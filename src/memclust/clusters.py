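"""Cluster identification, tracking and growth kinetics.

Clusters are connected components of the graph linking inclusion pairs
whose center-to-center minimum-image distance is within a cutoff.  Two
cutoffs are physically meaningful for lipid-separated inclusions such as
CNT porins: full contact (~1.7 nm) and separation by a single shared lipid
shell (~2.25 nm); both are plain parameters here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .core import Configuration, Trajectory, min_image_displacement

__all__ = [
    "ClusterAssignment",
    "ClusterSeries",
    "PowerLawFit",
    "min_image_distances",
    "find_clusters",
    "cluster_series",
    "fit_power_law",
    "neighbor_counts",
]


@dataclass
class ClusterAssignment:
    """Per-frame cluster labels.

    Labels are canonical: clusters are numbered by ascending minimum member
    index, so the inclusion with index 0 is always in cluster 0.
    """

    labels: np.ndarray
    cutoff: float
    time: float = 0.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    @property
    def sizes(self) -> np.ndarray:
        """Cluster sizes, indexed by canonical label."""
        return np.bincount(self.labels, minlength=self.n_clusters)

    def members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)


@dataclass
class ClusterSeries:
    """Per-frame cluster statistics and identity tracking."""

    times: np.ndarray
    n_clusters: np.ndarray
    n_max: np.ndarray
    mean_size: np.ndarray
    assignments: List[ClusterAssignment]
    cutoff: float
    #: per transition frame k -> k+1: mapping new canonical label -> inherited
    #: label of the frame-k cluster with the largest member overlap
    tracking: List[Dict[int, int]] = field(default_factory=list)
    #: (frame index k, kind, detail) where kind is "fusion" or "fission"
    events: List[Tuple[int, str, str]] = field(default_factory=list)


@dataclass
class PowerLawFit:
    """Least-squares power law y = prefactor * t**exponent (log-log space)."""

    exponent: float
    prefactor: float
    fit_range: Tuple[float, float]
    residual: float  # RMS residual in log space
    n_points: int = 0


def _canonicalize(raw_labels: np.ndarray) -> np.ndarray:
    """Renumber labels by ascending minimum member index."""
    order: Dict[int, int] = {}
    out = np.empty_like(raw_labels)
    for i, lab in enumerate(raw_labels):
        if lab not in order:
            order[lab] = len(order)
        out[i] = order[lab]
    return out


def min_image_distances(config: Configuration) -> np.ndarray:
    """All N(N-1)/2 pairwise minimum-image distances (condensed order,
    compatible with :func:`scipy.spatial.distance.squareform`)."""
    pos = config.positions
    n = config.n
    iu, ju = np.triu_indices(n, k=1)
    delta = min_image_displacement(pos[iu] - pos[ju], config.box_length)
    return np.hypot(delta[:, 0], delta[:, 1])


def find_clusters(config: Configuration, cutoff: float) -> ClusterAssignment:
    """Connected components at minimum-image distance <= cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if cutoff >= config.box_length / 2:
        raise ValueError("cutoff must be < box_length/2 (minimum image ambiguous)")
    n = config.n
    tree = cKDTree(config.positions, boxsize=config.box_length)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs):
        data = np.ones(len(pairs))
        adj = coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
        _, raw = connected_components(adj, directed=False)
    else:
        raw = np.arange(n)
    return ClusterAssignment(_canonicalize(raw), cutoff=cutoff, time=config.time)


def cluster_series(traj: Trajectory, cutoff: float) -> ClusterSeries:
    """Per-frame cluster statistics with identity tracking.

    A cluster at frame k+1 inherits the identity of the frame-k cluster
    sharing the largest member overlap (ties broken toward the lower
    canonical label).  A frame-k cluster whose members split over several
    frame-(k+1) clusters logs a fission; a frame-(k+1) cluster drawing
    members from several frame-k clusters logs a fusion.
    """
    if traj.n_frames < 1:
        raise ValueError("trajectory must have at least one frame")
    assigns = [find_clusters(traj.frame(i), cutoff) for i in range(traj.n_frames)]
    n_clusters = np.array([a.n_clusters for a in assigns])
    n_max = np.array([int(a.sizes.max()) for a in assigns])
    mean_size = traj.n / n_clusters.astype(float)
    tracking: List[Dict[int, int]] = []
    events: List[Tuple[int, str, str]] = []
    for k in range(len(assigns) - 1):
        prev, cur = assigns[k], assigns[k + 1]
        mapping: Dict[int, int] = {}
        parents_of: Dict[int, set] = {}
        for lab in range(cur.n_clusters):
            members = cur.members(lab)
            overlap = np.bincount(prev.labels[members], minlength=prev.n_clusters)
            parent = int(np.argmax(overlap))  # argmax takes the lowest label on ties
            mapping[lab] = parent
            parents_of[lab] = set(np.flatnonzero(overlap > 0).tolist())
        tracking.append(mapping)
        for lab, parents in parents_of.items():
            if len(parents) > 1:
                events.append((k, "fusion", f"{sorted(parents)} -> {lab}"))
        children: Dict[int, List[int]] = {}
        for lab, parents in parents_of.items():
            for p in parents:
                children.setdefault(p, []).append(lab)
        for p, childs in children.items():
            if len(childs) > 1:
                events.append((k, "fission", f"{p} -> {sorted(childs)}"))
    return ClusterSeries(
        times=traj.times.copy(),
        n_clusters=n_clusters,
        n_max=n_max,
        mean_size=mean_size,
        assignments=assigns,
        cutoff=cutoff,
        tracking=tracking,
        events=events,
    )


def fit_power_law(
    series: ClusterSeries, fit_range: Tuple[float, float]
) -> PowerLawFit:
    """Unweighted least-squares line in (log t, log N_max) over ``fit_range``.

    The fit range is a required input: growth exponents depend on the
    window, so it is recorded in the result rather than guessed.
    """
    lo, hi = fit_range
    sel = (series.times >= lo) & (series.times <= hi) & (series.times > 0)
    t = series.times[sel]
    y = series.n_max[sel].astype(float)
    if t.size < 5:
        raise ValueError("need at least 5 frames with t > 0 inside fit_range")
    if np.any(y <= 0):
        raise ValueError("N_max must be positive inside fit_range")
    logt, logy = np.log(t), np.log(y)
    slope, intercept = np.polyfit(logt, logy, 1)
    resid = logy - (slope * logt + intercept)
    return PowerLawFit(
        exponent=float(slope),
        prefactor=float(np.exp(intercept)),
        fit_range=(float(lo), float(hi)),
        residual=float(np.sqrt(np.mean(resid**2))),
        n_points=int(t.size),
    )


def neighbor_counts(config: Configuration, cutoff: float) -> np.ndarray:
    """Number of inclusions within ``cutoff`` of each inclusion (self excluded)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if cutoff >= config.box_length / 2:
        raise ValueError("cutoff must be < box_length/2 (minimum image ambiguous)")
    tree = cKDTree(config.positions, boxsize=config.box_length)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    counts = np.zeros(config.n, dtype=np.int64)
    if len(pairs):
        np.add.at(counts, pairs[:, 0], 1)
        np.add.at(counts, pairs[:, 1], 1)
    return counts
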