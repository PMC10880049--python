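"""Structural observables: 2D radial distribution function and tilt order."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .core import Configuration, Trajectory
from .clusters import min_image_distances

__all__ = ["RDFResult", "TiltSeries", "rdf_2d", "first_peak", "tilt_series"]


@dataclass
class RDFResult:
    """2D radial distribution function g(r)."""

    bin_centers: np.ndarray  # nm
    g: np.ndarray
    bin_width: float
    r_max: float
    n_frames_averaged: int

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if np.any(self.g < 0):
            raise ValueError("g must be non-negative")
        if np.any(np.diff(self.bin_centers) <= 0):
            raise ValueError("bin_centers must be strictly increasing")


@dataclass
class TiltSeries:
    """Per-frame average |cos(theta)| between inclusion axes and the normal."""

    times: np.ndarray
    mean_cos_theta: np.ndarray


def rdf_2d(
    traj: Union[Trajectory, Configuration],
    bin_width: float = 0.05,
    r_max: Optional[float] = None,
    frame_indices: Optional[Sequence[int]] = None,
) -> RDFResult:
    """2D radial distribution function under the minimum-image convention.

    Pair distances are histogrammed per frame and normalized by the
    ideal-gas expectation per inclusion, rho * pi * ((r + dr)^2 - r^2),
    with rho = N / L^2, then averaged over frames; g -> 1 at large r for
    homogeneous systems.

    ``r_max`` defaults to box_length / 2 (the largest unambiguous
    minimum-image distance along an axis).  ``frame_indices`` restricts the
    averaging window (e.g. late frames only).
    """
    if isinstance(traj, Configuration):
        frames = [traj]
        box = traj.box_length
    else:
        idx = range(traj.n_frames) if frame_indices is None else frame_indices
        frames = [traj.frame(i) for i in idx]
        box = traj.box_length
    if not frames:
        raise ValueError("no frames to average")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if r_max is None:
        r_max = box / 2.0
    if r_max > box / 2.0 + 1e-12:
        raise ValueError("r_max must be <= box_length/2")

    edges = np.arange(0.0, r_max + bin_width, bin_width)
    edges = edges[edges <= r_max + 1e-12]
    if len(edges) < 2:
        raise ValueError("r_max must cover at least one bin")
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell_area = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)

    g_acc = np.zeros(len(centers))
    for cfg in frames:
        n = cfg.n
        if n < 2:
            raise ValueError("need at least 2 inclusions for an RDF")
        dists = min_image_distances(cfg)
        hist, _ = np.histogram(dists, bins=edges)
        rho = n / box**2
        # pairs counted once; per-inclusion neighbor count is 2*hist/n
        g_acc += (2.0 * hist / n) / (rho * shell_area)
    return RDFResult(
        bin_centers=centers,
        g=g_acc / len(frames),
        bin_width=bin_width,
        r_max=float(r_max),
        n_frames_averaged=len(frames),
    )


def first_peak(
    rdf: RDFResult,
    r_min_search: float = 0.0,
    prominence: float = 1.2,
) -> Optional[float]:
    """Bin center of the first local maximum of g with g >= ``prominence``,
    searched from ``r_min_search`` upward.  Returns None if no peak exists
    (e.g. flat g = 1)."""
    g = rdf.g
    r = rdf.bin_centers
    if g.size == 0:
        raise ValueError("empty RDF")
    for i in range(g.size):
        if r[i] < r_min_search or g[i] < prominence:
            continue
        left = g[i - 1] if i > 0 else -np.inf
        right = g[i + 1] if i < g.size - 1 else -np.inf
        if g[i] >= left and g[i] >= right:
            return float(r[i])
    return None


def tilt_series(
    orientations: np.ndarray,
    membrane_normal: Sequence[float] = (0.0, 0.0, 1.0),
    times: Optional[np.ndarray] = None,
    tol: float = 1e-6,
) -> TiltSeries:
    """Per-frame mean of |cos(theta)| between inclusion axes and the normal.

    Folding by the absolute value makes up/down axis orientations
    equivalent (appropriate for inclusions symmetric under flipping).
    """
    ori = np.asarray(orientations, dtype=float)
    if ori.ndim != 3 or ori.shape[2] != 3:
        raise ValueError("orientations must have shape (n_frames, n, 3)")
    norms = np.linalg.norm(ori, axis=-1)
    if np.any(np.abs(norms - 1.0) > tol):
        raise ValueError(f"orientation vectors must be unit norm within {tol}")
    normal = np.asarray(membrane_normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    cos = np.abs(ori @ normal)
    mean = cos.mean(axis=1)
    if times is None:
        times = np.arange(ori.shape[0], dtype=float)
    return TiltSeries(times=np.asarray(times, dtype=float), mean_cos_theta=mean)
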