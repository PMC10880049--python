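"""Synthetic configurations and Brownian aggregation trajectories.

The generator is a kinetic stand-in for coarse-grained MD of membrane
inclusions (e.g. carbon-nanotube porins in a lipid bilayer): ~100
inclusions of radius ~1.05 nm in a ~70 nm periodic box, diffusing with
cluster-size-dependent mobility given by membrane hydrodynamics
(HPW-Petrov-Schwille), aggregating irreversibly into clusters whose
members sit on a triangular lattice at the lipid-separated packing
distance (~2.1 nm).  There are no lipid particles, no force field and no
energy function; clusters move as rigid bodies with a single cluster-level
diffusion coefficient, and small clusters never dissociate.

When ``finite_size_effects`` is enabled (the default) the generating
mobility of each cluster is the model value minus the periodic-box
self-mobility correction, emulating what a periodic simulation box does to
measured diffusion coefficients; the analysis pipeline adds the same
correction back.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import Configuration, Trajectory, min_image_displacement, wrap_positions
from .diffusion import HydroParams, effective_radius, hpw_ps_model, periodic_sd_correction

__all__ = [
    "SimParams",
    "TiltParams",
    "make_grid_configuration",
    "make_hex_cluster",
    "hex_lattice_sites",
    "simulate_aggregation",
    "simulate_fixed_clusters",
    "simulate_tilt",
]


@dataclass(frozen=True)
class SimParams:
    """Parameters of the synthetic Brownian-aggregation generator.

    Lengths in nm, times in ns, viscosities in SI.  The defaults are the
    standard system: 100 inclusions of radius 1.05 nm in a 70 nm periodic
    box at 300 K, clusters held at 2.1 nm nearest-neighbour packing and
    fused irreversibly at a 2.25 nm center-to-center cutoff, with membrane
    viscosity 4.5e-11 Pa·s·m.
    """

    n_inclusions: int = 100
    box_length: float = 70.0
    inclusion_radius: float = 1.05
    eta_m: float = 4.5e-11
    eta_w: float = 7e-4
    temperature: float = 300.0
    time_step: float = 0.1
    n_frames: int = 1000
    frame_interval: float = 0.5
    fusion_cutoff: float = 2.25
    packing_distance: float = 2.1
    seed: int = 0
    solvent_height: Optional[float] = None
    finite_size_effects: bool = True

    def __post_init__(self) -> None:
        if self.box_length <= 0:
            raise ValueError("box_length must be positive")
        if self.eta_m <= 0 or self.eta_w <= 0:
            raise ValueError("viscosities must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")
        if self.inclusion_radius <= 0:
            raise ValueError("inclusion_radius must be positive")
        if not (0 <= self.fusion_cutoff < self.box_length / 2):
            raise ValueError("fusion_cutoff must be in [0, box_length/2)")
        if self.packing_distance <= 0:
            raise ValueError("packing_distance must be positive")
        if self.time_step <= 0 or self.frame_interval <= 0:
            raise ValueError("time_step and frame_interval must be positive")
        if self.n_frames < 1 or self.n_inclusions < 1:
            raise ValueError("n_frames and n_inclusions must be >= 1")
        stride = self.frame_interval / self.time_step
        if abs(stride - round(stride)) > 1e-9 or round(stride) < 1:
            raise ValueError("frame_interval must be a positive integer multiple of time_step")

    @property
    def record_stride(self) -> int:
        return int(round(self.frame_interval / self.time_step))

    @property
    def hydro(self) -> HydroParams:
        # HydroParams requires T > 0; the zero-temperature freeze is handled
        # by the simulators directly (all mobilities are zero).
        return HydroParams(
            eta_m=self.eta_m, eta_w=self.eta_w, temperature=max(self.temperature, 1e-300)
        )


@dataclass(frozen=True)
class TiltParams:
    """Mean-reverting tilt dynamics: cos(theta) fluctuates around ``mean_cos``
    with the given relaxation time (ns) and stationary standard deviation
    ``noise_amplitude``."""

    mean_cos: float = 0.9
    relaxation_time: float = 10.0
    noise_amplitude: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.mean_cos <= 1:
            raise ValueError("mean_cos must be in (0, 1]")
        if self.relaxation_time <= 0:
            raise ValueError("relaxation_time must be positive")
        if self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be non-negative")


# ---------------------------------------------------------------------------
# Configuration builders
# ---------------------------------------------------------------------------


def make_grid_configuration(n_side: int, box_length: float) -> Configuration:
    """Square grid of ``n_side**2`` positions, cell-centered, spacing L/n_side."""
    if n_side < 1:
        raise ValueError("n_side must be >= 1")
    if box_length <= 0:
        raise ValueError("box_length must be positive")
    a = box_length / n_side
    coords = (np.arange(n_side) + 0.5) * a
    xx, yy = np.meshgrid(coords, coords, indexing="ij")
    pos = np.column_stack([xx.ravel(), yy.ravel()])
    return Configuration(pos, box_length, time=0.0)


def hex_lattice_sites(n: int, spacing: float) -> np.ndarray:
    """``n`` triangular-lattice sites closest to the origin, centroid-shifted to 0.

    Nearest-neighbour distance equals ``spacing``.  Site selection is
    deterministic: sorted by (distance to origin, angle, index).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    m = int(math.ceil(math.sqrt(n))) + 2
    i, j = np.meshgrid(np.arange(-m, m + 1), np.arange(-m, m + 1), indexing="ij")
    x = spacing * (i + 0.5 * j).ravel()
    y = spacing * (math.sqrt(3.0) / 2.0) * j.ravel()
    pts = np.column_stack([x, y])
    r = np.hypot(pts[:, 0], pts[:, 1])
    ang = np.arctan2(pts[:, 1], pts[:, 0])
    order = np.lexsort((np.arange(len(pts)), ang, np.round(r, 9)))
    sel = pts[order[:n]]
    return sel - sel.mean(axis=0)


def make_hex_cluster(n_inclusions: int, spacing: float, box_length: float) -> Configuration:
    """Hexagonally packed cluster of ``n_inclusions`` sites centered in the box."""
    if box_length <= 0:
        raise ValueError("box_length must be positive")
    sites = hex_lattice_sites(n_inclusions, spacing)
    extent = float(np.max(np.hypot(sites[:, 0], sites[:, 1]))) if n_inclusions > 1 else 0.0
    if 2 * extent + spacing >= box_length:
        raise ValueError(
            f"cluster of {n_inclusions} sites at spacing {spacing} nm does not fit "
            f"in a {box_length} nm box"
        )
    pos = wrap_positions(sites + box_length / 2.0, box_length)
    return Configuration(pos, box_length, time=0.0)


# ---------------------------------------------------------------------------
# Brownian dynamics with irreversible fusion
# ---------------------------------------------------------------------------


def _cluster_mobility(size: int, params: SimParams, delta: float) -> float:
    """Generating diffusion coefficient (nm^2/ns) for a cluster of ``size``."""
    if params.temperature == 0:
        return 0.0
    r_eff = effective_radius(size, params.inclusion_radius)
    d = hpw_ps_model(r_eff, params.hydro)
    d -= delta
    if d <= 0:
        raise ValueError(
            f"finite-size correction exceeds model mobility for cluster size {size}; "
            "box too small for these hydrodynamic parameters"
        )
    return d


def _finite_size_delta(params: SimParams) -> float:
    if not params.finite_size_effects or params.temperature == 0:
        return 0.0
    return periodic_sd_correction(params.box_length, params.solvent_height, params.hydro)


def _check_step_safety(d_max: float, params: SimParams) -> None:
    typical = math.sqrt(4.0 * d_max * params.time_step)
    if typical > params.box_length / 4.0:
        raise ValueError(
            "time_step unsafe: typical displacement "
            f"{typical:.3g} nm exceeds box_length/4 = {params.box_length / 4:.3g} nm"
        )


class _ClusterState:
    """Mutable cluster bookkeeping for the steppers.

    Unwrapped member coordinates are kept consistent within each cluster;
    cluster identity is its minimum member index.
    """

    def __init__(self, unwrapped: np.ndarray, labels: np.ndarray, params: SimParams, delta: float):
        self.params = params
        self.delta = delta
        self.unwrapped = unwrapped.copy()
        self.box = params.box_length
        self.members: Dict[int, np.ndarray] = {}
        self._d_cache: Dict[int, float] = {}
        for lab in np.unique(labels):
            mem = np.flatnonzero(labels == lab)
            self.members[int(mem.min())] = mem
        self.scales = self._compute_scales()

    def mobility(self, size: int) -> float:
        if size not in self._d_cache:
            self._d_cache[size] = _cluster_mobility(size, self.params, self.delta)
        return self._d_cache[size]

    def _compute_scales(self) -> Dict[int, float]:
        dt = self.params.time_step
        return {
            key: math.sqrt(2.0 * self.mobility(len(mem)) * dt)
            for key, mem in self.members.items()
        }

    @property
    def n_clusters(self) -> int:
        return len(self.members)

    def step(self, noise_row: np.ndarray) -> None:
        """Advance one time step; noise_row has shape (n, 2), indexed by
        inclusion id so the result is independent of iteration order."""
        for key, mem in self.members.items():
            self.unwrapped[mem] += self.scales[key] * noise_row[key]

    def wrapped(self) -> np.ndarray:
        return wrap_positions(self.unwrapped, self.box)

    def fuse_contacts(self, cutoff: float) -> int:
        """Merge all clusters with any cross-pair within ``cutoff``; returns
        the number of fusion events (merges)."""
        from scipy.spatial import cKDTree

        w = self.wrapped()
        tree = cKDTree(w, boxsize=self.box)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        if len(pairs) == 0:
            return 0
        owner = np.empty(self.unwrapped.shape[0], dtype=np.int64)
        for key, mem in self.members.items():
            owner[mem] = key
        parent = {k: k for k in self.members}

        def find(k: int) -> int:
            while parent[k] != k:
                parent[k] = parent[parent[k]]
                k = parent[k]
            return k

        merges = 0
        for a, b in pairs:
            ra, rb = find(int(owner[a])), find(int(owner[b]))
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
                merges += 1
        if merges == 0:
            return 0
        groups: Dict[int, List[int]] = {}
        for k in self.members:
            groups.setdefault(find(k), []).append(k)
        for root, keys in groups.items():
            if len(keys) == 1:
                continue
            self._merge(sorted(keys))
        self.scales = self._compute_scales()
        return merges

    def _merge(self, keys: List[int]) -> None:
        """Merge clusters, repacking members on a triangular lattice at the
        packing distance around the merged center of mass (COM preserved)."""
        ref = keys[0]
        ref_com_u = self.unwrapped[self.members[ref]].mean(axis=0)
        ref_com_w = wrap_positions(ref_com_u, self.box)
        total = 0
        weighted = np.zeros(2)
        all_members = []
        for k in keys:
            mem = self.members[k]
            com_u = self.unwrapped[mem].mean(axis=0)
            com_w = wrap_positions(com_u, self.box)
            rel = min_image_displacement(com_w - ref_com_w, self.box)
            shift = (ref_com_u + rel) - com_u
            self.unwrapped[mem] += shift
            weighted += (ref_com_u + rel) * len(mem)
            total += len(mem)
            all_members.append(mem)
        merged_com = weighted / total
        members = np.concatenate(all_members)
        members.sort()
        sites = hex_lattice_sites(len(members), self.params.packing_distance)
        self.unwrapped[members] = merged_com + sites
        for k in keys[1:]:
            del self.members[k]
        self.members[keys[0]] = members


def _noise_stream(seed: int, n: int, chunk: int = 2048):
    """Yields (chunk, n, 2) standard-normal blocks from a counter-based
    Philox stream keyed on the root seed; block/row layout is fixed so the
    draw consumed by inclusion slot i at step t never depends on cluster
    bookkeeping or iteration order."""
    bitgen = np.random.Philox(key=int(seed))
    rng = np.random.Generator(bitgen)
    while True:
        yield rng.standard_normal((chunk, n, 2))


def _labels_at_cutoff(config: Configuration, cutoff: float) -> np.ndarray:
    from .clusters import find_clusters

    if cutoff <= 0:
        return np.arange(config.n)
    return find_clusters(config, cutoff).labels


def _run_dynamics(
    initial: Configuration,
    params: SimParams,
    labels: np.ndarray,
    fuse: bool,
) -> Trajectory:
    delta = _finite_size_delta(params)
    state = _ClusterState(
        np.asarray(initial.positions, dtype=float), labels, params, delta
    )
    if params.temperature > 0:
        d_max = state.mobility(1)
        _check_step_safety(d_max, params)

    stride = params.record_stride
    n_steps = (params.n_frames - 1) * stride
    n = initial.n
    times = params.frame_interval * np.arange(params.n_frames)
    wrapped = np.empty((params.n_frames, n, 2))
    unwrapped = np.empty((params.n_frames, n, 2))
    wrapped[0] = state.wrapped()
    unwrapped[0] = state.unwrapped

    stream = _noise_stream(params.seed, n)
    chunk = next(stream)
    ci = 0
    frame = 1
    for step in range(n_steps):
        if ci >= chunk.shape[0]:
            chunk = next(stream)
            ci = 0
        state.step(chunk[ci])
        ci += 1
        if fuse and params.fusion_cutoff > 0:
            state.fuse_contacts(params.fusion_cutoff)
        if (step + 1) % stride == 0:
            wrapped[frame] = state.wrapped()
            unwrapped[frame] = state.unwrapped
            frame += 1
    return Trajectory(
        times=times,
        wrapped=wrapped,
        unwrapped=unwrapped,
        box_length=params.box_length,
        params=params,
    )


def simulate_aggregation(initial: Configuration, params: SimParams) -> Trajectory:
    """Overdamped 2D Brownian dynamics with irreversible cluster fusion.

    Connected components at ``fusion_cutoff`` move as rigid bodies; a
    cluster of size s receives isotropic Gaussian displacements of variance
    ``2 D(s) dt`` per coordinate, with D(s) the HPW-PS mobility of the
    area-equivalent disk (minus the periodic-box correction when
    ``finite_size_effects`` is set).  Clusters coming within
    ``fusion_cutoff`` fuse irreversibly and are repacked on a triangular
    lattice at ``packing_distance`` about the merged center of mass.
    """
    if initial.n != params.n_inclusions:
        params = replace(params, n_inclusions=initial.n)
    if abs(initial.box_length - params.box_length) > 1e-9:
        raise ValueError("initial configuration box_length differs from params.box_length")
    labels = _labels_at_cutoff(initial, params.fusion_cutoff)
    return _run_dynamics(initial, params, labels, fuse=True)


def simulate_fixed_clusters(cluster_sizes: Sequence[int], params: SimParams) -> Trajectory:
    """Same dynamics as :func:`simulate_aggregation` with fusion disabled.

    Builds one hexagonally packed cluster per entry of ``cluster_sizes``
    (nearest-neighbour spacing = ``packing_distance``) on a coarse grid of
    well-separated slots; memberships are constant for the whole run.
    """
    sizes = [int(s) for s in cluster_sizes]
    if any(s < 1 for s in sizes):
        raise ValueError("cluster sizes must be >= 1")
    k = len(sizes)
    slots_per_side = int(math.ceil(math.sqrt(k)))
    slot = params.box_length / slots_per_side
    positions = np.empty((sum(sizes), 2))
    labels = np.empty(sum(sizes), dtype=np.int64)
    idx = 0
    for c, s in enumerate(sizes):
        sites = hex_lattice_sites(s, params.packing_distance)
        extent = float(np.max(np.hypot(sites[:, 0], sites[:, 1]))) if s > 1 else 0.0
        if 2 * extent + params.packing_distance >= slot:
            raise ValueError(
                f"cluster of size {s} does not fit in its {slot:.3g} nm slot; "
                "fewer/smaller clusters or a larger box required"
            )
        center = np.array(
            [(c % slots_per_side + 0.5) * slot, (c // slots_per_side + 0.5) * slot]
        )
        positions[idx : idx + s] = center + sites
        labels[idx : idx + s] = c
        idx += s
    initial = Configuration(
        wrap_positions(positions, params.box_length), params.box_length, time=0.0
    )
    params = replace(params, n_inclusions=initial.n)
    return _run_dynamics(initial, params, labels, fuse=False)


# ---------------------------------------------------------------------------
# Tilt dynamics
# ---------------------------------------------------------------------------


def simulate_tilt(
    n_inclusions: int,
    n_frames: int,
    tilt: TiltParams,
    frame_interval: float = 1.0,
) -> np.ndarray:
    """Per-inclusion axis unit vectors with mean-reverting tilt.

    cos(theta) of each inclusion follows an exactly discretized
    Ornstein-Uhlenbeck process around ``mean_cos`` (stationary standard
    deviation ``noise_amplitude``, relaxation time in ns), reflected into
    [-1, 1]; azimuths are independent uniform angles.  Returns an array of
    shape (n_frames, n_inclusions, 3); the membrane normal is z.
    """
    if n_inclusions < 1 or n_frames < 1:
        raise ValueError("n_inclusions and n_frames must be >= 1")
    rng = np.random.Generator(np.random.Philox(key=int(tilt.seed)))
    decay = math.exp(-frame_interval / tilt.relaxation_time)
    kick = tilt.noise_amplitude * math.sqrt(max(1.0 - decay**2, 0.0))
    c = np.full(n_inclusions, tilt.mean_cos)
    out = np.empty((n_frames, n_inclusions, 3))
    for t in range(n_frames):
        if t > 0 and kick > 0:
            c = tilt.mean_cos + (c - tilt.mean_cos) * decay + kick * rng.standard_normal(
                n_inclusions
            )
            # reflect into [-1, 1] (triangle wave of period 4)
            t4 = np.mod(c + 1.0, 4.0)
            c = np.where(t4 <= 2.0, t4 - 1.0, 3.0 - t4)
        phi = rng.uniform(0.0, 2.0 * math.pi, size=n_inclusions)
        s = np.sqrt(np.clip(1.0 - c**2, 0.0, None))
        out[t, :, 0] = s * np.cos(phi)
        out[t, :, 1] = s * np.sin(phi)
        out[t, :, 2] = c
    return out
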