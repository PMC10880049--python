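"""Membrane-hydrodynamic diffusion analysis.

Estimates per-cluster-size lateral diffusion coefficients from mean-squared
displacements (MSD), corrects them for the finite periodic box, and fits
membrane-hydrodynamics models to recover the membrane surface viscosity.

Models
------
Saffman-Delbrück (SD) [Saffman & Delbrück, PNAS 72:3111 (1975)]:
a cylinder of radius R spanning a thin membrane of surface viscosity
``eta_m`` between two semi-infinite solvents of viscosity ``eta_w`` diffuses
with

    D = kT / (4 pi eta_m) * (ln(2/eps) - gamma),    eps = R / l_SD,

where ``l_SD = eta_m / (2 eta_w)`` is the SD length and gamma is the
Euler-Mascheroni constant.  Valid for eps << 1.

Hughes-Pailthorpe-White / Petrov-Schwille (HPW-PS): the HPW solution
[Hughes, Pailthorpe & White, JFM 110:349 (1981)] covers all inclusion
sizes; Petrov & Schwille [Biophys J 94:L41 (2008)] give the closed-form
interpolation used here,

    D = kT/(4 pi eta_m) * [ln(2/eps) - gamma + 4 eps/pi - (eps^2/2) ln(2/eps)]
        / [1 - (eps^3/pi) ln(2/eps) + c1 eps^b1 / (1 + c2 eps^b2)],

with fitted constants b1 = 2.74819, b2 = 0.61465, c1 = 0.73761,
c2 = 0.52119.  It reduces to SD as eps -> 0 and crosses over to
bulk-dominated ~1/R behaviour at large eps.

The finite-size correction is the periodic Saffman-Delbrück self-mobility
correction (the membrane analogue of the Yeh-Hummer cubic-box correction;
see Vögele & Hummer, J Phys Chem B 120:8722 (2016) and Vögele, Köfinger &
Hummer, PRL 120:268104 (2018)), evaluated here as a k-space lattice sum —
see :func:`periodic_sd_correction`.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import quad
from scipy.optimize import minimize_scalar

from .core import Trajectory
from .units import KB, M_PER_NM, d_si_to_nm2_ns

__all__ = [
    "HydroParams",
    "MSDCurve",
    "DiffusionRecord",
    "ViscosityFit",
    "effective_radius",
    "sd_model",
    "hpw_ps_model",
    "periodic_sd_correction",
    "finite_size_correction",
    "msd_by_size",
    "estimate_D",
    "fit_viscosity",
]

logger = logging.getLogger(__name__)

EULER_GAMMA = float(np.euler_gamma)

# Petrov-Schwille (2008) interpolation constants for the HPW solution.
PS_B1 = 2.74819
PS_B2 = 0.61465
PS_C1 = 0.73761
PS_C2 = 0.52119


@dataclass(frozen=True)
class HydroParams:
    """Membrane/solvent hydrodynamic parameters.

    Parameters
    ----------
    eta_m
        Membrane surface viscosity, Pa·s·m.
    eta_w
        Bulk solvent viscosity (one side), Pa·s.
    temperature
        Temperature, K.
    """

    eta_m: float
    eta_w: float
    temperature: float

    def __post_init__(self) -> None:
        if self.eta_m <= 0 or self.eta_w <= 0 or self.temperature <= 0:
            raise ValueError("eta_m, eta_w and temperature must all be positive")

    @property
    def thermal_energy(self) -> float:
        """k_B T in J."""
        return KB * self.temperature

    @property
    def sd_length(self) -> float:
        """Saffman-Delbrück length l_SD = eta_m / (2 eta_w), in m."""
        return self.eta_m / (2.0 * self.eta_w)

    @property
    def sd_length_nm(self) -> float:
        return self.sd_length / M_PER_NM


@dataclass
class MSDCurve:
    """Mean-squared displacement versus lag time for one cluster size."""

    lags: np.ndarray  # ns
    msd: np.ndarray  # nm^2
    cluster_size: int
    n_samples: np.ndarray  # per-lag count of (cluster, time-origin) pairs

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_samples = np.asarray(self.n_samples, dtype=float)
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.msd < 0):
            raise ValueError("msd must be non-negative")


@dataclass
class DiffusionRecord:
    """One row of the size-resolved diffusion table feeding the viscosity fit."""

    cluster_size: int
    effective_radius: float  # nm
    d_pbc: float  # nm^2/ns, as measured in the periodic box
    d_corrected: float  # nm^2/ns, finite-size corrected
    sigma: float  # nm^2/ns, standard error

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class ViscosityFit:
    """Result of a one-parameter membrane-viscosity fit."""

    eta_m_hat: float  # Pa·s·m
    chi2_reduced: float
    model_name: str
    n_points: int
    chi2: float = field(default=float("nan"))


def effective_radius(cluster_size: int, r_cnt: float = 1.05) -> float:
    """Area-equivalent disk radius of a cluster of ``cluster_size`` inclusions.

    A compact cluster of s disks of radius ``r_cnt`` covers s times the
    area, so the shape-independent effective radius is ``r_cnt * sqrt(s)``.
    """
    if cluster_size < 1:
        raise ValueError("cluster_size must be >= 1")
    if r_cnt <= 0:
        raise ValueError("r_cnt must be positive")
    return float(r_cnt * math.sqrt(cluster_size))


def sd_model(radius: float, hydro: HydroParams) -> float:
    """Saffman-Delbrück diffusion coefficient, nm^2/ns.

    ``radius`` in nm.  Warns (does not fail) outside the model's validity
    domain R >= l_SD.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    eps = radius * M_PER_NM / hydro.sd_length
    if eps >= 1.0:
        warnings.warn(
            "Saffman-Delbrück model evaluated outside its validity domain "
            f"(R = {radius} nm >= l_SD = {hydro.sd_length_nm:.3g} nm)",
            stacklevel=2,
        )
    d_si = hydro.thermal_energy / (4.0 * math.pi * hydro.eta_m) * (
        math.log(2.0 / eps) - EULER_GAMMA
    )
    return d_si_to_nm2_ns(d_si)


def hpw_ps_model(radius: float, hydro: HydroParams) -> float:
    """HPW diffusion coefficient via the Petrov-Schwille interpolation, nm^2/ns."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    eps = radius * M_PER_NM / hydro.sd_length
    ln_term = math.log(2.0 / eps)
    numer = ln_term - EULER_GAMMA + 4.0 * eps / math.pi - (eps**2 / 2.0) * ln_term
    denom = 1.0 - (eps**3 / math.pi) * ln_term + PS_C1 * eps**PS_B1 / (
        1.0 + PS_C2 * eps**PS_B2
    )
    d_si = hydro.thermal_energy / (4.0 * math.pi * hydro.eta_m) * numer / denom
    return d_si_to_nm2_ns(d_si)


def _mobility_kernel(k: np.ndarray, hydro: HydroParams, solvent_height: Optional[float]) -> np.ndarray:
    """Scalar in-plane mobility kernel mu(k) = 1/(eta_m k^2 + 2 eta_w k coth(kH)).

    k in 1/m.  ``solvent_height`` H (m) is the solvent slab thickness on each
    side of the membrane; ``None`` means semi-infinite solvent (coth -> 1).
    """
    k = np.asarray(k, dtype=float)
    if solvent_height is None:
        screen = 2.0 * hydro.eta_w * k
    else:
        kh = np.clip(k * solvent_height, 1e-12, 700.0)
        screen = 2.0 * hydro.eta_w * k / np.tanh(kh)
    return 1.0 / (hydro.eta_m * k**2 + screen)


@lru_cache(maxsize=128)
def _periodic_sd_correction_si(
    box_length_m: float,
    solvent_height_m: Optional[float],
    eta_m: float,
    eta_w: float,
    temperature: float,
    n_modes: int,
) -> float:
    hydro = HydroParams(eta_m=eta_m, eta_w=eta_w, temperature=temperature)
    dk = 2.0 * math.pi / box_length_m
    k_max = n_modes * dk
    k_damp = k_max / 3.0  # Gaussian spectral damp; boundary modes weigh e^-9

    n = np.arange(-n_modes, n_modes + 1)
    nx, ny = np.meshgrid(n, n, indexing="ij")
    kmag = dk * np.sqrt(nx.astype(float) ** 2 + ny.astype(float) ** 2)
    mask = kmag > 0
    kk = kmag[mask]
    weight = np.exp(-((kk / k_damp) ** 2))
    lattice_sum = float(np.sum(_mobility_kernel(kk, hydro, solvent_height_m) * weight))
    lattice_sum /= box_length_m**2

    def integrand(k: float) -> float:
        return (
            k
            * float(_mobility_kernel(np.array([k]), hydro, solvent_height_m)[0])
            * math.exp(-((k / k_damp) ** 2))
        )

    integral, _ = quad(integrand, 0.0, k_max, limit=400, epsabs=0.0, epsrel=1e-10)
    integral /= 2.0 * math.pi

    # Transverse projector: each diagonal component of the isotropic
    # self-mobility tensor picks up half of the scalar kernel in 2D.
    return 0.5 * hydro.thermal_energy * (integral - lattice_sum)


def periodic_sd_correction(
    box_length: float,
    solvent_height: Optional[float],
    hydro: HydroParams,
    n_modes: int = 64,
) -> float:
    """Additive finite-size correction Delta = D_infinity - D_pbc, in nm^2/ns.

    Lattice-sum evaluation of the periodic Saffman-Delbrück self-mobility
    correction: the difference between the k-space integral of the membrane
    mobility kernel mu(k) = 1/(eta_m k^2 + 2 eta_w k coth(kH)) and its
    periodic-box lattice sum over k = 2 pi n / L (k = 0 excluded), damped by
    a common Gaussian spectral filter so the UV parts — identical between sum
    and integral — drop out.  This is the membrane analogue of the Yeh-Hummer
    correction for cubic boxes (Vögele & Hummer, J Phys Chem B 2016; Vögele,
    Köfinger & Hummer, PRL 2018).

    The correction is independent of inclusion size, vanishes as the box
    grows, and increases logarithmically once the box side drops below the
    SD length.

    Parameters
    ----------
    box_length
        Lateral box side, nm.
    solvent_height
        Solvent slab thickness on each side of the membrane, nm;
        ``None`` for semi-infinite solvent.
    hydro
        Hydrodynamic parameters (the membrane viscosity used here is the
        assumed/known one; the correction is evaluated at those parameters).
    n_modes
        Lattice-sum cutoff in units of 2 pi / L per axis.
    """
    if box_length <= 0:
        raise ValueError("box_length must be positive")
    if solvent_height is not None and solvent_height <= 0:
        raise ValueError("solvent_height must be positive or None")
    delta_si = _periodic_sd_correction_si(
        box_length * M_PER_NM,
        None if solvent_height is None else solvent_height * M_PER_NM,
        hydro.eta_m,
        hydro.eta_w,
        hydro.temperature,
        n_modes,
    )
    return d_si_to_nm2_ns(delta_si)


def finite_size_correction(
    d_pbc: float,
    box_length: float,
    solvent_height: Optional[float],
    hydro: HydroParams,
    n_modes: int = 64,
) -> float:
    """Convert a periodic-box diffusion coefficient to its infinite-system value.

    Returns ``d_pbc + Delta(box_length, solvent_height, hydro)`` with the
    size-independent additive correction of :func:`periodic_sd_correction`.
    All diffusion coefficients in nm^2/ns.
    """
    if box_length <= 0:
        raise ValueError("geometry must be positive")
    return d_pbc + periodic_sd_correction(box_length, solvent_height, hydro, n_modes=n_modes)


# ---------------------------------------------------------------------------
# MSD estimation
# ---------------------------------------------------------------------------


def msd_by_size(
    traj: Trajectory,
    cutoff: float,
    max_lag: float,
    min_samples: int = 1,
) -> List[MSDCurve]:
    """Size-resolved mean-squared displacements.

    For each cluster size s observed in the trajectory, MSD(tau) is averaged
    over all inclusions, time origins and cluster instances whose cluster
    member set is unchanged over the whole interval [t0, t0 + tau].  The
    per-lag sample count records (cluster instance, time-origin) pairs.

    Parameters
    ----------
    traj
        Trajectory with unwrapped coordinates.
    cutoff
        Cluster-definition cutoff, nm (center-to-center, minimum image).
    max_lag
        Largest lag time, ns.
    min_samples
        Sizes with fewer than this many samples at every lag are dropped
        with a logged warning.
    """
    from .clusters import find_clusters  # local import to avoid cycle

    n_frames, n = traj.n_frames, traj.n
    if n_frames < 2:
        raise ValueError("need at least 2 frames for MSD")
    dt = float(traj.times[1] - traj.times[0])
    if not np.allclose(np.diff(traj.times), dt, rtol=1e-8, atol=1e-12):
        raise ValueError("msd_by_size requires uniformly spaced frames")
    max_lag_frames = int(round(max_lag / dt))
    if max_lag_frames < 1:
        raise ValueError("max_lag shorter than one frame interval")
    max_lag_frames = min(max_lag_frames, n_frames - 1)

    # Per-frame, per-inclusion cluster signature (id of the member set) and size.
    signatures = np.empty((n_frames, n), dtype=np.int64)
    sizes = np.empty((n_frames, n), dtype=np.int64)
    sig_ids: dict = {}
    for t in range(n_frames):
        assign = find_clusters(traj.frame(t), cutoff)
        labels = assign.labels
        for lab in range(labels.max() + 1):
            members = np.flatnonzero(labels == lab)
            key = members.tobytes()
            sid = sig_ids.setdefault(key, len(sig_ids))
            signatures[t, members] = sid
            sizes[t, members] = members.size

    # Membership unchanged over a window  <=>  change-counter constant.
    changes = np.zeros((n_frames, n), dtype=np.int64)
    changes[1:] = np.cumsum(signatures[1:] != signatures[:-1], axis=0)

    u = traj.unwrapped
    observed_sizes = np.unique(sizes)
    size_index = {int(s): i for i, s in enumerate(observed_sizes)}
    n_sizes = len(observed_sizes)
    msd_acc = np.zeros((n_sizes, max_lag_frames + 1))
    count_acc = np.zeros((n_sizes, max_lag_frames + 1))

    for lag in range(1, max_lag_frames + 1):
        persistent = changes[lag:] == changes[:-lag]  # (n_frames-lag, n)
        disp2 = np.sum((u[lag:] - u[:-lag]) ** 2, axis=-1)
        origin_sizes = sizes[:-lag]
        for i, s in enumerate(observed_sizes):
            sel = persistent & (origin_sizes == s)
            msd_acc[i, lag] += float(np.sum(disp2[sel]))
            count_acc[i, lag] += float(np.sum(sel))

    curves: List[MSDCurve] = []
    lags_ns = dt * np.arange(0, max_lag_frames + 1)
    for s in observed_sizes:
        i = size_index[int(s)]
        counts = count_acc[i]
        valid = counts > 0
        valid[0] = True
        if not np.all(valid):
            if np.max(counts[1:]) < min_samples:
                logger.warning("cluster size %d has no persistent interval; omitted", s)
                continue
        with np.errstate(invalid="ignore", divide="ignore"):
            msd = np.where(counts > 0, msd_acc[i] / np.maximum(counts, 1), np.nan)
        msd[0] = 0.0
        keep = ~np.isnan(msd)
        # counts are per (inclusion, origin); convert to (cluster, origin) pairs
        cluster_counts = counts / float(s)
        cluster_counts[0] = np.max(cluster_counts) if cluster_counts.size else 0
        curves.append(
            MSDCurve(
                lags=lags_ns[keep],
                msd=msd[keep],
                cluster_size=int(s),
                n_samples=cluster_counts[keep],
            )
        )
    return curves


def estimate_D(msd: MSDCurve, window: Tuple[float, float] = (5.0, 15.0)) -> Tuple[float, float]:
    """Diffusion coefficient from a weighted linear fit of MSD(tau) in ``window``.

    In 2D, MSD = 4 D tau (+ optional offset); the estimator fits slope and
    intercept and returns ``D = slope / 4`` with a standard error derived
    from the fit covariance.  Per-lag weights use an effective sample count
    that discounts overlapping time origins (n_eff = n_samples / lag_frames),
    with sigma_MSD = MSD / sqrt(n_eff) — the counting error of a mean of
    squared 2D Gaussian displacements.
    """
    lo, hi = window
    sel = (msd.lags >= lo) & (msd.lags <= hi) & (msd.lags > 0)
    if np.count_nonzero(sel) < 3:
        raise ValueError("need at least 3 lags inside the fit window")
    tau = msd.lags[sel]
    y = msd.msd[sel]
    nsamp = msd.n_samples[sel]
    dt_min = float(np.min(np.diff(np.concatenate([[0.0], msd.lags[msd.lags > 0]]))))
    lag_frames = np.maximum(tau / dt_min, 1.0)
    n_eff = np.maximum(nsamp / lag_frames, 1e-12)
    sigma = np.where(y > 0, y / np.sqrt(n_eff), 1.0)
    # all-zero MSD (static data): unweighted exact fit of zeros
    if np.all(y == 0):
        return 0.0, 0.0

    w = 1.0 / sigma**2
    X = np.column_stack([tau, np.ones_like(tau)])
    WX = X * w[:, None]
    cov = np.linalg.inv(X.T @ WX)
    beta = cov @ (WX.T @ y)
    slope = float(beta[0])
    slope_var = float(cov[0, 0])
    return slope / 4.0, math.sqrt(max(slope_var, 0.0)) / 4.0


# ---------------------------------------------------------------------------
# Viscosity fitting
# ---------------------------------------------------------------------------

_MODELS = {"SD": sd_model, "HPW-PS": hpw_ps_model}


def fit_viscosity(
    records: Sequence[DiffusionRecord],
    eta_w: float,
    temperature: float,
    model: str = "HPW-PS",
    eta_bounds: Tuple[float, float] = (1e-13, 1e-8),
) -> ViscosityFit:
    """One-parameter weighted least-squares fit of the membrane viscosity.

    Minimizes chi^2(eta_m) = sum_i [(D_i - D_model(R_i; eta_m)) / sigma_i]^2
    over ``eta_m`` (bounded scalar minimization on log eta_m, relative
    tolerance 1e-6), using the finite-size-corrected coefficients
    ``d_corrected``.  Reports the minimizer and the reduced chi-square
    chi2 / (n_points - 1).
    """
    model = model.upper().replace("_", "-")
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}; choose SD or HPW-PS")
    if len(records) < 2:
        raise ValueError("need at least 2 diffusion records")
    radii = np.array([r.effective_radius for r in records], dtype=float)
    if np.allclose(radii, radii[0]):
        raise ValueError("degenerate input: all effective radii are equal")
    d = np.array([r.d_corrected for r in records], dtype=float)
    sig = np.array([r.sigma for r in records], dtype=float)
    if np.any(sig <= 0):
        raise ValueError("all sigmas must be positive")
    model_fn = _MODELS[model]

    def chi2(log_eta: float) -> float:
        hydro = HydroParams(eta_m=math.exp(log_eta), eta_w=eta_w, temperature=temperature)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pred = np.array([model_fn(r, hydro) for r in radii])
        return float(np.sum(((d - pred) / sig) ** 2))

    res = minimize_scalar(
        chi2,
        bounds=(math.log(eta_bounds[0]), math.log(eta_bounds[1])),
        method="bounded",
        options={"xatol": 1e-7},
    )
    nu = len(records) - 1
    return ViscosityFit(
        eta_m_hat=float(math.exp(res.x)),
        chi2=float(res.fun),
        chi2_reduced=float(res.fun) / nu,
        model_name=model,
        n_points=len(records),
    )
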