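"""End-to-end pipeline driver and the viscosity-recovery experiment.

``run_pipeline`` composes the full analysis — simulate (or load) a
trajectory, identify clusters at one or more cutoffs, quantify growth,
compute the RDF and tilt order, extract size-resolved diffusion
coefficients, and fit the membrane viscosity — writing tidy CSVs and a
deterministic JSON summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import __version__
from .clusters import cluster_series, fit_power_law
from .core import Trajectory
from .diffusion import (
    DiffusionRecord,
    HydroParams,
    effective_radius,
    estimate_D,
    finite_size_correction,
    fit_viscosity,
    msd_by_size,
    periodic_sd_correction,
)
from .io import read_config, read_trajectory, write_trajectory
from .structure import first_peak, rdf_2d, tilt_series
from .synthetic import SimParams, make_grid_configuration, simulate_aggregation

logger = logging.getLogger(__name__)

__all__ = ["AnalysisParams", "PipelineConfig", "run_pipeline", "recover_viscosity_experiment"]


@dataclass(frozen=True)
class AnalysisParams:
    """Analysis-stage settings (cutoffs in nm, windows in ns)."""

    cutoffs: Tuple[float, ...] = (1.7, 2.25)
    rdf_bin_width: float = 0.05
    rdf_r_max: Optional[float] = None
    rdf_frame_fraction: float = 1.0  # use the last fraction of frames
    msd_cutoff: float = 2.25
    msd_max_lag: float = 15.0
    fit_window: Tuple[float, float] = (5.0, 15.0)
    fit_model: str = "HPW-PS"
    powerlaw_range: Optional[Tuple[float, float]] = None
    min_msd_samples: int = 50


@dataclass
class PipelineConfig:
    """Full pipeline configuration (simulation, analysis, output).

    ``trajectory`` switches to analysis-only mode: the simulation stage is
    skipped and the trajectory is read from the given path.
    """

    simulation: Optional[SimParams] = field(default_factory=SimParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    trajectory: Optional[str] = None
    grid_side: Optional[int] = None  # initial square grid; default sqrt(n)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {"simulation", "analysis", "trajectory", "grid_side"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")

        def build(dc, section, name):
            if section is None:
                return None
            fields = {f.name for f in dataclasses.fields(dc)}
            bad = set(section) - fields
            if bad:
                raise ValueError(f"unknown keys in {name!r} section: {sorted(bad)}")
            section = dict(section)
            for key in ("cutoffs", "fit_window", "powerlaw_range"):
                if key in section and section[key] is not None:
                    section[key] = tuple(section[key])
            return dc(**section)

        return cls(
            simulation=build(SimParams, raw.get("simulation", {}), "simulation")
            if raw.get("simulation", {}) is not None
            else None,
            analysis=build(AnalysisParams, raw.get("analysis", {}), "analysis"),
            trajectory=raw.get("trajectory"),
            grid_side=raw.get("grid_side"),
        )

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "PipelineConfig":
        return cls.from_dict(read_config(path))


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: PipelineConfig, outdir: Union[str, Path]) -> dict:
    """Execute the full pipeline; returns the JSON summary (also written).

    Stages: simulate (or load) -> clusters -> power law -> rdf -> tilt ->
    msd -> finite-size correction -> viscosity fit.  Any stage failure
    raises with the stage name; outputs written so far remain on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"schema_version": 1, "memclust_version": __version__}
    stage = "setup"
    try:
        ana = config.analysis
        if config.trajectory is not None:
            stage = "load"
            traj = read_trajectory(config.trajectory)
            summary["source"] = str(config.trajectory)
            params = config.simulation
        else:
            stage = "simulate"
            params = config.simulation or SimParams()
            side = config.grid_side or int(round(np.sqrt(params.n_inclusions)))
            if side * side != params.n_inclusions:
                raise ValueError(
                    "n_inclusions must be a perfect square for a grid start "
                    "(or set grid_side explicitly)"
                )
            initial = make_grid_configuration(side, params.box_length)
            traj = simulate_aggregation(initial, params)
            write_trajectory(traj, outdir / "trajectory.npz")
            summary["source"] = "synthetic"
            summary["seed"] = params.seed
        summary["n_inclusions"] = traj.n
        summary["n_frames"] = traj.n_frames
        summary["box_length_nm"] = traj.box_length

        stage = "clusters"
        rows = []
        series_by_cutoff = {}
        for cutoff in ana.cutoffs:
            series = cluster_series(traj, cutoff)
            series_by_cutoff[cutoff] = series
            for i in range(traj.n_frames):
                rows.append(
                    dict(
                        time_ns=series.times[i],
                        cutoff_nm=cutoff,
                        n_clusters=int(series.n_clusters[i]),
                        n_max=int(series.n_max[i]),
                        mean_size=float(series.mean_size[i]),
                    )
                )
        pd.DataFrame(rows).to_csv(outdir / "clusters.csv", index=False)
        main_cutoff = ana.msd_cutoff if ana.msd_cutoff in series_by_cutoff else ana.cutoffs[-1]
        main_series = series_by_cutoff[main_cutoff]
        summary["final_n_clusters"] = int(main_series.n_clusters[-1])
        summary["final_n_max"] = int(main_series.n_max[-1])
        summary["n_fusion_events"] = sum(1 for e in main_series.events if e[1] == "fusion")

        stage = "power_law"
        if ana.powerlaw_range is not None:
            pl_range = ana.powerlaw_range
        else:
            positive = main_series.times[main_series.times > 0]
            pl_range = (float(positive[0]), float(main_series.times[-1])) if positive.size else None
        summary["power_law"] = None
        if pl_range is not None:
            try:
                fit = fit_power_law(main_series, pl_range)
                summary["power_law"] = dict(
                    exponent=fit.exponent,
                    prefactor=fit.prefactor,
                    fit_range_ns=list(fit.fit_range),
                    rms_log_residual=fit.residual,
                )
            except ValueError as exc:
                logger.warning("power-law fit skipped: %s", exc)

        stage = "rdf"
        n_skip = int((1.0 - ana.rdf_frame_fraction) * traj.n_frames)
        rdf = rdf_2d(
            traj,
            bin_width=ana.rdf_bin_width,
            r_max=ana.rdf_r_max,
            frame_indices=range(n_skip, traj.n_frames),
        )
        pd.DataFrame({"r_nm": rdf.bin_centers, "g": rdf.g}).to_csv(
            outdir / "rdf.csv", index=False
        )
        peak = first_peak(rdf, r_min_search=0.0)
        summary["rdf_first_peak_nm"] = peak

        stage = "tilt"
        summary["mean_cos_theta"] = None
        if traj.orientations is not None:
            ts = tilt_series(traj.orientations, times=traj.times)
            pd.DataFrame(
                {"time_ns": ts.times, "mean_cos_theta": ts.mean_cos_theta}
            ).to_csv(outdir / "tilt.csv", index=False)
            summary["mean_cos_theta"] = float(np.mean(ts.mean_cos_theta))

        stage = "msd"
        curves = msd_by_size(traj, cutoff=main_cutoff, max_lag=ana.msd_max_lag)
        msd_rows = []
        for c in curves:
            for lag, m, ns in zip(c.lags, c.msd, c.n_samples):
                msd_rows.append(
                    dict(cluster_size=c.cluster_size, lag_ns=lag, msd_nm2=m, n_samples=ns)
                )
        pd.DataFrame(msd_rows).to_csv(outdir / "msd.csv", index=False)

        stage = "diffusion"
        records: List[DiffusionRecord] = []
        if params is not None:
            hydro = params.hydro
            box = traj.box_length
            solvent_height = params.solvent_height
        else:
            hydro = HydroParams(eta_m=4.5e-11, eta_w=7e-4, temperature=300.0)
            box = traj.box_length
            solvent_height = None
        r_cnt = params.inclusion_radius if params is not None else 1.05
        for c in curves:
            in_window = (
                (c.lags >= ana.fit_window[0])
                & (c.lags <= ana.fit_window[1])
                & (c.lags > 0)
            )
            if np.count_nonzero(in_window) < 3:
                continue
            if float(np.min(c.n_samples[in_window])) < ana.min_msd_samples:
                continue
            d_pbc, sigma = estimate_D(c, window=ana.fit_window)
            if sigma <= 0 or d_pbc <= 0:
                continue
            records.append(
                DiffusionRecord(
                    cluster_size=c.cluster_size,
                    effective_radius=effective_radius(c.cluster_size, r_cnt),
                    d_pbc=d_pbc,
                    d_corrected=finite_size_correction(d_pbc, box, solvent_height, hydro),
                    sigma=sigma,
                )
            )
        pd.DataFrame(
            [
                dict(
                    cluster_size=r.cluster_size,
                    effective_radius_nm=r.effective_radius,
                    d_pbc_nm2_ns=r.d_pbc,
                    d_corrected_nm2_ns=r.d_corrected,
                    sigma_nm2_ns=r.sigma,
                )
                for r in records
            ]
        ).to_csv(outdir / "diffusion_records.csv", index=False)

        stage = "fit"
        summary["viscosity_fit"] = None
        distinct = {r.cluster_size for r in records}
        if len(distinct) >= 2:
            fit = fit_viscosity(
                records, eta_w=hydro.eta_w, temperature=hydro.temperature, model=ana.fit_model
            )
            summary["viscosity_fit"] = dict(
                eta_m_hat_Pa_s_m=fit.eta_m_hat,
                chi2_reduced=fit.chi2_reduced,
                model=fit.model_name,
                n_points=fit.n_points,
            )
        else:
            logger.warning("viscosity fit skipped: fewer than 2 distinct cluster sizes")

        stage = "summary"
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=_jsonify)
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc


def recover_viscosity_experiment(
    eta_m_true: float = 4.5e-11,
    sizes: Sequence[int] = (1, 4, 9, 16, 25, 64),
    seed: int = 1,
    n_frames: int = 20001,
    time_step: float = 0.1,
    frame_interval: float = 0.5,
    box_length: float = 70.0,
    eta_w: float = 7e-4,
    temperature: float = 300.0,
    fit_window: Tuple[float, float] = (5.0, 15.0),
) -> dict:
    """Generate-and-recover experiment for the membrane viscosity.

    For each cluster size, one fixed cluster is simulated in its own
    periodic box with the HPW-PS generating mobility (minus the periodic
    finite-size correction); the trajectory is pushed through the full
    measurement chain — size-resolved MSD, weighted linear fit in the
    5-15 ns window, finite-size correction, weighted HPW-PS fit — and the
    recovered viscosity is compared with the generating one.

    Each size runs in its own box (rather than all in one) so that
    transiently interpenetrating non-fusing clusters cannot contaminate the
    size-resolved MSD.

    Returns a dict with the records, the fit, and the true value.
    """
    from .synthetic import simulate_fixed_clusters

    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(sizes))]
    hydro = HydroParams(eta_m=eta_m_true, eta_w=eta_w, temperature=temperature)
    records: List[DiffusionRecord] = []
    for s, child in zip(sizes, child_seeds):
        params = SimParams(
            n_inclusions=s,
            box_length=box_length,
            eta_m=eta_m_true,
            eta_w=eta_w,
            temperature=temperature,
            time_step=time_step,
            n_frames=n_frames,
            frame_interval=frame_interval,
            seed=child,
            finite_size_effects=True,
        )
        traj = simulate_fixed_clusters([s], params)
        curves = msd_by_size(traj, cutoff=params.fusion_cutoff, max_lag=fit_window[1])
        curve = next(c for c in curves if c.cluster_size == s)
        d_pbc, sigma = estimate_D(curve, window=fit_window)
        d_corr = finite_size_correction(d_pbc, box_length, params.solvent_height, hydro)
        records.append(
            DiffusionRecord(
                cluster_size=s,
                effective_radius=effective_radius(s, params.inclusion_radius),
                d_pbc=d_pbc,
                d_corrected=d_corr,
                sigma=sigma,
            )
        )
    fit = fit_viscosity(records, eta_w=eta_w, temperature=temperature, model="HPW-PS")
    return dict(
        eta_m_true=eta_m_true,
        eta_m_hat=fit.eta_m_hat,
        relative_error=abs(fit.eta_m_hat - eta_m_true) / eta_m_true,
        chi2_reduced=fit.chi2_reduced,
        records=records,
        fit=fit,
        n_steps_per_size=(n_frames - 1) * int(round(frame_interval / time_step)),
    )
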