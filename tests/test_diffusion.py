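"""Hydrodynamic models, MSD estimation, finite-size correction, viscosity fit."""

import math
import warnings

import numpy as np
import pytest

from memclust import (
    DiffusionRecord,
    HydroParams,
    MSDCurve,
    SimParams,
    Trajectory,
    effective_radius,
    estimate_D,
    finite_size_correction,
    fit_viscosity,
    hpw_ps_model,
    msd_by_size,
    periodic_sd_correction,
    sd_model,
    simulate_fixed_clusters,
)
from memclust.units import KB, d_si_to_nm2_ns

EULER_GAMMA = float(np.euler_gamma)


class TestEffectiveRadius:
    @pytest.mark.parametrize("size,expected", [(1, 1.05), (4, 2.10), (100, 10.5)])
    def test_area_equivalent_mapping(self, size, expected):
        assert effective_radius(size, 1.05) == pytest.approx(expected)

    def test_rejects_size_below_one(self):
        with pytest.raises(ValueError):
            effective_radius(0, 1.05)


class TestSDModel:
    def test_hand_computed_value(self, hydro):
        # independent arithmetic: D = kT/(4 pi eta_m) (ln(2 l_SD / R) - gamma)
        r_nm = 1.05
        l_sd = hydro.eta_m / (2 * hydro.eta_w)
        expected_si = (
            KB * 300.0 / (4 * math.pi * hydro.eta_m)
            * (math.log(2 * l_sd / (r_nm * 1e-9)) - EULER_GAMMA)
        )
        assert sd_model(r_nm, hydro) == pytest.approx(
            d_si_to_nm2_ns(expected_si), rel=1e-12
        )

    def test_bracket_root(self, hydro):
        r_zero_nm = 2 * hydro.sd_length_nm * math.exp(-EULER_GAMMA)
        assert sd_model(r_zero_nm, hydro) == pytest.approx(0.0, abs=1e-15)

    def test_doubling_viscosity_rescales_by_closed_form(self, hydro):
        h2 = HydroParams(eta_m=2 * hydro.eta_m, eta_w=hydro.eta_w, temperature=300.0)
        r = 2.0
        expected = (
            KB * 300.0 / (4 * math.pi * h2.eta_m)
            * (math.log(2 * h2.sd_length / (r * 1e-9)) - EULER_GAMMA)
        )
        assert sd_model(r, h2) == pytest.approx(d_si_to_nm2_ns(expected), rel=1e-12)

    def test_warns_outside_validity(self, hydro):
        with pytest.warns(UserWarning, match="validity"):
            sd_model(2 * hydro.sd_length_nm, hydro)


class TestHPWPSModel:
    def test_reduces_to_sd_at_small_epsilon(self, hydro):
        for eps in (1e-4, 1e-3):
            r_nm = eps * hydro.sd_length_nm
            assert hpw_ps_model(r_nm, hydro) == pytest.approx(
                sd_model(r_nm, hydro), rel=5e-3
            )

    def test_small_epsilon_agreement_across_parameter_grid(self):
        for eta_m in (1e-11, 4.5e-11, 5e-10):
            for eta_w in (7e-4, 1e-3):
                h = HydroParams(eta_m=eta_m, eta_w=eta_w, temperature=300.0)
                for eps in (1e-4, 1e-3):
                    r = eps * h.sd_length_nm
                    rel = abs(hpw_ps_model(r, h) - sd_model(r, h)) / sd_model(r, h)
                    assert rel < 1e-2

    def test_strictly_decreasing_in_radius(self, hydro):
        eps = np.logspace(-3, 2, 600)
        radii = eps * hydro.sd_length_nm
        d = np.array([hpw_ps_model(r, hydro) for r in radii])
        assert np.all(np.diff(d) < 0)

    def test_large_epsilon_bulk_scaling(self, hydro):
        # ~1/R behaviour far beyond the SD length
        r1 = 100 * hydro.sd_length_nm
        r2 = 200 * hydro.sd_length_nm
        ratio = hpw_ps_model(r1, hydro) / hpw_ps_model(r2, hydro)
        assert ratio == pytest.approx(2.0, rel=0.15)

    def test_sd_to_bulk_transition_scale(self):
        """The crossover sits at ~10 nm for experiment-like parameters
        (water solvent, membrane viscosity ~1e-10 Pa s m): order of
        magnitude only."""
        h = HydroParams(eta_m=1e-10, eta_w=1e-3, temperature=300.0)
        radii = np.logspace(-1, 3, 400)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d_sd = np.array([sd_model(r, h) for r in radii])
        d_ps = np.array([hpw_ps_model(r, h) for r in radii])
        with np.errstate(invalid="ignore"):
            dev = np.abs(d_sd - d_ps) / d_ps
        idx = np.argmax(dev > 0.5)
        r_transition = radii[idx]
        assert 1.0 < r_transition < 100.0


class TestFiniteSizeCorrection:
    def test_vanishes_for_large_box(self, hydro):
        d_pbc = 0.02
        delta = periodic_sd_correction(1e8, None, hydro)
        assert abs(delta) < 1e-6 * d_pbc

    def test_size_independent_and_additive(self, hydro):
        delta = periodic_sd_correction(70.0, None, hydro)
        for d_pbc in (0.005, 0.01, 0.02):
            assert finite_size_correction(d_pbc, 70.0, None, hydro) == pytest.approx(
                d_pbc + delta
            )

    def test_logarithmic_growth_below_sd_length(self, hydro):
        # increments per box halving approach kT ln2 / (4 pi eta_m)
        l_sd = hydro.sd_length_nm
        boxes = [l_sd / 2, l_sd / 4, l_sd / 8]
        deltas = [periodic_sd_correction(b, None, hydro) for b in boxes]
        increments = np.diff(deltas)
        expected = d_si_to_nm2_ns(
            hydro.thermal_energy / (4 * math.pi * hydro.eta_m) * math.log(2)
        )
        assert increments[0] > 0
        np.testing.assert_allclose(increments, expected, rtol=0.1)

    def test_stable_under_cutoff_refinement(self, hydro):
        d64 = periodic_sd_correction(70.0, None, hydro, n_modes=64)
        d192 = periodic_sd_correction(70.0, None, hydro, n_modes=192)
        assert d64 == pytest.approx(d192, rel=1e-3)

    def test_solvent_height_screens_correction(self, hydro):
        # a thin momentum-absorbing solvent slab reduces the correction
        thin = periodic_sd_correction(70.0, 10.0, hydro)
        semi_infinite = periodic_sd_correction(70.0, None, hydro)
        assert 0 < thin < semi_infinite

    def test_generator_roundtrip_recovers_model(self, hydro):
        """Generator subtracts the periodic correction; the pipeline adds it
        back: recovered D matches the infinite-system model within error."""
        params = SimParams(
            n_inclusions=1, box_length=70.0, n_frames=20_001, time_step=0.1,
            frame_interval=0.5, seed=29, finite_size_effects=True,
        )
        traj = simulate_fixed_clusters([1], params)
        curve = msd_by_size(traj, 2.25, 15.0)[0]
        d_pbc, sigma = estimate_D(curve, (5.0, 15.0))
        d_corr = finite_size_correction(d_pbc, 70.0, None, hydro)
        d_model = hpw_ps_model(1.05, hydro)
        assert abs(d_corr - d_model) < 4 * sigma


class TestMSD:
    def test_static_positions_zero_msd(self):
        pos = np.random.default_rng(0).uniform(0, 30.0, size=(3, 2))
        wrapped = np.repeat(pos[None], 40, axis=0)
        traj = Trajectory(
            times=0.5 * np.arange(40), wrapped=wrapped, unwrapped=wrapped.copy(),
            box_length=30.0,
        )
        curves = msd_by_size(traj, 2.25, 10.0)
        for c in curves:
            np.testing.assert_allclose(c.msd, 0.0)
            assert estimate_D(c, (2.0, 10.0)) == (0.0, 0.0)

    def test_pooled_samples_double_with_two_clusters(self):
        params = SimParams(
            n_inclusions=2, box_length=60.0, n_frames=501, seed=31,
            finite_size_effects=False,
        )
        traj2 = simulate_fixed_clusters([1, 1], params)
        traj1 = simulate_fixed_clusters([1], params)
        c2 = next(c for c in msd_by_size(traj2, 2.25, 10.0) if c.cluster_size == 1)
        c1 = next(c for c in msd_by_size(traj1, 2.25, 10.0) if c.cluster_size == 1)
        np.testing.assert_allclose(c2.n_samples[1:], 2 * c1.n_samples[1:], rtol=0.05)


class TestEstimateD:
    @staticmethod
    def _curve(lags, msd):
        return MSDCurve(
            lags=lags, msd=msd, cluster_size=1, n_samples=np.full(len(lags), 100.0)
        )

    def test_exact_on_linear_msd(self):
        lags = np.arange(1.0, 20.0)
        d, sigma = estimate_D(self._curve(lags, 4 * 0.02 * lags), (5.0, 15.0))
        assert d == pytest.approx(0.02, rel=1e-12)

    def test_intercept_insensitive(self):
        lags = np.arange(1.0, 20.0)
        d, _ = estimate_D(self._curve(lags, 4 * 0.02 * lags + 0.7), (5.0, 15.0))
        assert d == pytest.approx(0.02, rel=1e-12)

    def test_window_outside_range_rejected(self):
        lags = np.arange(1.0, 5.0)
        with pytest.raises(ValueError):
            estimate_D(self._curve(lags, lags), (10.0, 20.0))


def _records_from_model(hydro, sizes, sigma=1e-4, noise_rng=None):
    records = []
    for s in sizes:
        r = effective_radius(s, 1.05)
        d = hpw_ps_model(r, hydro)
        if noise_rng is not None:
            d = d + noise_rng.normal(0.0, sigma)
        records.append(
            DiffusionRecord(
                cluster_size=s, effective_radius=r, d_pbc=d, d_corrected=d, sigma=sigma
            )
        )
    return records


class TestFitViscosity:
    def test_noiseless_recovery(self, hydro):
        records = _records_from_model(hydro, [1, 4, 9, 16, 25, 64])
        fit = fit_viscosity(records, eta_w=hydro.eta_w, temperature=300.0, model="HPW-PS")
        assert fit.eta_m_hat == pytest.approx(hydro.eta_m, rel=1e-5)
        assert fit.chi2_reduced == pytest.approx(0.0, abs=1e-6)

    def test_chi2_calibrated_with_exact_sigmas(self, hydro):
        rng = np.random.default_rng(123)
        sizes = list(range(1, 41))
        records = _records_from_model(hydro, sizes, sigma=2e-4, noise_rng=rng)
        fit = fit_viscosity(records, eta_w=hydro.eta_w, temperature=300.0)
        nu = len(sizes) - 1
        assert abs(fit.chi2_reduced - 1.0) < 3 * math.sqrt(2.0 / nu)

    def test_sd_worse_than_hpw_ps_on_large_clusters(self, hydro):
        rng = np.random.default_rng(7)
        sizes = [25, 64, 144, 256, 400]  # eps up to ~0.65
        records = _records_from_model(hydro, sizes, sigma=5e-5, noise_rng=rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit_sd = fit_viscosity(records, eta_w=hydro.eta_w, temperature=300.0, model="SD")
        fit_ps = fit_viscosity(records, eta_w=hydro.eta_w, temperature=300.0, model="HPW-PS")
        assert fit_sd.chi2_reduced > fit_ps.chi2_reduced

    def test_matches_grid_scan_oracle(self, hydro):
        rng = np.random.default_rng(99)
        records = _records_from_model(hydro, [1, 4, 16, 64], sigma=3e-4, noise_rng=rng)
        fit = fit_viscosity(records, eta_w=hydro.eta_w, temperature=300.0)
        etas = np.geomspace(1e-12, 1e-9, 20_000)
        d = np.array([r.d_corrected for r in records])
        sig = np.array([r.sigma for r in records])
        radii = [r.effective_radius for r in records]
        chi2 = []
        for eta in etas:
            h = HydroParams(eta_m=eta, eta_w=hydro.eta_w, temperature=300.0)
            pred = np.array([hpw_ps_model(r, h) for r in radii])
            chi2.append(np.sum(((d - pred) / sig) ** 2))
        best = np.min(chi2)
        assert fit.chi2_reduced * (len(records) - 1) == pytest.approx(
            best, rel=1e-4, abs=1e-12
        )

    def test_degenerate_radii_refused(self, hydro):
        records = _records_from_model(hydro, [4, 4, 4])
        with pytest.raises(ValueError, match="degenerate"):
            fit_viscosity(records, eta_w=hydro.eta_w, temperature=300.0)
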