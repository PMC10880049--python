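# memclust

Analysis of lipid-mediated self-assembly of membrane inclusions — such as
carbon-nanotube (CNT) porins in a lipid bilayer — from trajectories of
in-plane centre-of-mass positions in a periodic box, together with a
synthetic Brownian-aggregation generator so that every stage can be tested
and demonstrated without any MD data.

**Who it is for.** People studying the aggregation kinetics and lateral
diffusion of membrane inclusions (CNT porins, proteins, nanoparticles) from
coarse-grained MD or from any source that can produce a 2D
centre-of-mass trajectory.

**What it computes.**

- *Cluster kinetics* — connected-component clusters at a centre-to-centre
  minimum-image cutoff (e.g. 1.7 nm for full contact, 2.25 nm for
  separation by one lipid layer), per-frame counts, largest-cluster size
  N_max(t), identity tracking with fusion/fission events, and power-law
  growth fits N_max ~ t^α.
- *Structure* — 2D radial distribution function g(r) under periodic
  boundaries (the lipid-separated packing of CNT porins shows a first peak
  near 2.1 nm) and tilt order ⟨|cos θ|⟩ of inclusion axes.
- *Diffusion* — size-resolved mean-squared displacements restricted to
  intervals of unchanged cluster membership; D from a weighted linear fit
  (default window 5–15 ns); the additive periodic-box finite-size
  correction; and a one-parameter weighted fit of the membrane surface
  viscosity η_m using either the Saffman–Delbrück (SD) model

      D = kT/(4π η_m) [ln(2 ℓ_SD/R) − γ],   ℓ_SD = η_m/(2 η_w),

  or the Petrov–Schwille interpolation of the Hughes–Pailthorpe–White
  solution (HPW‑PS), valid for all inclusion sizes. The effective radius of
  a cluster of s inclusions is the area-equivalent disk R = R_CNT·√s.
- *Synthetic data* — overdamped 2D Brownian dynamics of rigid clusters with
  HPW‑PS mobilities, irreversible fusion, and triangular-lattice repacking
  at the lipid-separated spacing; plus an Ornstein–Uhlenbeck tilt generator.

## Worked example

Simulate the standard system — 100 inclusions of radius 1.05 nm on a square
grid in a 70 nm box, η_m = 4.5×10⁻¹¹ Pa·s·m — for 1 µs and run the full
analysis:

```python
from memclust import AnalysisParams, PipelineConfig, SimParams, run_pipeline

cfg = PipelineConfig(
    simulation=SimParams(n_inclusions=100, box_length=70.0, n_frames=2001, seed=1),
    analysis=AnalysisParams(),
)
summary = run_pipeline(cfg, "demo_out")
```

yields (summary.json, abbreviated):

```json
{
  "final_n_clusters": 31,
  "final_n_max": 10,
  "n_fusion_events": 69,
  "power_law": {"exponent": 0.553, "prefactor": 0.217, "fit_range_ns": [0.5, 1000.0]},
  "rdf_first_peak_nm": 2.075,
  "viscosity_fit": {"eta_m_hat_Pa_s_m": 4.709e-11, "chi2_reduced": 3.42, "n_points": 10}
}
```

Reading: the 100 initially dispersed inclusions coalesce into 31 clusters
within 1 µs (69 fusions), the largest reaching 10 members with sub-linear
power-law growth (exponent ≈ 0.55 over this window); the RDF first peak
falls in the bin containing the 2.1 nm packing distance; and fitting HPW‑PS
to the size-resolved, finite-size-corrected diffusion coefficients recovers
a membrane viscosity close to the generating 4.5×10⁻¹¹ Pa·s·m even from a
single aggregating run.

The same pipeline is available from the shell:

```bash
memclust simulate --config cfg.yaml --out traj.npz
memclust clusters --traj traj.npz --cutoff 1.7 --cutoff 2.25 --out clusters.csv
memclust rdf --traj traj.npz --out rdf.csv
memclust msd --traj traj.npz --out msd.csv
memclust fit --records d_table.csv --eta-w 7e-4 --temperature 300 --out fit.json
memclust run --config cfg.yaml --out results/
```

`memclust fit` accepts any external `(cluster_size, D, sigma)` CSV, so
tables derived from real MD can be fitted directly.

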