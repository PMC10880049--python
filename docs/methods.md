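# Methods

## Scope and data model

memclust analyses trajectories of N membrane inclusions described by their
in-plane (2D) centre-of-mass positions in a square periodic box of side L,
with optional per-inclusion axis orientation unit vectors (membrane normal
along z). Lengths are nm, times ns, diffusion coefficients nm²/ns
(1 nm²/ns = 10⁻⁹ m²/s); hydrodynamic model evaluation is done in SI
internally, with the conversion constants collected in `memclust.units`.
Trajectories carry both wrapped coordinates (used for all distance-based
analyses under the minimum-image convention) and unwrapped coordinates
(used for displacements), which must agree modulo L.

## Cluster identification and tracking

Clusters are connected components of the graph joining pairs whose
centre-to-centre minimum-image distance is at most a cutoff r_c. The
criterion is centre distance, not surface gap, matching how contact
cutoffs for lipid-separated inclusions are usually quoted (≈1.7 nm for
direct contact of CNT porins, ≈2.25 nm for separation by a single lipid
layer). Labels are canonical — clusters numbered by ascending minimum
member index — making results permutation-equivariant and reproducible.
The cutoff must be < L/2; beyond that the minimum image is ambiguous and
the operation refuses.

Identity tracking between consecutive frames assigns each cluster the
identity of the previous-frame cluster with the largest member overlap,
ties broken toward the lower canonical label. A present-frame cluster
overlapping several past clusters logs a fusion; a past cluster split over
several present clusters logs a fission (possible only in imported data —
the generator's fusion is irreversible).

Growth kinetics: N_max(t) is fitted by an unweighted least-squares line in
(log t, log N_max). The fit range is a required input recorded in the
result, because growth exponents are window-dependent; t = 0 is always
excluded. On noiseless power-law inputs the exponent is recovered to
floating-point accuracy.

## Radial distribution function and tilt order

g(r) is the per-frame histogram of minimum-image pair distances normalized
by the 2D ideal-gas expectation ρ·π[(r+Δr)² − r²] per inclusion
(ρ = N/L²), averaged over frames. Defaults: bin width 0.05 nm, r_max =
L/2. For a system of fixed N the ideal-gas plateau is (N−1)/N, an O(1/N)
offset the tests account for. The first-peak locator returns the bin
centre of the first local maximum with g above a prominence threshold
(default 1.2, configurable) at or beyond a search start; a flat g returns
"no peak" rather than an error.

Tilt order is the per-frame mean of |cos θ| between inclusion axes and the
membrane normal. The absolute value folds the up/down symmetry of
inclusions such as CNT porins; for isotropically random axes the
expectation is 1/2.

## Hydrodynamic models

With membrane surface viscosity η_m (Pa·s·m), solvent viscosity η_w
(Pa·s) on each side and temperature T, the Saffman–Delbrück length is
ℓ_SD = η_m/(2 η_w) and the reduced radius ε = R/ℓ_SD.

- SD model (Saffman & Delbrück 1975): D = kT/(4π η_m)[ln(2/ε) − γ], the
  small-ε limit; a warning (not an error) is raised outside its domain.
- HPW‑PS: the Petrov–Schwille (2008) closed-form interpolation of the
  Hughes–Pailthorpe–White solution, with the published constants
  b₁ = 2.74819, b₂ = 0.61465, c₁ = 0.73761, c₂ = 0.52119. It reduces to SD
  as ε → 0 (within 1% for ε ≤ 10⁻³) and crosses over to bulk-dominated
  ~1/R behaviour at large ε.

The effective radius of a cluster of s inclusions of radius R_CNT is the
area-equivalent disk R = R_CNT √s — shape-independent and exact for
compact packings at the area level.

## Finite-size correction

A diffusion coefficient measured in a periodic box underestimates the
infinite-system value because the inclusion drags its own periodic images.
The additive correction Δ = D_∞ − D_PBC is evaluated from first principles
as the difference between the k-space integral and the periodic lattice
sum of the in-plane membrane mobility kernel

    μ(k) = 1 / (η_m k² + 2 η_w k coth(kH)),

with H the solvent height on each side (H → ∞, i.e. coth → 1, for
semi-infinite solvent — the default):

    Δ = (kT/2) [ ∫ d²k/(2π)² μ(k) − L⁻² Σ_{k≠0} μ(k) ],

the membrane analogue of the Yeh–Hummer cubic-box correction (cf. Vögele &
Hummer 2016; Vögele, Köfinger & Hummer 2018). Both terms are damped by a
common Gaussian spectral filter so their identical UV parts cancel; the
default cutoff (64 modes per axis) is converged to ~10⁻⁴ relative and a
test verifies stability under refinement. The correction is independent of
inclusion size, vanishes as L → ∞ (~1/L for semi-infinite solvent), and
grows by kT ln2/(4π η_m) per box halving once L ≪ ℓ_SD — all verified
against closed forms in the tests. Note Δ depends on the (assumed) η_m;
in the recovery experiment the generating parameters are used, mirroring
the usual practice of correcting MD estimates with a known or iterated
viscosity.

## MSD estimation

MSD(τ) is accumulated per cluster size over all inclusions, overlapping
time origins and cluster instances whose member set is unchanged over the
entire interval [t₀, t₀+τ]; mixing membership would blur sizes together.
Per-lag sample counts record (cluster instance, origin) pairs. D is the
slope/4 of a weighted linear fit of MSD vs τ in a window (default 5–15 ns,
configurable), intercept free, so a non-zero offset does not bias D. The
per-lag weight uses an effective sample count n_eff = n_samples/lag_frames
that discounts overlapping origins, with σ_MSD = MSD/√n_eff; the quoted σ_D
comes from the weighted-fit covariance. Residual correlation between lags
is not modelled, so σ_D is approximate (the χ²ν of downstream fits on
simulated data runs slightly above 1); the χ²-calibration test instead uses
records with exactly known Gaussian errors.

## Viscosity fit

η̂_m minimizes χ²(η_m) = Σ[(D_i − D_model(R_i; η_m))/σ_i]² by bounded
scalar minimization on log η_m (relative tolerance 10⁻⁶, bounds
10⁻¹³–10⁻⁸ Pa·s·m), with χ²ν = χ²_min/(n − 1) for the single fitted
parameter. Degenerate inputs (all radii equal) are refused. A grid-scan
oracle test confirms the minimizer.

## Synthetic generator

The generator emulates the statistical structure of coarse-grained MD of
~100 CNT-porin-like inclusions without simulating lipids:

- *Dynamics*: overdamped 2D Brownian motion. Clusters move as rigid bodies
  (consistent with clusters diffusing as single large objects); each
  cluster of size s receives an isotropic Gaussian displacement of
  variance 2 D(s) Δt per coordinate with D(s) = HPW‑PS(R_CNT√s). With
  `finite_size_effects` on (default), the periodic correction Δ(L, H) is
  subtracted from D(s), so the generated box behaves like a periodic
  simulation; the analysis chain adds Δ back. Rotational diffusion of
  clusters is omitted — only translational MSD is analysed.
- *Fusion*: when any inter-cluster pair comes within `fusion_cutoff`
  (default 2.25 nm), the clusters fuse irreversibly and their members are
  repacked on a triangular lattice at `packing_distance` (default 2.1 nm)
  about the merged centre of mass (preserved). Repacking reproduces the
  2.1 nm RDF peak structure; no dissociation ever occurs. Repacking jumps
  do not contaminate MSD because membership changes break persistence.
- *Randomness*: all draws come from a counter-based (Philox) stream keyed
  on the seed, with a fixed (step, inclusion-slot) layout, so trajectories
  are bit-reproducible and independent of cluster-bookkeeping iteration
  order. Identical parameters + seed ⇒ bit-identical output.
- *Safety*: a step whose typical single-step displacement √(4DΔt) exceeds
  L/4 is refused (minimum-image dynamics would be unsafe).
- *Tilt*: cos θ follows an exactly discretized Ornstein–Uhlenbeck process
  around `mean_cos` (stationary sd = `noise_amplitude`), reflected into
  [−1, 1], with uniform azimuths; zero noise gives exactly constant tilt.
- Temperature 0 is allowed and freezes all motion exactly (the zero-
  mobility limit).

Defaults are the standard study conditions: N = 100, L = 70 nm,
R_CNT = 1.05 nm, η_m = 4.5×10⁻¹¹ Pa·s·m, T = 300 K, fusion at 2.25 nm,
packing at 2.1 nm. The solvent viscosity default η_w = 7×10⁻⁴ Pa·s is a
coarse-grained-water scale (configurable); ℓ_SD ≈ 32 nm then, so the
70 nm box carries a sizeable (~30% of D₁) finite-size correction — a
realistic regime for membrane simulations. The frame interval (0.5 ns) and
step (0.1 ns) are package conventions chosen so that the 5–15 ns fit window
contains ≥ 20 lags; a 20 000-frame (10 µs-equivalent, 10⁵-step) run per
cluster size gives D estimates good to ~2%, which the recovery experiment
uses.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no explicit lipids or annular-shell
thermodynamics (fusion kinetics are diffusion-limited by construction, so
the growth exponent of the synthetic system is its own, not a universal
value); no cluster rotation or internal rearrangement; no hydrodynamic
coupling between distinct clusters; no dissociation. Analyses of real MD
imports are unaffected by these choices.

## Viscosity-recovery experiment

`recover_viscosity_experiment` simulates one fixed cluster per size
(default sizes 1, 4, 9, 16, 25, 64) in its own 70 nm box — separate boxes
so that non-fusing clusters cannot transiently interpenetrate and
contaminate the size-resolved MSD — then runs the full measurement chain
(cluster-resolved MSD → windowed fit → finite-size correction → weighted
HPW‑PS fit). With the default sampling it recovers the generating
η_m = 4.5×10⁻¹¹ Pa·s·m to ~1–2%, comfortably within the 10% acceptance
band; per-size child seeds are spawned deterministically from one root
seed.

## Numerical and design choices

- Pair searches use a periodic cKDTree; connected components via
  scipy.sparse.csgraph. A brute-force 9-image oracle validates both.
- Hex lattice construction selects the n sites closest to the origin with
  deterministic (distance, angle, index) tie-breaking, then recentres the
  centroid; fusion repacking reuses it.
- The canonical trajectory interchange format is documented column text;
  `.npz` is the compact binary container; an optional MDAnalysis adapter
  projects 3D group centres of mass onto the membrane plane (Å → nm,
  ps → ns) and unwraps by accumulated minimum-image steps.
- Config files are YAML mirroring the parameter dataclasses; unknown keys
  are rejected. All thresholds actually used are logged at INFO level, and
  pipeline summaries are byte-deterministic for a given seed.

## Known limitations

- σ_D underestimates slightly because MSD lags are correlated; χ²ν of
  fits to simulated trajectories is therefore biased high (the recovered
  η̂_m is not noticeably affected).
- The finite-size correction assumes a flat membrane spanning the full
  periodic cell with equal solvent slabs on both sides.
- The power-law growth exponent of the synthetic aggregation is
  window- and condition-dependent; it is reported with its fit range, not
  asserted against any particular value.
- `simulate_fixed_clusters` places clusters on a slot grid and refuses
  configurations that cannot fit without contact; it does not attempt
  optimal packing.
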