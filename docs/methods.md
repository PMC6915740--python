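# Methods

## Scientific model

### The two-state EVB description of the rate-limiting step

The rate-limiting acylation step of elastase-catalyzed peptide hydrolysis
(formation of the tetrahedral intermediate, TI) is modeled with a two-state
empirical valence bond Hamiltonian.  Two diabatic states — reactant (ε₁)
and product (ε₂) — mix through a constant off-diagonal coupling H₁₂, and a
constant gas-phase shift Δα is added to ε₂ to calibrate the reaction
energetics:

    Eg = ½(ε₁ + ε₂′) − ½√((ε₁ − ε₂′)² + 4H₁₂²),   ε₂′ = ε₂ + Δα.

Defaults are Δα = 195.0 and H₁₂ = 113.0 kcal/mol.  The shift is applied at
exactly one point in the code (`evb.shifted_state2`); everything downstream
consumes the shifted ε₂′, which prevents double-shifting.  The generalized
reaction coordinate is the energy gap X = ε₁ − ε₂′, with the reactant at
negative X (a convention of this package; either sign works).

Free-energy profiles along X come from the classic EVB-FEP/umbrella
estimator: sampling is driven by the mapping potential
ε_m = (1 − λ)ε₁ + λε₂′ over 51 evenly spaced windows; the Zwanzig
exponential average accumulates ΔG(λ_m); and a per-bin reweighting from
ε_m to Eg yields ΔG(X).  All exponential averages are log-sum-exp
stabilized, which matters here: near the diabatic crossing ε_m − Eg is of
order H₁₂ ≈ 190 RT and the raw weights overflow by hundreds of orders of
magnitude.

### Enthalpy–entropy decomposition and rates

With ΔH‡ and ΔS‡ treated as temperature-independent, ΔG‡/T is linear in
1/T with slope ΔH‡ and intercept −ΔS‡.  Barriers sampled at 285, 290, 295,
300 and 305 K are fitted by ordinary least squares (inverse-variance
weighting is available behind a flag but is not the default, since the
source protocol specifies only a plain regression).  The fitted object
always reports ΔG‡(T_ref) as ΔH‡ − T_ref·ΔS‡, so that identity holds to
machine precision by construction.  T_ref = 295.15 K: the tables are
quoted at 22 °C, and 295.15 K (not the loosely equated 295 K) reproduces
the printed wildtype rate entry exactly.

Rates use Eyring transition-state theory with unit transmission
coefficient, k = (k_B T/h)·exp(−ΔG‡/RT), with R = 1.987204×10⁻³
kcal/(mol·K) and k_B/h = 2.083661×10¹⁰ s⁻¹K⁻¹.  Printed rate tables use
the convention printed value = k(s⁻¹) × 100; we verified this reading by
the wildtype entry (ΔG‡ = 18.0 kcal/mol → 0.289 s⁻¹ → 28.9).  Most other
printed rate entries cannot be regenerated exactly from the rounded
activation parameters (the published values clearly come from unrounded
fits), so only self-consistent entries are treated as exact identities;
activity ratios are computed from the printed rates themselves.

The replicate policy mirrors the source protocol: at least 50 replicates
per temperature, grown in batches of 10 until the Arrhenius fit reaches
R² > 0.8 (`thermo.converge_activation`; capped at 200 with a diagnostic
error carrying the R² trajectory).

## The surrogate system

Cluster-scale all-atom EVB/MD (the original study spent ~2 μs of MD) is
not reproducible at desk scale, so the solvated enzyme–substrate system is
replaced by a calibrated surrogate whose free-energy profile is known in
closed form.  The reaction coordinate x is one-dimensional; the diabats
are harmonic wells ½k(x∓1)² (equal force constants, so X is an affine
function of x and the X-marginal Jacobian is a constant); and the protein
environment is a set of harmonic bath modes whose stiffness switches from
k_R far from the transition state to k_TS at it, log-linearly along a
Gaussian switching profile (width 0.25) centered on the barrier top.

The key property is that a classical harmonic mode stores RT/2 of
potential energy regardless of stiffness, so the bath contributes no
enthalpy; integrating it out adds the purely entropic term

    G(x;T) = Eg(x) + T·η(x),   η(x) = Σᵢ (R/2)·ln(kᵢ(x)/kᵢ(x_R)).

This makes the two adaptation dials exactly orthogonal: diabat geometry
sets ΔH‡, the stiffness ratio k_TS/k_R sets ΔS‡ = −η(x‡).  A bath that
stiffens at the transition state gives the negative activation entropy
characteristic of psychrophilic enzymes — a minimal encoding of the
surface-loop-rigidification mechanism.  The switching profile is
renormalized to be exactly zero at the reactant minimum (the Gaussian tail
would otherwise leak a percent-level entropy contribution into the
reactant state, because the EVB coupling pulls the minima well inside the
diabat centers).

The package encodes the *direction* of the loop-flexibility → entropy
link only; no quantitative RMSF→ΔS‡ mapping is claimed, and the
acceptance checks assert direction, not magnitude, for that link.

### Preset calibration

Sixteen presets (two wildtypes, seven psychrophilic-side and seven
mesophilic-side mutants) carry the published (ΔH‡, TΔS‡) pairs as
targets.  Calibration is numerical, not hand-tuned: a decoupled initial
guess (Brent solves on the bare ground surface for the force constant and
product offset; the log-stiffness ratio from the closed form
ln r = −2ΔS‡/(n_modes·R)) is polished by a three-dimensional Newton solve
(`scipy.optimize.root`) against the exact stationary points of G(x;T) at
285 and 305 K.  Residuals are driven below 5×10⁻³ kcal/mol, comfortably
inside the 0.1 kcal/mol tolerance.  Shared choices: n_modes = 10,
k_R = 1, and a ground-surface reaction energy to the TI of +2.0 kcal/mol
for every preset (the TI is a high-energy intermediate; its exact offset
is not an observable of interest here and holding it fixed keeps profiles
comparable across presets).

## Sampling

Metropolis Monte Carlo replaces molecular dynamics.  Every observable in
the pipeline (free-energy profiles, RMSF) is configurational, so dynamics
are unnecessary; the Maxwell–Boltzmann velocity randomization of the MD
protocol maps onto seed-randomized MC streams.  This is the central
surrogate substitution.

The sampler works on the bath-marginal effective potential
V_m(x;T) = ε_m(x) + T·η(x), which is the exact x-marginal of the joint
mapping potential; explicit bath coordinates for retained frames are
drawn from their conditional Gaussians q ~ N(0, RT/k(x)), which together
reproduce exact joint samples.  Proposals are Gaussian single-coordinate
moves; the step size is tuned during each window's burn-in (first 10% of
steps, discarded) toward a 30–50% acceptance rate and then frozen, which
preserves detailed balance during production.

Protocol mirrored from the source: systems are annealed from 1 K to the
target temperature in the TI state (geometric 12-rung ladder) before the
windows run in ascending λ, each starting from the previous window's final
state.  The per-window production length defaults to 10⁴ steps — a
desk-scale choice (the original MD window lengths are not stated) that is
config-exposed; the oracle comparisons below quantify what it buys.

Randomness is organized hash-free around counter-based Philox streams:
one 64-bit master key plus the counter (temperature index, replicate,
window, stage).  Replicates and windows are therefore statistically
independent by construction, every draw is reachable from the master
seed, identical seeds reproduce runs bitwise, and replicate chains can be
advanced in lockstep (vectorized across replicates) while consuming
exactly the per-replicate streams a serial run would — batched and serial
sampling are bit-identical, which is tested.

## Free-energy estimation choices

* Per-replicate barriers are extracted first and then averaged (never
  average profiles, then extract one barrier): this preserves the
  replicate dispersion needed by the convergence rule and the bootstrap.
* FEP increments default to bidirectional averaging (forward estimate
  from window m averaged with the backward estimate from window m+1).
  The backward pass reuses the same samples at zero cost and cancels the
  leading-order bias of the exponential average; at desk-scale window
  lengths the forward-only estimator was measurably biased in the
  Arrhenius slope (~1 kcal/mol in ΔH‡ at 10⁴ steps/window, halved by
  averaging).  Forward-only accumulation remains available via a flag.
* Binning: 100 bins over the pooled X range trimmed to its 0.5–99.5
  percentiles; a window contributes to a bin only with ≥ 10 raw frames
  (bounds the variance of the per-bin log average); bins without support
  are masked, never interpolated.  If masked bins separate the two
  minima the profile raises a "barrier unresolved" error naming the λ
  range to densify.
* Stationary points on binned (noisy) profiles: candidate minima are the
  endpoints of the supported range plus interior minima with ≥ 0.5
  kcal/mol prominence; the transition state is the highest interior
  maximum between the outermost minima (documented tie-break).  On the
  analytic oracle, stationary points come from root-finding on dG/dx, not
  from bins.
* Uncertainty: percentile bootstrap (default 2000 resamples, 95%),
  resampling replicates within each temperature and refitting per
  resample.

## Backbone-flexibility analysis

Backbone = atoms named N, CA, C (three beads per residue; the source says
only "backbone" — config-exposed).  Superposition uses the proper-rotation
Kabsch solution (via `scipy.spatial.transform.Rotation.align_vectors`,
determinant +1 guaranteed); the average structure is computed by iterative
superposition (superpose all frames onto the current average, recompute
the mean, repeat until the average moves < 10⁻⁴ Å, max 100 iterations).
RMSF is measured after superposing every frame onto that average, with
the superposition mask defaulting to all backbone atoms of the chain so
loop fluctuations are measured in the frame of the stable core rather
than self-fitted.  When the equilibration protocol flag is used, the
first sixth of frames is discarded (the 2 ns equilibration of a 12 ns
trajectory).  Four independent replicate trajectories are averaged at the
RMSF level — not pooled as frames — before percent changes are taken, and
a multi-loop mutant's single reported number is the mean of its per-loop
percent changes (the source's aggregation is unstated; both choices are
config-exposed).

The synthetic trajectory generator draws statistically independent frames
(reference bead-chain helix + isotropic per-residue Gaussian
displacements, optional random rigid-body motion per frame).  Real MD
frames are autocorrelated; independence is a deliberate deviation that is
irrelevant to the RMSF estimator but means these ensembles say nothing
about kinetics.  The per-atom RMSF of such an ensemble converges to
σ√3.  Loop regions of the 60-residue surrogate chain are named after the
elastase surface loops they stand in for (Nβ3-Nβ4, Nβ5-Nβ6, Cβ2-Cβ3,
Cβ3-Cβ4, Cβ5-Cβ6); the default contrast multiplier 1.35 mirrors the
reported 30–40% higher psychrophile loop RMSF.

## What the surrogate does and does not show

Passing tests demonstrate that the estimator stack (FEP/umbrella →
Arrhenius → TST; superposition → RMSF → loop percent changes) is correct
against exact oracles, and that systems constructed with a known
enthalpy–entropy partitioning are recovered within statistical error at
stated problem sizes.  They do not validate any all-atom force field,
solvation model, or real-protein conformational sampling — the surrogate
has no protein topology, no explicit water, and no kinetics.  Conclusions
about the real elastase pair enter only through the published activation
parameter and rate tables, which the thermodynamic layer consumes as
input.

## Problem sizes and numerical tolerances

* Scaled-down end-to-end recovery: 2 wildtype presets × 5 temperatures ×
  10 replicates × 51 windows × 10⁴ steps (the package's standard
  desk-scale study; a few minutes of CPU).  Declared (ΔH‡, TΔS‡) are
  recovered within the bootstrap CIs (typical half-widths ≈ 1 kcal/mol at
  10 replicates).
* Oracle comparison: bath-free system, 2×10⁵ production samples per
  window; observed max deviation from the closed form ≈ 0.04 kcal/mol
  against a 0.15 kcal/mol requirement.
* Preset calibration: < 5×10⁻³ kcal/mol residual against targets.
* Superposition/RMSF invariances hold to 10⁻⁹ Å; profile gauge invariance
  (constant added to both diabats) is exact to the bit, since Metropolis
  decisions depend only on energy differences.
* Degenerate inputs raise typed errors: barrier-less surfaces
  (`DegenerateSystemError`), collinear superposition sets
  (`DegenerateGeometryError`), unresolved barriers naming the λ range to
  densify, zero-acceptance samplers, non-convergent replicate growth
  (with its R² history).

## Known limitations

* ΔS‡ is strictly temperature-independent in fits and extrapolations (no
  heat-capacity ΔCp‡ model); curved Arrhenius plots are out of scope.
* The Zwanzig estimator is used per the source method; WHAM/MBAR
  multi-state reweighting is deliberately not implemented.
* The bath "modes" are a thermodynamic device, not an embedding of real
  loop motions; only the sign of the flexibility–entropy link is encoded.
* XYZ trajectory files carry no residue metadata; reading assigns the
  three-bead convention, so loop selections on arbitrary third-party XYZ
  files need a PDB instead.
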