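# Methods

This note documents the models, estimators and numerical choices behind
`flexfes`, and what its synthetic validation does and does not demonstrate.

## Scope and data model

The package analyzes coarse bead models (one bead per residue, Cα-level) of
multi-domain complexes. Domains are named, disjoint index sets
(`DomainMap`); the collective variables (CVs) are Euclidean distances
between domain centers of mass. Centers of mass are **unweighted centroids**:
at Cα resolution all beads have identical mass, so mass weighting would only
add a constant table to the data model without changing any distance.
Units are nm / ns / kJ·mol⁻¹ internally; free energies are reported in
kcal·mol⁻¹ (1 kcal = 4.184 kJ), min-shifted to zero. k_B =
0.0083144621 kJ·mol⁻¹·K⁻¹, so k_BT = 2.5775 kJ·mol⁻¹ = 0.616 kcal·mol⁻¹ at
the default 310 K.

Superposition uses the Kabsch solution (via
`scipy.spatial.transform.Rotation.align_vectors`), which always returns a
proper rotation; selections with fewer than 3 beads or collinear geometry
are rejected because the optimal rotation is then underdetermined. RMSD
series may fit one selection (a folded core) and measure another (flexible
loops), the standard way to separate local disorder from global motion.
Flexible-loop beads are likewise meant to be excluded from PCA fitting and
covariance via the `selection` argument.

## Synthetic study system

The generator replaces long all-atom MD with systems whose answers are known
exactly:

- **Analytic potentials.** Harmonic ½κ(x−c)²; double well
  U = h((x²−x₀²)/x₀²)² with barrier h at x = 0 and minima ±x₀; a linear
  tilt a·x to split the basins; and separable 2D combinations. Basin
  free-energy differences are computed by quadrature of e^(−U/kT) with the
  basin boundary at the barrier top — the oracle all free-energy estimators
  are scored against.
- **Overdamped Langevin (Brownian) integrator.** Euler–Maruyama:
  x ← x − (Δt/γ)∇U + √(2k_BTΔt/γ)·ξ. Only equilibrium sampling matters for
  validating estimators, so inertia is omitted. The scheme's leading
  sampling bias is a relative variance error of ≈ Δt·κ_eff/2γ in a well of
  curvature κ_eff; default timesteps are chosen so this is ≲ 1–3% (e.g.
  Δt = 10⁻⁵ ps at γ = 1 ps⁻¹ for κ_eff ≈ 1500 kJ·mol⁻¹·nm⁻²). Noise is
  precomputed from a seeded `numpy` Generator and the inner loop is a
  numba kernel, so every run is bitwise reproducible from its seed.
  Divergence (|x| beyond a bound) raises an error naming the step.
- **Exact window sampler.** For a harmonic base (κ, c_base) under a
  harmonic restraint (k, c) the Boltzmann distribution is Gaussian with
  mean (κc_base + kc)/(κ+k) and variance k_BT/(κ+k); sampling it i.i.d.
  tests WHAM with zero integrator error.
- **Bead complexes.** Five domains (default names RBD, CRD, KD, and the two
  14-3-3 protomer anchors P365/P729) arranged on a 2-nm circle with seeded
  0.2-nm Gaussian clouds; an anisotropic elastic network (intra- vs
  inter-domain spring constants, pseudo-inverse Hessian with the six
  rigid-body modes removed) supplies a physically shaped covariance for
  ensemble generation.
- **Campaign bookkeeping.** The manifest encodes a full Cartesian product
  of loop variants times replicas; the defaults (9 × 3 × 5 at 500 ns, last
  1000 of 5000 frames analyzed per run) describe a 27-model /
  135-simulation / 135 000-frame design, and the staged-equilibration
  default (20 stages × 2.5 ns) totals 50 ns per window.

What the toy system does **not** emulate: conformational substates beyond
the analytic wells, anharmonic loop dynamics coupled to the CV, solvent
friction anisotropy, or multi-dimensional barriers between CVs. Passing the
synthetic recovery tests therefore certifies the estimators, not the
biology: on real trajectories the dominant uncertainty is sampling, not
estimation.

## Essential dynamics

Covariance uses the 1/n (ensemble-average) normalization; at the intended
frame counts (10³–10⁵) the difference from 1/(n−1) is far below statistical
error. Frames are superposed on a reference before accumulation; appending
rigidly moved copies of frames leaves the covariance unchanged, which the
suite asserts. Eigendecomposition sorts descending and fixes each
eigenvector's sign by its largest-magnitude component, making decompositions
deterministic.

The mode-limited DCCM between residues i and j is

C_ij = Σ_{l≤n} (u_iˡ·u_jˡ) λ_l / √(Σ_{l≤n} |u_iˡ|²λ_l) √(Σ_{l≤n} |u_jˡ|²λ_l),

with u_iˡ the 3-vector block of mode l on residue i and n = 10 by default.
The denominator is the product of the two **per-residue** mode-limited
variances — the only normalization that gives a unit diagonal; a
cross-term denominator (occasionally seen in print) cannot. With n = m
(all modes) the formula reduces exactly to the classical covariance-block
DCCM, which the suite verifies against a brute-force computation from raw
frames. Residues with zero mode-limited variance cannot be normalized;
their rows/columns are set to 0 and reported via `degenerate_residues`.

## Umbrella sampling and WHAM

Windows are evenly spaced with endpoints included; the staged equilibration
walks the restraint center linearly from a start value, ending exactly at
the target (stage i of n sits at start + (i/n)(target − start)).

Statistical inefficiency g = 1 + 2Σ_t (1 − t/n)ρ̂(t), with ρ̂ estimated per
lag (unbiased normalization, FFT) and the sum truncated at the first
negative estimate — a simple, conservative surrogate for
initial-positive-sequence estimators; subsampling keeps every ⌈g⌉-th
sample. Against AR(1) with ρ = 0.9 (exact g = 19) the estimator is within a
few percent at n = 10⁵. Pooling across conformers requires bitwise-matching
window schedules and concatenates decorrelated samples with provenance
tags.

WHAM solves the standard self-consistent equations on histograms,

p_b ∝ Σ_k n_kb / Σ_k N_k exp[(f_k − U_k(x_b))/k_BT],  
f_k = −k_BT ln Σ_b p_b exp(−U_k(x_b)/k_BT),

with two numerical refinements:

1. **Internal grid refinement.** The equations are iterated on
   `n_bins × refine` fine bins (default refine = 10) and the fine
   probabilities are summed into the requested output bins. With stiff
   springs (k = 1000 kJ·mol⁻¹·nm⁻², window σ ≈ 0.05 nm) a 0.1-nm output
   bin spans several k_BT of bias, and iterating directly on the coarse
   grid leaves a sawtooth discretization error of several tenths of a
   kcal·mol⁻¹; resolving the histogram at the window-width scale removes
   it while the reported PMF stays on the requested 40-bin grid.
2. **Bin-averaged bias.** The per-bin bias factor uses the Gauss–Legendre
   average ⟨e^(−U_k/kT)⟩_bin rather than the bin-center value.

Convergence: the equations are the stationarity conditions of a convex
likelihood in f_k/k_BT, which is minimized directly (L-BFGS) and then
certified by fixed-point iteration against the documented tolerance
(10⁻⁶ kcal·mol⁻¹ on max|Δf_k|, 10⁵-iteration cap; non-convergence sets a
flag and warns, never returns silently). Samples outside the analysis range
are dropped and counted — sampling and analysis ranges are independent
settings. Bins are half-open with the final bin closed. Preconditions:
every window must have at least one in-range sample, and the occupied bin
ranges of center-adjacent windows must overlap or touch; a gap raises a
connectivity error naming the windows.

**Accuracy limits.** PMF error has three parts: histogram noise per bin
(~k_BT/√n_b), the f_k linkage noise between adjacent windows (grows like a
random walk when overlap is thin), and discretization (removed by the
refinements above). With 15 windows spaced 5.7σ apart at n = 5000/window,
the linkage noise alone puts the central-80% RMS at ≈ 0.1–0.3 kcal·mol⁻¹ —
confirmed to be the information-theoretic floor by comparison with a
binless estimate on identical data — so sub-0.1 kcal·mol⁻¹ accuracy in that
geometry is a matter of seed luck for any estimator. At the study's window
densities (spacing ≈ 2σ) the same pipeline reaches ≈ 0.03–0.08 kcal·mol⁻¹.

**Bootstrap.** Each of the (default 100) Monte-Carlo trials redraws every
window's decorrelated samples with replacement — implemented exactly as a
multinomial redraw of the window's fine-bin histogram including its
out-of-range mass — re-solves WHAM warm-started from the point estimate,
and min-shifts. The 95% band is the 2.5/97.5 percentile envelope, widened
if necessary to bracket the point estimate (except the degenerate
single-trial case, which is a zero-width band and warns). Trials that lose
window connectivity are discarded and counted; more than 20% discarded is
an error. Bands reproduce the true sampling standard deviation of the PMF
well (checked against independent replications), but *per-bin* coverage of
a min-shifted band fluctuates dataset-to-dataset because bin errors are
strongly correlated through the shared f_k.

## Metadynamics

Standard (non-well-tempered) metadynamics with constant hill height: every
`stride` steps (default 1000) a Gaussian of height 0.25 kJ·mol⁻¹ and width
0.08 nm per CV is deposited at the post-step CV value; forces use analytic
Gaussian gradients, and hills farther than 6σ are skipped. A run of
n_steps deposits exactly ⌊n_steps/stride⌋ hills. The free-energy surface is
estimated from the **final-time bias only**, F(s) = −V_G(s, t_end),
converted to kcal·mol⁻¹ and min-shifted; no time-averaging over the filling
trajectory is applied. Variance reduction comes instead from replica
averaging: each replica surface is min-shifted, node-wise averaged, and the
mean re-shifted (min-shift-then-average is the implemented convention). On
a tilted double well the 15-replica average recovers the basin ΔF to
≈ 0.03–0.1 kcal·mol⁻¹ with ~800 hills per replica.

Basin free-energy differences are measured from a reconstructed surface by
Boltzmann-summing grid nodes on each side of the analytic barrier top —
the same definition the quadrature oracle uses — rather than comparing well
depths, which is more robust to local noise.

For two-CV surfaces the protomer-splitting helper partitions a domain's
sorted bead indices at the midpoint (extra bead to the first half,
deterministically) and returns one COM-distance CV per half against an
anchor domain, together with a new `DomainMap` in which the protomer is
replaced by its halves (returning the parent and its halves side by side
would violate the map's disjointness invariant).

## Pipelines, seeding, reproducibility

All randomness derives from one master seed through named offsets
(`derive_seed(master, *path)`, a SeedSequence hash kept below 2³¹); replica
seeds are distinct by construction and validated when given explicitly.
Re-running an experiment from its persisted YAML config reproduces the
primary outputs bitwise (asserted in the suite by comparing file bytes).
Every stage appends a structured JSON record (parameters, sample counts,
convergence flags, discard counts) to an append-only run log; primary
result files contain no timestamps.

## Problem sizes used in the validation suite

Chosen so each check is decisively resolved while the whole suite stays
desk-scale: 10⁴ frames for PCA recovery (sampling error on eigenvalues
≈ 1.4%, against 10% tolerances); 29–31 windows × 6×10⁴ steps × 3 conformers
for Langevin umbrella runs; 5000 exact samples per window for the WHAM and
bootstrap oracles; 15 replicas × 8×10⁵ steps (800 hills each) for
metadynamics recovery; 10⁵-point series for autocorrelation checks. The
acceleration property test runs at Δt = 10⁻⁵ ps so that the unbiased
crossing of a 5 k_BT barrier is genuinely rare on the step grid being
compared.

## Known limitations

- 1D WHAM only; no MBAR-style binless estimator is exposed (one was used
  as an external oracle during validation), and no reweighting to
  observables other than the PMF.
- No well-tempered or adaptive-Gaussian metadynamics; hill height is
  constant by design.
- The toy integrator is overdamped and non-periodic; friction is scalar.
- Euler–Maruyama has a known O(Δt) sampling bias; the defaults keep it
  below the tolerances used here, but very stiff user-supplied systems
  require proportionally smaller timesteps.
- Elastic-network covariances are harmonic by construction and cannot
  represent multi-basin flexibility.
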