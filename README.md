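# flexfes

Essential-dynamics and free-energy analysis for coarse (Cα/bead-level)
models of multi-domain protein complexes — the kind of analysis used to
characterize how an autoinhibited kinase complex (e.g. BRAF bound to a
14-3-3 dimer) breathes around its closed state and how hard its
inter-domain interfaces are to pull apart.

The package implements three estimator families over a shared geometric
core, and validates all of them end-to-end on a built-in overdamped-Langevin
toy system whose free-energy landscapes are known in closed form:

- **Essential dynamics** (`flexfes.essdyn`): positional covariance
  C_ij = ⟨(x_i − ⟨x_i⟩)(x_j − ⟨x_j⟩)⟩ of a superposed trajectory,
  eigendecomposition C = PΔPᵀ, per-mode variance fractions, and mode-limited
  dynamic cross-correlation maps (DCCM) computed from the first *n* modes.
  Exposed as a scikit-learn-style estimator (`EssentialDynamics.fit/transform`).
- **Umbrella sampling / WHAM** (`flexfes.umbrella`): evenly spaced harmonic
  windows along a center-of-mass distance collective variable, staged
  restraint equilibration, statistical-inefficiency subsampling, pooling
  across independent starting conformers, the self-consistent Weighted
  Histogram Analysis Method, and Monte-Carlo bootstrap 95% bands
  (`WHAM.fit`, `wham_solve`, `bootstrap_pmf`).
- **Metadynamics** (`flexfes.metad`): history-dependent Gaussian bias
  V_G(s,t) = Σ_{t′≤t} w·exp(−Σ_i (s_i−s_i(t′))²/2σ_i²), free-energy
  surfaces as the negative final bias, and replica averaging, in one or two
  collective variables.
- **Synthetic data** (`flexfes.toysim`): analytic potentials (harmonic,
  double well, tilted double well, separable 2D), a seeded Brownian-dynamics
  integrator, an exact Gaussian sampler for restrained harmonic wells,
  bead-domain complexes with elastic-network covariances, Gaussian
  trajectory ensembles, and the (9 loop-I × 3 loop-II × 5 replica) campaign
  bookkeeping of a 135-simulation study design.
- **Pipelines and CLI** (`flexfes.pipeline`, `flexfes.cli`): YAML-configured,
  bitwise-reproducible end-to-end experiments and a `flexfes` command with
  `simulate`, `windows`, `subsample`, `wham`, `bootstrap`, `pca`, `dccm`,
  `metad`, `fes` and `run` subcommands.

Units: nm, ns, kJ/mol internally; free-energy profiles are reported in
kcal/mol, min-shifted to zero; 310 K default temperature.

## Worked example

Recover the free-energy difference between the basins of a tilted double
well (barrier 4 k_BT, minima ±0.4 nm, tilt 5 kJ/mol/nm) with umbrella
sampling and WHAM:

```python
import numpy as np
import flexfes as ff

kT = ff.kt(310.0)
pot = ff.PotentialSpec.tilted_double_well(4 * kT, 0.4, 5.0)

windows = ff.make_window_schedule([-0.7, 0.7], 29, force_constant=1000.0)
pooled = []
for i, w in enumerate(windows):
    s = ff.run_langevin(
        pot,
        restraints=[ff.RestraintSpec(w.center, w.force_constant)],
        params=ff.LangevinParams(timestep=1e-5, n_steps=60_000, seed=100 + i),
        x0=w.center, save_every=10,
    )
    s.window = w
    pooled.append(ff.subsample(s, ff.statistical_inefficiency(s)))

res = ff.wham_solve(windows, pooled, [-0.7, 0.7], n_bins=40)
p = np.exp(-res.free_energy * 4.184 / kT)
dF = -kT / 4.184 * np.log(p[res.bin_centers > 0].sum() / p[res.bin_centers < 0].sum())
print(f"dF = {dF:.3f} kcal/mol   (analytic "
      f"{ff.basin_free_energy_difference(pot) / 4.184:.3f})")
```

Output:

```
dF = 1.074 kcal/mol   (analytic 0.894)
```

A single pass over the windows lands within ~0.2 kcal/mol (below thermal
accuracy, k_BT ≈ 0.62 kcal/mol at 310 K) of the quadrature value of the
analytic potential; pooling windows from several independent starting
conformers, as `run_us_experiment` does, tightens this further. The
positive sign means the right-hand basin sits higher in free energy, as the
tilt dictates.

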